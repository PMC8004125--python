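"""VIA round trips, the polygon-intersection labelling rule, augmentation."""

import json

import numpy as np
import pytest

from usfusion.annotations import (HCC, PAR, AnnotatedFramePair, PairedPatch,
                                  PolygonAnnotation, augment_rotations,
                                  candidate_grid, extract_patches,
                                  patch_intersections, polygon_mask,
                                  read_via_annotations, train_time_augment,
                                  translate_reflect, write_via_annotations)

TRIANGLE = [(10.0, 10.0), (40.0, 10.0), (25.0, 40.0)]


# ---------------------------------------------------------------------------
# VIA JSON

def test_via_round_trip_exact(tmp_path):
    anns = [PolygonAnnotation("frame000", TRIANGLE),
            PolygonAnnotation("frame001",
                              [(1.5, 2.25), (8.0, 3.0), (7.0, 9.0), (2.0, 8.5)])]
    path = tmp_path / "via.json"
    write_via_annotations(anns, path)
    loaded = read_via_annotations(path)
    assert len(loaded) == 2
    for orig, back in zip(anns, loaded):
        assert back.frame_id == orig.frame_id
        assert back.vertices == orig.vertices


def test_via_triangle_has_three_vertices(tmp_path):
    path = tmp_path / "via.json"
    write_via_annotations([PolygonAnnotation("f", TRIANGLE)], path)
    (ann,) = read_via_annotations(path)
    assert len(ann.vertices) == 3


def test_via_zero_regions_gives_empty_collection(tmp_path):
    path = tmp_path / "via.json"
    write_via_annotations([], path)
    assert read_via_annotations(path) == []


def test_via_malformed_and_non_polygon_rejected(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(ValueError):
        read_via_annotations(bad)
    path = tmp_path / "rect.json"
    write_via_annotations([PolygonAnnotation("f", TRIANGLE)], path)
    doc = json.loads(path.read_text())
    key = next(iter(doc["metadata"]))
    doc["metadata"][key]["xy"][0] = 2  # rectangle shape code
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError):
        read_via_annotations(path)


def test_polygon_needs_three_vertices():
    with pytest.raises(ValueError):
        PolygonAnnotation("f", [(0, 0), (1, 1)])


# ---------------------------------------------------------------------------
# Rasterization

def test_polygon_mask_matches_point_in_polygon_oracle(rng):
    """Raster mask equals a brute-force crossing-number test per pixel."""
    verts = [(5.3, 4.2), (24.7, 6.1), (27.2, 25.8), (14.1, 29.3), (3.9, 18.4)]
    mask = polygon_mask(verts, (32, 32))

    def inside(px, py):
        crossings = 0
        n = len(verts)
        for i in range(n):
            x1, y1 = verts[i]
            x2, y2 = verts[(i + 1) % n]
            if (y1 > py) != (y2 > py):
                x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                if px < x_at:
                    crossings += 1
        return crossings % 2 == 1

    oracle = np.array([[inside(x, y) for x in range(32)] for y in range(32)])
    assert np.array_equal(mask, oracle)


def test_degenerate_polygon_rejected():
    frame = AnnotatedFramePair("f", np.zeros((300, 300), np.uint8),
                               np.zeros((300, 300), np.uint8))
    degenerate = PolygonAnnotation("f", [(5, 5), (10, 10), (15, 15)])
    with pytest.raises(ValueError):
        extract_patches(frame, degenerate)


# ---------------------------------------------------------------------------
# Patch extraction

def _frame(size=360):
    img = np.arange(size * size, dtype=np.int64).reshape(size, size) % 256
    return AnnotatedFramePair("f0", img.astype(np.uint8),
                              (255 - img).astype(np.uint8))


def test_candidate_grid_is_4x4_for_default_sizes():
    corners = candidate_grid((180, 180), (360, 360))
    assert len(corners) == 16  # floor(250/51) = 4 per axis
    for (r1, c1) in corners:
        for (r2, c2) in corners:
            if (r1, c1) != (r2, c2):
                assert abs(r1 - r2) >= 51 or abs(c1 - c2) >= 51


def test_full_cover_polygon_labels_everything_hcc():
    frame = _frame()
    poly = PolygonAnnotation("f0", [(0, 0), (359, 0), (359, 359), (0, 359)])
    inter = patch_intersections(frame.bmode.shape, poly)
    assert len(inter) == 16
    assert all(v == 51 * 51 == 2601 for _, v in inter)
    patches = extract_patches(frame, poly)
    assert len(patches) == 16
    assert all(p.label == HCC for p in patches)


def test_disjoint_polygon_labels_everything_par():
    frame = _frame()
    # positive area but no pixel center inside -> intersection 0 everywhere
    poly = PolygonAnnotation("f0", [(10.2, 10.2), (10.8, 10.2), (10.5, 10.8)])
    patches = extract_patches(frame, poly)
    assert patches and all(p.label == PAR for p in patches)
    assert all(v == 0 for _, v in patch_intersections(frame.bmode.shape, poly))


def test_partial_intersections_are_discarded():
    """Every emitted patch has intersection 0 or 2601, never in between."""
    from usfusion.synthetic import SyntheticParams, generate_annotated_study

    study = generate_annotated_study(SyntheticParams(seed=13), n_frames=1)
    frame, poly = study.frames[0], study.polygons[0]
    ann = PolygonAnnotation(frame.frame_id, poly)
    inter = dict(patch_intersections(frame.bmode.shape, ann))
    patches = extract_patches(frame, ann)
    emitted = {(int(p.origin[1]), int(p.origin[2])) for p in patches}
    assert any(0 < v < 2601 for v in inter.values())  # mixed tiles exist
    for corner, v in inter.items():
        if v in (0, 2601):
            assert corner in emitted
        else:
            assert corner not in emitted
    for p in patches:
        assert p.label == (HCC if inter[(p.origin[1], p.origin[2])] else PAR)


def test_patches_carry_coregistered_channels():
    frame = _frame()
    poly = PolygonAnnotation("f0", [(0, 0), (359, 0), (359, 359), (0, 359)])
    p = extract_patches(frame, poly)[0]
    r, c = int(p.origin[1]), int(p.origin[2])
    assert np.array_equal(p.bmode, frame.bmode[r:r + 51, c:c + 51])
    assert np.array_equal(p.ceus, frame.ceus[r:r + 51, c:c + 51])


# ---------------------------------------------------------------------------
# Augmentation

def _patch(rng, size=5):
    return PairedPatch(bmode=rng.integers(0, 256, (size, size), dtype=np.uint8),
                       ceus=rng.integers(0, 256, (size, size), dtype=np.uint8),
                       label=HCC)


def test_rotation_augmentation_quadruples_and_keeps_labels(rng):
    patches = [_patch(rng) for _ in range(3)]
    out = augment_rotations(patches)
    assert len(out) == 4 * len(patches)
    assert all(p.label == HCC for p in out)
    tags = [p.augmentation_tag for p in out[:4]]
    assert tags == ["none", "rot90", "rot180", "rot270"]


def test_rot180_twice_is_identity(rng):
    p = _patch(rng)
    once = augment_rotations([p])[2]
    twice = augment_rotations([once])[2]
    assert np.array_equal(twice.bmode, p.bmode)
    assert np.array_equal(twice.ceus, p.ceus)


def test_rot90_matches_index_remapping_oracle(rng):
    p = _patch(rng, size=5)
    rot = augment_rotations([p])[1]
    n = 5
    oracle = np.empty_like(p.bmode)
    for r in range(n):
        for c in range(n):
            # counter-clockwise quarter turn: (r, c) <- (c, n-1-r)
            oracle[r, c] = p.bmode[c, n - 1 - r]
    assert np.array_equal(rot.bmode, oracle)


def test_rotation_requires_square():
    p = PairedPatch(bmode=np.zeros((4, 5), np.uint8),
                    ceus=np.zeros((4, 5), np.uint8), label=PAR)
    with pytest.raises(ValueError):
        augment_rotations([p])


def test_translation_matches_reflected_shift_oracle():
    ramp = (np.arange(49).reshape(7, 7) * 3 % 256).astype(np.uint8)
    dr, dc = 2, 3
    shifted = translate_reflect(ramp, dr, dc)

    def reflect(i, n):
        while not 0 <= i < n:
            i = -i - 1 if i < 0 else 2 * n - 1 - i
        return i

    oracle = np.empty_like(ramp)
    for r in range(7):
        for c in range(7):
            oracle[r, c] = ramp[reflect(r - dr, 7), reflect(c - dc, 7)]
    assert np.array_equal(shifted, oracle)


def test_translate_zero_is_identity(rng):
    p = _patch(rng)
    assert np.array_equal(translate_reflect(p.bmode, 0, 0), p.bmode)


def test_train_time_augment_identity_draw_exists_and_flip_involutes(rng):
    p = _patch(rng, size=9)
    found_identity = False
    for seed in range(5000):
        out = train_time_augment(p, np.random.default_rng(seed))
        if np.array_equal(out.bmode, p.bmode):
            found_identity = True
            break
    assert found_identity
    flipped = PairedPatch(bmode=p.bmode[:, ::-1].copy(),
                          ceus=p.ceus[:, ::-1].copy(), label=p.label)
    assert np.array_equal(flipped.bmode[:, ::-1], p.bmode)


def test_train_time_augment_applies_same_transform_to_both_channels():
    base = np.arange(81, dtype=np.uint8).reshape(9, 9)
    p = PairedPatch(bmode=base, ceus=base.copy(), label=HCC)
    out = train_time_augment(p, np.random.default_rng(5))
    assert np.array_equal(out.bmode, out.ceus)
    assert out.label == HCC
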