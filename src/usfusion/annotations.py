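"""Polygon annotations and paired-patch extraction.

Lesions are delineated as closed polygons (VIA-3 style JSON, as produced
by the VGG Image Annotator) on co-registered B-mode/CEUS frame pairs.
Fixed-size square patches are harvested from a search region around each
polygon centroid with a non-overlapping sliding window; a candidate patch
is kept only when its pixel-center intersection with the polygon is
*complete* (labelled HCC) or *empty* (labelled PAR).  Partially covered
patches are discarded so that both classes stay pure.

Coordinate conventions: images are row-major numpy arrays with the origin
at the top-left; polygon vertices are (x, y) = (column, row) pairs, the
VIA convention.  Pixel (r, c) has its center at x = c, y = r.  Points on
the polygon boundary count as inside (deterministic tie rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

HCC = "HCC"
PAR = "PAR"

#: VIA-3 shape code for a polygon region.
_VIA_POLYGON = 7


@dataclass
class PolygonAnnotation:
    """One closed lesion polygon on one frame."""

    frame_id: str
    vertices: list  # [(x, y), ...] in pixel coordinates

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]

    @property
    def area(self) -> float:
        xs = np.array([v[0] for v in self.vertices])
        ys = np.array([v[1] for v in self.vertices])
        return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))

    @property
    def centroid(self) -> tuple[int, int]:
        """Arithmetic vertex centroid, rounded to the nearest pixel (x, y)."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (int(round(sum(xs) / len(xs))), int(round(sum(ys) / len(ys))))


@dataclass
class AnnotatedFramePair:
    """Co-registered B-mode and CEUS frames of identical size."""

    frame_id: str
    bmode: np.ndarray
    ceus: np.ndarray

    def __post_init__(self) -> None:
        self.bmode = np.asarray(self.bmode)
        self.ceus = np.asarray(self.ceus)
        if self.bmode.shape != self.ceus.shape:
            raise ValueError("bmode and ceus frames must share dimensions")


@dataclass
class PairedPatch:
    """A labelled pair of co-registered square grayscale patches."""

    bmode: np.ndarray
    ceus: np.ndarray
    label: str
    origin: tuple = ("", 0, 0)  # (frame_id, top row, left col)
    augmentation_tag: str = "none"

    def __post_init__(self) -> None:
        self.bmode = np.asarray(self.bmode)
        self.ceus = np.asarray(self.ceus)
        if self.bmode.shape != self.ceus.shape:
            raise ValueError("channel shapes differ")
        if self.label not in (HCC, PAR):
            raise ValueError(f"label must be {HCC} or {PAR}")

    @property
    def size(self) -> int:
        return self.bmode.shape[0]


# ---------------------------------------------------------------------------
# VIA-3 style JSON

def write_via_annotations(annotations: Sequence[PolygonAnnotation],
                          path: str | Path,
                          project_name: str = "usfusion") -> None:
    """Write polygons as a VIA-3 style project JSON (one file per frame_id)."""
    frame_ids = sorted({a.frame_id for a in annotations})
    files = {str(i + 1): {"fid": str(i + 1), "fname": fid, "type": 2,
                          "loc": 1, "src": fid}
             for i, fid in enumerate(frame_ids)}
    fid_of = {fid: str(i + 1) for i, fid in enumerate(frame_ids)}
    metadata = {}
    for k, ann in enumerate(annotations):
        xy = [_VIA_POLYGON]
        for x, y in ann.vertices:
            xy.extend([x, y])
        metadata[f"{fid_of[ann.frame_id]}_{k:04d}"] = {
            "vid": fid_of[ann.frame_id], "flg": 0, "z": [], "xy": xy, "av": {}}
    doc = {
        "project": {"pid": "__VIA_PROJECT_ID__", "pname": project_name,
                    "data_format_version": "3.1.1"},
        "config": {"file": {"loc_prefix": {"1": ""}}, "ui": {}},
        "attribute": {},
        "file": files,
        "metadata": metadata,
        "view": {fid: {"fid_list": [fid]} for fid in files},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_via_annotations(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon regions from a VIA-3 style project JSON.

    Non-polygon regions raise a format error; a project with zero regions
    returns an empty list.
    """
    try:
        doc = json.loads(Path(path).read_text())
        files = doc["file"]
        metadata = doc.get("metadata", {})
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"not a VIA-style annotation file: {path}") from exc
    fname_of = {fid: rec.get("fname", fid) for fid, rec in files.items()}
    annotations = []
    for key in sorted(metadata):
        rec = metadata[key]
        xy = rec.get("xy", [])
        if not xy or int(xy[0]) != _VIA_POLYGON:
            raise ValueError(f"region {key} is not a polygon (xy code {xy[:1]})")
        coords = xy[1:]
        if len(coords) < 6 or len(coords) % 2:
            raise ValueError(f"region {key} has a malformed vertex list")
        verts = [(coords[i], coords[i + 1]) for i in range(0, len(coords), 2)]
        annotations.append(PolygonAnnotation(frame_id=fname_of.get(rec["vid"],
                                                                   rec["vid"]),
                                             vertices=verts))
    return annotations


# ---------------------------------------------------------------------------
# Rasterization and extraction

def polygon_mask(vertices: Sequence[tuple[float, float]],
                 shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers covered by the polygon.

    Pixel (r, c) is True iff the point (x=c, y=r) lies inside the polygon
    or exactly on its boundary.
    """
    poly = _ShapelyPolygon([(float(x), float(y)) for x, y in vertices])
    if poly.area == 0:
        raise ValueError("degenerate polygon with zero area")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    return shapely.covers(poly, pts).reshape(h, w)


def candidate_grid(center: tuple[int, int], image_shape: tuple[int, int],
                   patch_size: int = 51, region: int = 250
                   ) -> list[tuple[int, int]]:
    """Top-left corners of non-overlapping candidate tiles.

    A ``region`` x ``region`` search box is centered on ``center`` (x, y),
    clipped to the image; tiles are anchored at the box's top-left corner
    with stride ``patch_size`` and only fully in-bounds tiles are kept.
    """
    h, w = image_shape
    cx, cy = center
    top = max(0, cy - region // 2)
    left = max(0, cx - region // 2)
    bottom = min(h, cy - region // 2 + region)
    right = min(w, cx - region // 2 + region)
    corners = []
    for r in range(top, bottom - patch_size + 1, patch_size):
        for c in range(left, right - patch_size + 1, patch_size):
            corners.append((r, c))
    return corners


def extract_patches(frame: AnnotatedFramePair, polygon: PolygonAnnotation,
                    patch_size: int = 51, region: int = 250
                    ) -> list[PairedPatch]:
    """Harvest labelled paired patches around one polygon.

    The intersection of a candidate tile with the polygon is the number of
    its pixel centers covered by the polygon: ``patch_size**2`` labels the
    tile HCC, 0 labels it PAR, anything in between discards it.
    """
    if polygon.area == 0:
        raise ValueError("degenerate polygon with zero area")
    mask = polygon_mask(polygon.vertices, frame.bmode.shape)
    full = patch_size * patch_size
    patches = []
    for r, c in candidate_grid(polygon.centroid, frame.bmode.shape,
                               patch_size, region):
        inter = int(mask[r:r + patch_size, c:c + patch_size].sum())
        if inter == full:
            label = HCC
        elif inter == 0:
            label = PAR
        else:
            continue
        patches.append(PairedPatch(
            bmode=frame.bmode[r:r + patch_size, c:c + patch_size].copy(),
            ceus=frame.ceus[r:r + patch_size, c:c + patch_size].copy(),
            label=label, origin=(frame.frame_id, r, c)))
    return patches


def patch_intersections(frame_shape: tuple[int, int],
                        polygon: PolygonAnnotation,
                        patch_size: int = 51, region: int = 250
                        ) -> list[tuple[tuple[int, int], int]]:
    """(corner, intersection-count) for every candidate tile (diagnostics)."""
    mask = polygon_mask(polygon.vertices, frame_shape)
    return [((r, c), int(mask[r:r + patch_size, c:c + patch_size].sum()))
            for r, c in candidate_grid(polygon.centroid, frame_shape,
                                       patch_size, region)]


# ---------------------------------------------------------------------------
# Augmentation

def augment_rotations(patches: Iterable[PairedPatch]) -> list[PairedPatch]:
    """Original + 90/180/270-degree rotations of every patch.

    Both channels are rotated identically and labels are preserved, so the
    output has exactly four times as many patches as the input.
    """
    out = []
    for p in patches:
        if p.bmode.shape[0] != p.bmode.shape[1]:
            raise ValueError("rotation augmentation requires square patches")
        out.append(p)
        for k, tag in ((1, "rot90"), (2, "rot180"), (3, "rot270")):
            out.append(PairedPatch(bmode=np.rot90(p.bmode, k).copy(),
                                   ceus=np.rot90(p.ceus, k).copy(),
                                   label=p.label, origin=p.origin,
                                   augmentation_tag=tag))
    return out


def train_time_augment(patch: PairedPatch, rng: np.random.Generator,
                       max_shift: int = 5) -> PairedPatch:
    """Random flip/translation applied identically to both channels.

    Each flip axis is applied with probability 1/2 and the patch is
    translated by integer offsets drawn uniformly from
    [-max_shift, max_shift], with reflected borders.
    """
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    dr, dc = (int(v) for v in rng.integers(-max_shift, max_shift + 1, size=2))

    def apply(img: np.ndarray) -> np.ndarray:
        out = img
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        out = translate_reflect(out, dr, dc)
        return out

    tag = "translate" if (dr or dc) else (
        "flip_h" if flip_h and not flip_v else
        "flip_v" if flip_v and not flip_h else
        "flip_h" if flip_h else "none")
    return PairedPatch(bmode=apply(patch.bmode), ceus=apply(patch.ceus),
                       label=patch.label, origin=patch.origin,
                       augmentation_tag=tag)


def translate_reflect(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift image content by (dr, dc), filling borders by reflection."""
    if dr == 0 and dc == 0:
        return img.copy()
    pad = max(abs(dr), abs(dc))
    # half-sample symmetric reflection, matching scipy.ndimage's "reflect"
    padded = np.pad(img, pad, mode="symmetric")
    h, w = img.shape
    r0 = pad - dr
    c0 = pad - dc
    return padded[r0:r0 + h, c0:c0 + w].copy()
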