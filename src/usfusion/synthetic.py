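"""Seeded synthetic paired B-mode / CEUS data.

The generators in this module stand in for a clinical dataset of
co-registered B-mode and contrast-enhanced ultrasound (CEUS) frames of
hepatocellular carcinoma (HCC) lesions on cirrhotic parenchyma (PAR).
They reproduce the statistical structure the downstream pipeline relies
on, not ultrasound physics:

* each patch channel is a smoothed Gaussian random field (white noise
  convolved with a Gaussian kernel, then affinely mapped to a class mean
  and standard deviation) — HCC fields are coarser and more variable
  than PAR fields, mimicking tumour heterogeneity;
* the CEUS channel is correlated with the B-mode channel and, for HCC,
  shifted upward by an arterial-phase enhancement offset;
* HCC patches mix in a small population of dark disks emulating
  necrotic regions;
* a zero-mean per-patch brightness jitter, shared by all pixels of a
  patch, emulates acquisition-to-acquisition gain variability so that
  classes overlap the way real acquisitions do.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import AnnotatedFramePair, PairedPatch

HCC = "HCC"
PAR = "PAR"


@dataclass
class SyntheticParams:
    """Parameters of the paired-patch generative model.

    Gray-level parameters are on the 8-bit [0, 255] scale; lengths are in
    pixels.  ``ceus_enhancement_offset`` is added to the CEUS channel of
    HCC patches only (PAR parenchyma is iso-enhanced by construction).
    """

    seed: int = 0
    n_per_class: int = 100
    patch_size: int = 51
    bmode_mean: dict = field(default_factory=lambda: {HCC: 135.0, PAR: 125.0})
    ceus_enhancement_offset: float = 22.0
    correlation_length: dict = field(default_factory=lambda: {HCC: 4.0, PAR: 2.0})
    field_sd: dict = field(default_factory=lambda: {HCC: 26.0, PAR: 18.0})
    necrosis_fraction: float = 0.5
    cross_channel_rho: float = 0.5
    patch_jitter_sd: float = 18.0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        for cls in (HCC, PAR):
            if not 0.0 <= self.bmode_mean[cls] <= 255.0:
                raise ValueError(f"bmode_mean[{cls}] outside [0, 255]")
            if self.correlation_length[cls] <= 0:
                raise ValueError("correlation_length must be positive")
            if self.field_sd[cls] < 0:
                raise ValueError("field_sd must be non-negative")
        if not 0.0 <= self.necrosis_fraction <= 1.0:
            raise ValueError("necrosis_fraction must be in [0, 1]")
        if not -1.0 <= self.cross_channel_rho <= 1.0:
            raise ValueError("cross_channel_rho must be in [-1, 1]")
        if self.patch_jitter_sd < 0:
            raise ValueError("patch_jitter_sd must be non-negative")


def _smooth_field(rng: np.ndarray, corr_len: float) -> np.ndarray:
    """Unit-variance smoothed field from white noise (zero mean)."""
    sm = gaussian_filter(rng, sigma=corr_len, mode="reflect")
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros_like(sm)
    return (sm - sm.mean()) / sd


def _class_fields(rng: np.random.Generator, size: int, corr_len: float,
                  rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two unit fields with cross-correlation ``rho`` at every pixel."""
    a = _smooth_field(rng.standard_normal((size, size)), corr_len)
    b = _smooth_field(rng.standard_normal((size, size)), corr_len)
    c = rho * a + np.sqrt(max(0.0, 1.0 - rho * rho)) * b
    return a, c


def _necrosis_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Boolean union of 2-4 random disks of radius ~ U(3, 8) px."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(int(rng.integers(2, 5))):
        r = rng.uniform(3.0, 8.0)
        cy, cx = rng.uniform(0, size, size=2)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return mask


def _synth_patch(rng: np.random.Generator, params: SyntheticParams,
                 label: str) -> PairedPatch:
    p = params
    size = p.patch_size
    mean = p.bmode_mean[label]
    sd = p.field_sd[label]
    f_b, f_c = _class_fields(rng, size, p.correlation_length[label],
                             p.cross_channel_rho)
    jitter = rng.normal(0.0, p.patch_jitter_sd) if p.patch_jitter_sd > 0 else 0.0
    bmode = mean + jitter + sd * f_b
    offset = p.ceus_enhancement_offset if label == HCC else 0.0
    ceus = mean + offset + jitter + sd * f_c
    if label == HCC and p.necrosis_fraction > 0:
        # draw first so the rng stream does not depend on the outcome
        use_necrosis = rng.uniform() < p.necrosis_fraction
        mask = _necrosis_mask(rng, size)
        if use_necrosis:
            dark = p.bmode_mean[HCC] - 60.0
            bmode = np.where(mask, dark + 0.5 * (bmode - mean), bmode)
            ceus = np.where(mask, dark + 0.5 * (ceus - mean - offset), ceus)
    bmode8 = np.clip(np.rint(bmode), 0, 255).astype(np.uint8)
    ceus8 = np.clip(np.rint(ceus), 0, 255).astype(np.uint8)
    return PairedPatch(bmode=bmode8, ceus=ceus8, label=label,
                       origin=("synthetic", 0, 0))


def generate_paired_patches(params: SyntheticParams) -> list[PairedPatch]:
    """Draw ``n_per_class`` labelled patch pairs per class.

    Reproducible: the same ``params`` (including ``seed``) always return a
    bitwise-identical patch list, HCC patches first.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    patches = [_synth_patch(rng, params, HCC) for _ in range(params.n_per_class)]
    patches += [_synth_patch(rng, params, PAR) for _ in range(params.n_per_class)]
    return patches


def _lesion_polygon(rng: np.random.Generator, center: tuple[float, float],
                    radius: float, n_vertices: int = 12) -> list[tuple[float, float]]:
    """Star-convex polygon around ``center`` with jittered radii."""
    cy, cx = center
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = radius * rng.uniform(0.75, 1.0, size=n_vertices)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def generate_annotated_study(params: SyntheticParams,
                             frame_size: tuple[int, int] = (360, 360),
                             n_frames: int = 3,
                             seed: int | None = None,
                             patient_id: str = "synthetic-001") -> "AnnotatedStudy":
    """Whole B-mode/CEUS frame pairs with one polygon-delineated lesion each.

    The lesion interior carries HCC-class texture (and CEUS enhancement),
    the exterior PAR-class texture; the polygon is large enough that a
    250x250 search region around its centroid contains both pure-HCC and
    pure-PAR candidate patches.
    """
    params.validate()
    h, w = frame_size
    min_side = 250 + params.patch_size
    if h < min_side or w < min_side:
        raise ValueError(
            f"frame_size must be at least {min_side} in both dimensions")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    frames: list[AnnotatedFramePair] = []
    polygons: list[list[tuple[float, float]]] = []
    for idx in range(n_frames):
        # both tissues share one acquisition, so no per-patch gain jitter
        big = replace(params, patch_size=max(h, w), patch_jitter_sd=0.0)
        hcc = _synth_patch(rng, big, HCC)
        par = _synth_patch(rng, big, PAR)
        cy = h / 2 + rng.uniform(-10, 10)
        cx = w / 2 + rng.uniform(-10, 10)
        radius = rng.uniform(95.0, 115.0)
        poly = _lesion_polygon(rng, (cy, cx), radius)
        from .annotations import polygon_mask  # local import: cycle-free
        mask = polygon_mask(poly, (h, w))
        bmode = np.where(mask, hcc.bmode[:h, :w], par.bmode[:h, :w])
        ceus = np.where(mask, hcc.ceus[:h, :w], par.ceus[:h, :w])
        frames.append(AnnotatedFramePair(frame_id=f"frame{idx:03d}",
                                         bmode=bmode, ceus=ceus))
        polygons.append(poly)
    return AnnotatedStudy(frames=frames, polygons=polygons,
                          patient_id=patient_id)


@dataclass
class AnnotatedStudy:
    """A set of co-registered frame pairs with per-frame lesion polygons."""

    frames: list
    polygons: list
    patient_id: str

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.polygons):
            raise ValueError("one polygon list entry per frame required")
        for fr, poly in zip(self.frames, self.polygons):
            if fr.bmode.shape != fr.ceus.shape:
                raise ValueError("bmode and ceus frames must share dimensions")
            if len(poly) < 3:
                raise ValueError("polygons need at least 3 vertices")
            h, w = fr.bmode.shape
            for x, y in poly:
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError("polygon vertex outside the frame")
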