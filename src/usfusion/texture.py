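"""Classical and higher-order texture features for ultrasound patches.

The per-channel texture signature is a 41-element vector combining:

* Haralick statistics (local homogeneity, energy, entropy, correlation,
  contrast, variance) of second-order gray-level co-occurrence matrices,
  averaged over the eight unit displacements at 45-degree multiples (6);
* the same six statistics generalized to third-order co-occurrence
  matrices over collinear and right-angle pixel triples (6);
* edge frequency, edge contrast and edge orientation variability from
  Sobel gradients (3);
* the lag-1 autocorrelation index (granularity) (1);
* the Hurst fractal index (1);
* Shannon entropies of the detail coefficients after one and two Haar
  wavelet decompositions (2);
* density and frequency of the micro-structures extracted by eleven
  zero-sum Laws 5x5 convolution masks (22).

Generalized co-occurrence matrices (GCMs) count pixel n-tuples in fixed
spatial configurations given by displacement vectors; for order 3 the
current pixel always occupies the central tuple slot, its two companions
sitting either on a line through it or on the two arms of a right angle
at its vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

# ---------------------------------------------------------------------------
# Quantization

def quantize(patch: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniformly bin 8-bit gray levels into ``n_levels`` levels.

    value -> floor(value * n_levels / 256); n_levels = 256 is the identity.
    """
    if not 2 <= n_levels <= 256:
        raise ValueError("n_levels must be in [2, 256]")
    p = np.asarray(patch)
    if p.min() < 0 or p.max() > 255:
        raise ValueError("expected 8-bit input in [0, 255]")
    return (p.astype(np.int64) * n_levels) // 256


# ---------------------------------------------------------------------------
# Generalized co-occurrence matrices

#: Unit displacements at all eight 45-degree multiples, as (dx, dy).
ORDER2_DIRECTIONS: tuple = tuple(
    (dx, dy) for dx, dy in
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)])

#: Third-order families: four collinear orientations with the current
#: pixel in the middle, and four right angles with it at the vertex.
ORDER3_CONFIGURATIONS: tuple = (
    ((1, 0), (-1, 0)), ((1, 1), (-1, -1)), ((0, 1), (0, -1)), ((-1, 1), (1, -1)),
    ((1, 0), (0, 1)), ((0, 1), (-1, 0)), ((-1, 0), (0, -1)), ((0, -1), (1, 0)),
)


@dataclass
class GCMConfig:
    """Spatial configuration of a generalized co-occurrence matrix."""

    order: int = 2
    n_levels: int = 256
    displacements: tuple = ORDER2_DIRECTIONS

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if not 2 <= self.n_levels <= 256:
            raise ValueError("n_levels must be in [2, 256]")
        self.displacements = tuple(self.displacements)
        for disp in self.displacements:
            arms = (disp,) if self.order == 2 else disp
            if self.order == 3 and len(arms) != 2:
                raise ValueError("order-3 configurations need two displacements")
            for dx, dy in arms:
                if dx == 0 and dy == 0:
                    raise ValueError("displacements must be non-zero")


def default_config(order: int, n_levels: int | None = None) -> GCMConfig:
    if order == 2:
        return GCMConfig(2, 256 if n_levels is None else n_levels,
                         ORDER2_DIRECTIONS)
    return GCMConfig(3, 64 if n_levels is None else n_levels,
                     ORDER3_CONFIGURATIONS)


@dataclass
class GCM:
    """Sparse co-occurrence counts over quantized gray-level tuples."""

    levels: np.ndarray   # (m, order) occupied cells
    counts: np.ndarray   # (m,) positive integer counts
    config: GCMConfig

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty co-occurrence matrix")
        return self.counts / self.total

    def to_dense(self) -> np.ndarray:
        n = self.config.n_levels
        dense = np.zeros((n,) * self.config.order, dtype=np.int64)
        if len(self.counts):
            dense[tuple(self.levels.T)] = self.counts
        return dense


def _pair_codes(q: np.ndarray, dx: int, dy: int, n: int) -> np.ndarray:
    """Codes f1*n + f2 for all in-bounds pixel pairs at displacement (dx, dy)."""
    h, w = q.shape
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64)
    f1 = q[r0:r1, c0:c1]
    f2 = q[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    return (f1.astype(np.int64) * n + f2).ravel()


def _triple_codes(q: np.ndarray, d1: tuple, d2: tuple, n: int) -> np.ndarray:
    """Codes for (f(p+d1), f(p), f(p+d2)) triples with the current pixel central."""
    h, w = q.shape
    (dx1, dy1), (dx2, dy2) = d1, d2
    r0 = max(0, -dy1, -dy2)
    r1 = min(h, h - dy1, h - dy2)
    c0 = max(0, -dx1, -dx2)
    c1 = min(w, w - dx1, w - dx2)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64)
    fc = q[r0:r1, c0:c1].astype(np.int64)
    fa = q[r0 + dy1:r1 + dy1, c0 + dx1:c1 + dx1]
    fb = q[r0 + dy2:r1 + dy2, c0 + dx2:c1 + dx2]
    return ((fa.astype(np.int64) * n + fc) * n + fb).ravel()


def _codes_for(q: np.ndarray, config: GCMConfig, disp) -> np.ndarray:
    if config.order == 2:
        dx, dy = disp
        return _pair_codes(q, dx, dy, config.n_levels)
    return _triple_codes(q, disp[0], disp[1], config.n_levels)


def _gcm_from_codes(codes: np.ndarray, config: GCMConfig) -> GCM:
    if codes.size == 0:
        return GCM(levels=np.empty((0, config.order), dtype=np.int64),
                   counts=np.empty(0, dtype=np.int64), config=config)
    uniq, cnt = np.unique(codes, return_counts=True)
    n = config.n_levels
    if config.order == 2:
        levels = np.stack([uniq // n, uniq % n], axis=1)
    else:
        levels = np.stack([uniq // (n * n), (uniq // n) % n, uniq % n], axis=1)
    return GCM(levels=levels, counts=cnt.astype(np.int64), config=config)


def compute_gcm(patch: np.ndarray, config: GCMConfig) -> GCM:
    """Accumulate co-occurrence counts over the whole displacement family.

    ``patch`` must already be quantized to ``config.n_levels`` levels.
    Tuples reaching outside the patch are skipped; a patch smaller than
    the displacement extent yields an empty GCM (total 0).
    """
    q = np.asarray(patch)
    if q.size and q.max() >= config.n_levels:
        raise ValueError("patch is not quantized to config.n_levels")
    codes = [_codes_for(q, config, disp) for disp in config.displacements]
    return _gcm_from_codes(np.concatenate(codes) if codes else
                           np.empty(0, dtype=np.int64), config)


def gcm_per_displacement(patch: np.ndarray, config: GCMConfig) -> list[GCM]:
    """One GCM per displacement (or configuration) in the family."""
    q = np.asarray(patch)
    if q.size and q.max() >= config.n_levels:
        raise ValueError("patch is not quantized to config.n_levels")
    single = [GCMConfig(config.order, config.n_levels, (disp,))
              for disp in config.displacements]
    return [_gcm_from_codes(_codes_for(q, config, disp), cfg)
            for disp, cfg in zip(config.displacements, single)]


# ---------------------------------------------------------------------------
# Haralick statistics

HARALICK_NAMES = ("homogeneity", "energy", "entropy", "correlation",
                  "contrast", "variance")


def _marginal_stats(levels: np.ndarray, p: np.ndarray):
    mus = np.array([(levels[:, k] * p).sum() for k in range(levels.shape[1])])
    sds = np.sqrt(np.array([((levels[:, k] - mus[k]) ** 2 * p).sum()
                            for k in range(levels.shape[1])]))
    return mus, sds


def _pairwise_correlation(levels, p, mus, sds, a, b) -> float:
    if sds[a] < 1e-12 or sds[b] < 1e-12:
        return 0.0
    cov = ((levels[:, a] - mus[a]) * (levels[:, b] - mus[b]) * p).sum()
    return float(cov / (sds[a] * sds[b]))


def haralick(gcm: GCM) -> dict:
    """Six Haralick statistics of a probability-normalized GCM.

    Order-3 generalizations use the squared differences of consecutive
    tuple slots; correlation is the mean of the three two-index
    correlations.  Degenerate marginals (zero spread) give correlation 0.
    """
    p = gcm.probabilities()
    lv = gcm.levels.astype(float)
    if gcm.config.order == 2:
        d2 = (lv[:, 0] - lv[:, 1]) ** 2
    else:
        d2 = ((lv[:, 0] - lv[:, 1]) ** 2 + (lv[:, 1] - lv[:, 2]) ** 2) / 2.0
    mus, sds = _marginal_stats(lv, p)
    if gcm.config.order == 2:
        corr = _pairwise_correlation(lv, p, mus, sds, 0, 1)
    else:
        corr = float(np.mean([_pairwise_correlation(lv, p, mus, sds, a, b)
                              for a, b in ((0, 1), (1, 2), (0, 2))]))
    dev2 = np.mean([(lv[:, k] - mus[k]) ** 2 for k in range(lv.shape[1])], axis=0)
    return {
        "homogeneity": float((p / (1.0 + d2)).sum()),
        "energy": float((p * p).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "correlation": corr,
        "contrast": float((p * d2).sum()),
        "variance": float((p * dev2).sum()),
    }


def haralick_mean(patch: np.ndarray, config: GCMConfig) -> dict:
    """Haralick statistics per displacement, arithmetically averaged."""
    per = [haralick(g) for g in gcm_per_displacement(patch, config)
           if g.total > 0]
    if not per:
        raise ValueError("no valid pixel tuples for this configuration")
    return {k: float(np.mean([f[k] for f in per])) for k in HARALICK_NAMES}


# ---------------------------------------------------------------------------
# Edge features

def edge_features(patch: np.ndarray) -> tuple[float, float, float]:
    """(edge_frequency, edge_contrast, edge_orientation_variability).

    Sobel gradient magnitude; a pixel is an edge pixel when its magnitude
    exceeds the patch-mean magnitude.  Orientation variability is the
    circular variance of gradient orientations over the edge pixels; a
    patch with no edge pixels returns (0, 0, 0).
    """
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("patch must be at least 3x3")
    gy = ndimage.sobel(p, axis=0, mode="reflect")
    gx = ndimage.sobel(p, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    edges = mag > mag.mean()
    if not edges.any():
        return (0.0, 0.0, 0.0)
    theta = np.arctan2(gy[edges], gx[edges])
    resultant = abs(np.exp(1j * theta).mean())
    return (float(edges.mean()), float(mag[edges].mean()),
            float(1.0 - resultant))


# ---------------------------------------------------------------------------
# Laws texture energy

_LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: Retained mask classes (all zero-sum, so constant patches respond 0).
LAWS_CLASSES = ("E5E5", "S5S5", "R5R5", "W5W5", "L5E5", "L5S5", "L5R5",
                "L5W5", "E5S5", "E5R5", "E5W5")


def _laws_energy_map(patch: np.ndarray, cls: str) -> np.ndarray:
    a, b = cls[:2], cls[2:]
    ka = np.outer(_LAWS_1D[a], _LAWS_1D[b])
    resp = np.abs(ndimage.convolve(patch, ka, mode="reflect"))
    if a != b:
        kb = np.outer(_LAWS_1D[b], _LAWS_1D[a])
        resp = 0.5 * (resp + np.abs(ndimage.convolve(patch, kb, mode="reflect")))
    return resp


def laws_features(patch: np.ndarray) -> dict:
    """Density and frequency of Laws micro-structures, per mask class.

    Density is the fraction of pixels whose energy exceeds the map mean,
    frequency the mean energy; symmetric mask pairs (e.g. L5E5/E5L5) are
    averaged into one map.  22 values over the 11 retained classes.
    """
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 5 or p.shape[1] < 5:
        raise ValueError("patch must be at least 5x5")
    out = {}
    for cls in LAWS_CLASSES:
        e = _laws_energy_map(p, cls)
        mean = e.mean()
        out[f"laws_{cls}_density"] = float((e > mean).mean()) if mean > 0 else 0.0
        out[f"laws_{cls}_frequency"] = float(mean)
    return out


# ---------------------------------------------------------------------------
# Fractal, wavelet and autocorrelation features

def hurst_index(patch: np.ndarray, max_lag: int = 8) -> float:
    """Hurst exponent estimate from mean absolute intensity increments.

    Fits log E|I(p+g) - I(p)| against log g over lags 1..max_lag
    (horizontal and vertical pairs pooled); the slope, clipped to [0, 1],
    estimates H of a fractional Brownian surface.  A zero-variance patch
    returns 0 by convention.
    """
    p = np.asarray(patch, dtype=float)
    if min(p.shape) < 2 * max_lag:
        raise ValueError("patch too small for the requested lag range")
    if p.std() < 1e-12:
        return 0.0
    lags = np.arange(1, max_lag + 1)
    mean_abs = []
    for g in lags:
        d = np.concatenate([np.abs(p[:, g:] - p[:, :-g]).ravel(),
                            np.abs(p[g:, :] - p[:-g, :]).ravel()])
        mean_abs.append(d.mean())
    mean_abs = np.array(mean_abs)
    if np.any(mean_abs <= 0):
        return 0.0
    slope = np.polyfit(np.log(lags), np.log(mean_abs), 1)[0]
    return float(np.clip(slope, 0.0, 1.0))


def _even_crop(x: np.ndarray) -> np.ndarray:
    return x[:x.shape[0] - x.shape[0] % 2, :x.shape[1] - x.shape[1] % 2]


def haar_level(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    """One orthonormal 2-D Haar step on the even-cropped input."""
    return pywt.dwt2(_even_crop(np.asarray(x, dtype=float)), "haar",
                     mode="periodization")


def _coef_entropy(details: tuple) -> float:
    e = np.concatenate([np.ravel(d) for d in details]) ** 2
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e[e > 0] / total
    return float(-(p * np.log2(p)).sum())


def wavelet_entropies(patch: np.ndarray) -> tuple[float, float]:
    """Shannon entropies of the detail energy after 1 and 2 Haar levels.

    Detail coefficients of the three subbands are pooled per level and
    their squared magnitudes normalized to a distribution (0 log 0 = 0);
    an all-constant patch has zero detail energy and returns (0, 0).
    """
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 4 or p.shape[1] < 4:
        raise ValueError("patch must be at least 4x4")
    approx1, details1 = haar_level(p)
    _, details2 = haar_level(approx1)
    return (_coef_entropy(details1), _coef_entropy(details2))


def autocorrelation_index(patch: np.ndarray) -> float:
    """Mean normalized autocorrelation at lags (1, 0) and (0, 1).

    cov(lag)/var with the global patch mean; a constant patch returns 1
    by convention (perfectly smooth texture).
    """
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 2 or p.shape[1] < 2:
        raise ValueError("patch must be at least 2x2")
    mu = p.mean()
    var = ((p - mu) ** 2).mean()
    if var < 1e-12:
        return 1.0
    c = p - mu
    rho_h = (c[:, 1:] * c[:, :-1]).mean() / var
    rho_v = (c[1:, :] * c[:-1, :]).mean() / var
    return float(0.5 * (rho_h + rho_v))


# ---------------------------------------------------------------------------
# The 41-feature vector

@dataclass
class TextureConfig:
    """Composition of the per-channel texture vector (default: 41 features)."""

    gcm2: GCMConfig = field(default_factory=lambda: default_config(2))
    gcm3: GCMConfig = field(default_factory=lambda: default_config(3))
    laws_classes: tuple = LAWS_CLASSES
    hurst_max_lag: int = 8


def feature_names(config: TextureConfig | None = None) -> list[str]:
    config = config or TextureConfig()
    names = [f"gcm2_{n}" for n in HARALICK_NAMES]
    names += [f"gcm3_{n}" for n in HARALICK_NAMES]
    names += ["edge_frequency", "edge_contrast", "edge_orientation_variability"]
    names += ["autocorrelation", "hurst"]
    names += ["wavelet_entropy_l1", "wavelet_entropy_l2"]
    for cls in config.laws_classes:
        names += [f"laws_{cls}_density", f"laws_{cls}_frequency"]
    return names


FEATURE_NAMES = feature_names()


def texture_vector(patch: np.ndarray,
                   config: TextureConfig | None = None) -> np.ndarray:
    """Full texture signature of one grayscale channel (length 41).

    Deterministic and independent of patch orientation for the
    direction-averaged co-occurrence blocks (the 45-degree displacement
    family is closed under 90-degree rotations).
    """
    config = config or TextureConfig()
    p = np.asarray(patch)
    if min(p.shape) < 16:
        raise ValueError("texture vector requires patches of at least 16x16")
    h2 = haralick_mean(quantize(p, config.gcm2.n_levels), config.gcm2)
    h3 = haralick_mean(quantize(p, config.gcm3.n_levels), config.gcm3)
    ef, ec, ev = edge_features(p)
    laws = laws_features(p)
    values = [h2[n] for n in HARALICK_NAMES]
    values += [h3[n] for n in HARALICK_NAMES]
    values += [ef, ec, ev]
    values += [autocorrelation_index(p),
               hurst_index(p, config.hurst_max_lag)]
    values += list(wavelet_entropies(p))
    for cls in config.laws_classes:
        values += [laws[f"laws_{cls}_density"], laws[f"laws_{cls}_frequency"]]
    vec = np.array(values, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite texture feature computed")
    return vec


# ---------------------------------------------------------------------------
# Feature tables

def feature_table(patches, channels: str = "both",
                  config: TextureConfig | None = None):
    """Per-patch texture features as a pandas DataFrame.

    ``channels`` selects 'bmode', 'ceus' or 'both' (concatenated with
    channel-prefixed column names); label and provenance columns are
    appended for downstream selection and classification.
    """
    import pandas as pd

    config = config or TextureConfig()
    names = feature_names(config)
    wanted = ("bmode", "ceus") if channels == "both" else (channels,)
    for ch in wanted:
        if ch not in ("bmode", "ceus"):
            raise ValueError("channels must be 'bmode', 'ceus' or 'both'")
    rows = []
    for p in patches:
        row = {}
        for ch in wanted:
            vec = texture_vector(getattr(p, ch), config)
            row.update({f"{ch}_{n}": v for n, v in zip(names, vec)})
        row["label"] = p.label
        row["frame_id"] = p.origin[0]
        row["row"], row["col"] = int(p.origin[1]), int(p.origin[2])
        row["augmentation"] = p.augmentation_tag
        rows.append(row)
    return pd.DataFrame(rows)


def write_arff(df, path, relation: str = "usfusion_features") -> None:
    """Minimal ARFF export of a feature table (numeric + nominal label)."""
    feature_cols = [c for c in df.columns
                    if c not in ("label", "frame_id", "row", "col",
                                 "augmentation")]
    lines = [f"@RELATION {relation}", ""]
    for c in feature_cols:
        lines.append(f"@ATTRIBUTE {c} NUMERIC")
    classes = ",".join(sorted(df["label"].unique()))
    lines.append(f"@ATTRIBUTE class {{{classes}}}")
    lines += ["", "@DATA"]
    for _, r in df.iterrows():
        vals = ",".join(repr(float(r[c])) for c in feature_cols)
        lines.append(f"{vals},{r['label']}")
    from pathlib import Path as _P
    _P(path).write_text("\n".join(lines) + "\n")
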