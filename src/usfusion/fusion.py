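"""Fusion of the B-mode and CEUS modalities at three levels.

* **feature level** — pixelwise combination of the two co-registered
  images (arithmetic mean, weighted mean with CEUS weight 2, or
  rescaled multiplication) before a single classifier;
* **classifier level** — combination of the per-modality branch feature
  vectors (concatenation, elementwise means/multiplication after PCA
  dimension matching, or concatenation followed by kernel PCA) before a
  shared supervised head;
* **decision level** — arithmetic or weighted averaging of the class
  probabilities emitted by two fully separate classifiers.

The weighted mean always emphasizes the CEUS channel:
``(2 * ceus + bmode) / 3``; the CEUS argument carries weight 2 in every
weighted form, which the channel-order contract of this module fixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dimredux import KPCAModel, PCAReducer, fit_kpca

IMAGE_METHODS = ("arithmetic_mean", "weighted_mean", "multiplication")
VECTOR_METHODS = ("concatenation", "arithmetic_mean", "weighted_mean",
                  "multiplication", "kpca")
DECISION_METHODS = ("arithmetic_mean", "weighted_mean")

DEFAULT_WEIGHTS = (2.0, 1.0)  # (w_ceus, w_bmode)


@dataclass
class FusionSpec:
    """Which fusion level/method to apply, with channel weights."""

    level: str
    method: str
    weights: tuple = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        valid = {"feature": IMAGE_METHODS, "classifier": VECTOR_METHODS,
                 "decision": DECISION_METHODS}
        if self.level not in valid:
            raise ValueError(f"unknown fusion level {self.level!r}")
        if self.method not in valid[self.level]:
            raise ValueError(
                f"method {self.method!r} is not valid at the {self.level} level")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


@dataclass
class ClassProbabilities:
    """Normalized (HCC, PAR) probability pair."""

    p_hcc: float
    p_par: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hcc <= 1.0 and 0.0 <= self.p_par <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_hcc + self.p_par - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_hcc, self.p_par])


def _weighted(ceus: np.ndarray, bmode: np.ndarray, weights) -> np.ndarray:
    w_c, w_b = weights
    return (w_c * ceus + w_b * bmode) / (w_c + w_b)


def fuse_images(bmode: np.ndarray, ceus: np.ndarray,
                method: str = "weighted_mean",
                weights: tuple = DEFAULT_WEIGHTS) -> np.ndarray:
    """Pixelwise fusion of an 8-bit image pair, returning an 8-bit image.

    ``arithmetic_mean`` is (b + c)/2, ``weighted_mean`` is
    (2c + b)/3 with the default weights, and ``multiplication`` is
    b*c/255 — a fixed rescaling that keeps [0, 255] endpoints exact and
    is monotone regardless of image content.  Results are rounded.
    """
    b = np.asarray(bmode, dtype=float)
    c = np.asarray(ceus, dtype=float)
    if b.shape != c.shape:
        raise ValueError("image shapes differ")
    if method == "arithmetic_mean":
        out = (b + c) / 2.0
    elif method == "weighted_mean":
        out = _weighted(c, b, weights)
    elif method == "multiplication":
        out = b * c / 255.0
    else:
        raise ValueError(f"unknown image fusion method {method!r}")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def fuse_vectors(v_ceus: np.ndarray, v_bmode: np.ndarray,
                 method: str = "concatenation",
                 weights: tuple = DEFAULT_WEIGHTS,
                 reducer: PCAReducer | None = None,
                 kpca: KPCAModel | None = None) -> np.ndarray:
    """Fuse two branch feature vectors.

    Elementwise methods require equal lengths; when the lengths differ a
    fitted PCA ``reducer`` for the longer side must be supplied (fit it
    on training-set features only).  ``kpca`` projects the concatenation
    through a fitted kernel-PCA model.
    """
    vc = np.asarray(v_ceus, dtype=float).ravel()
    vb = np.asarray(v_bmode, dtype=float).ravel()
    if method == "concatenation":
        return np.concatenate([vc, vb])
    if method == "kpca":
        if kpca is None:
            raise ValueError("kpca fusion requires a fitted KPCAModel")
        return np.asarray(kpca.transform(np.concatenate([vc, vb])))
    if vc.shape != vb.shape:
        if reducer is None:
            raise ValueError(
                "elementwise fusion of unequal lengths requires a PCA reducer")
        if len(vc) > len(vb):
            vc = np.asarray(reducer.transform(vc)).ravel()
        else:
            vb = np.asarray(reducer.transform(vb)).ravel()
        if vc.shape != vb.shape:
            raise ValueError("reducer did not match the vector lengths")
    if method == "arithmetic_mean":
        return (vc + vb) / 2.0
    if method == "weighted_mean":
        return _weighted(vc, vb, weights)
    if method == "multiplication":
        return vc * vb
    raise ValueError(f"unknown vector fusion method {method!r}")


def fit_kpca_fusion(train_ceus: np.ndarray, train_bmode: np.ndarray,
                    kernel: str = "linear", d: int = 128) -> KPCAModel:
    """Fit the kernel-PCA reduction on concatenated training features."""
    X = np.concatenate([np.asarray(train_ceus, dtype=float),
                        np.asarray(train_bmode, dtype=float)], axis=1)
    return fit_kpca(X, kernel=kernel, d=min(d, X.shape[0]))


def split_concatenation(fused: np.ndarray, len_ceus: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Recover both inputs from a concatenation (lossless inverse)."""
    fused = np.asarray(fused)
    return fused[:len_ceus], fused[len_ceus:]


def fuse_decisions(p_ceus: ClassProbabilities, p_bmode: ClassProbabilities,
                   method: str = "arithmetic_mean",
                   weights: tuple = DEFAULT_WEIGHTS) -> ClassProbabilities:
    """Per-class mean of two probability pairs, renormalized.

    Means of valid probability vectors are valid probability vectors; the
    explicit renormalization only removes floating-point residue.
    """
    if method not in DECISION_METHODS:
        raise ValueError(f"method {method!r} is not valid at the decision level")
    a = p_ceus.as_array()
    b = p_bmode.as_array()
    fused = (a + b) / 2.0 if method == "arithmetic_mean" else _weighted(a, b, weights)
    fused = fused / fused.sum()
    return ClassProbabilities(p_hcc=float(fused[0]), p_par=float(fused[1]))


def fuse_decision_scores(s_ceus: np.ndarray, s_bmode: np.ndarray,
                         method: str = "arithmetic_mean",
                         weights: tuple = DEFAULT_WEIGHTS) -> np.ndarray:
    """Vectorized decision fusion of positive-class score vectors."""
    a = np.asarray(s_ceus, dtype=float)
    b = np.asarray(s_bmode, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vector shapes differ")
    return (a + b) / 2.0 if method == "arithmetic_mean" else _weighted(a, b, weights)


# ---------------------------------------------------------------------------
# Fused-classifier heads

class FusionHead:
    """Supervised head mapping fused feature vectors to probabilities."""

    def __init__(self, kind: str = "softmax", seed: int = 0,
                 hidden: int = 32, svm_degree: int = 3):
        if kind not in ("feedforward", "softmax", "svm"):
            raise ValueError(f"unknown head kind {kind!r}")
        self.kind = kind
        self.seed = seed
        self.hidden = hidden
        self.svm_degree = svm_degree
        self._model = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y) -> "FusionHead":
        from sklearn.linear_model import LogisticRegression
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        if self.kind == "softmax":
            model = make_pipeline(
                StandardScaler(),
                LogisticRegression(max_iter=2000, random_state=self.seed))
        elif self.kind == "feedforward":
            model = make_pipeline(
                StandardScaler(),
                MLPClassifier(hidden_layer_sizes=(self.hidden,),
                              max_iter=800, random_state=self.seed))
        else:
            # probability via Platt-style logistic calibration of the margin
            model = make_pipeline(
                StandardScaler(),
                SVC(kernel="poly", degree=self.svm_degree, probability=True,
                    random_state=self.seed))
        model.fit(np.asarray(X, dtype=float), y)
        self._model = model
        self.classes_ = model.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) probabilities ordered [HCC, PAR]."""
        if self._model is None:
            raise RuntimeError("head is not fitted")
        proba = self._model.predict_proba(np.asarray(X, dtype=float))
        order = np.argsort([{"HCC": 0, "PAR": 1}.get(c, i)
                            for i, c in enumerate(self.classes_)])
        proba = proba[:, order]
        return proba / proba.sum(axis=1, keepdims=True)

    def predict_hcc_scores(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 0]


def train_fusion_head(fused_features: np.ndarray, labels,
                      head: str = "softmax", seed: int = 0,
                      **kwargs) -> FusionHead:
    """Fit a supervised head on fused training features (frozen branches)."""
    return FusionHead(kind=head, seed=seed, **kwargs).fit(fused_features, labels)
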