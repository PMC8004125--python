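"""PCA and kernel PCA used for dimension matching and fused-vector reduction.

Kernel PCA eigendecomposes the double-centered kernel matrix of the
training vectors; a new vector is projected by evaluating its (centered)
kernel row against the training references and contracting it with the
retained eigenvectors.  With the linear kernel this reduces exactly to
classical PCA scores (up to per-component sign), which the tests assert.

The eigenproblem is always solved on the n x n kernel matrix (n = number
of training vectors), never in feature space, so the reduction stays
cheap even when branch feature vectors have thousands of elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

KERNELS = ("linear", "polynomial_deg3", "gaussian")


def _kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: str,
                   gamma: float | None) -> np.ndarray:
    if kernel == "linear":
        return X @ Y.T
    if kernel == "polynomial_deg3":
        return (X @ Y.T + 1.0) ** 3
    if kernel == "gaussian":
        sq = (np.sum(X * X, axis=1)[:, None] + np.sum(Y * Y, axis=1)[None, :]
              - 2.0 * X @ Y.T)
        return np.exp(-gamma * np.maximum(sq, 0.0))
    raise ValueError(f"unknown kernel {kernel!r}")


def _median_heuristic(X: np.ndarray) -> float:
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med * med)


@dataclass
class KPCAModel:
    """Fitted kernel-PCA projection."""

    kernel: str
    gamma: float | None
    alphas: np.ndarray        # n x d, scaled so scores = K_centered @ alphas
    training_refs: np.ndarray  # n x p
    d: int
    row_means: np.ndarray      # per-training-point kernel row mean
    total_mean: float
    eigenvalues: np.ndarray    # d largest, descending
    train_scores: np.ndarray   # n x d embeddings of the training set

    def transform(self, x: np.ndarray) -> np.ndarray:
        return transform_kpca(self, x)


def fit_kpca(X: np.ndarray, kernel: str = "linear", d: int = 2,
             gamma: float | None = None) -> KPCAModel:
    """Fit kernel PCA on the rows of ``X``, retaining ``d`` components.

    Eigenvectors of the double-centered kernel matrix are sorted by
    descending eigenvalue; negative numerical residue is clipped at zero.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("kernel PCA needs at least 2 training vectors")
    if d > n:
        raise ValueError(f"cannot retain d={d} components from n={n} vectors")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    if kernel == "gaussian" and gamma is None:
        gamma = _median_heuristic(X)
    K = _kernel_matrix(X, X, kernel, gamma)
    row_means = K.mean(axis=1)
    total_mean = float(K.mean())
    Kc = K - row_means[:, None] - row_means[None, :] + total_mean
    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1][:d]
    lam = np.clip(eigvals[order], 0.0, None)
    V = eigvecs[:, order]
    # scale so that (Kc @ alpha_k) has squared norm lam_k, matching PCA scores
    with np.errstate(divide="ignore"):
        scale = np.where(lam > 1e-12, 1.0 / np.sqrt(np.maximum(lam, 1e-300)), 0.0)
    alphas = V * scale[None, :]
    train_scores = Kc @ alphas
    return KPCAModel(kernel=kernel, gamma=gamma, alphas=alphas,
                     training_refs=X, d=d, row_means=row_means,
                     total_mean=total_mean, eigenvalues=lam,
                     train_scores=train_scores)


def transform_kpca(model: KPCAModel, x: np.ndarray) -> np.ndarray:
    """Project vectors onto the retained kernel principal components."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != model.training_refs.shape[1]:
        raise ValueError("dimensionality differs from the training vectors")
    k = _kernel_matrix(x2, model.training_refs, model.kernel, model.gamma)
    kc = (k - k.mean(axis=1, keepdims=True) - model.row_means[None, :]
          + model.total_mean)
    scores = kc @ model.alphas
    return scores[0] if single else scores


@dataclass
class PCAReducer:
    """Linear projection onto the top principal components of a training set."""

    _pca: PCA
    target_dim: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        out = self._pca.transform(np.atleast_2d(X))
        return out[0] if single else out

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_


def fit_pca_reduce(X: np.ndarray, target_dim: int) -> PCAReducer:
    """Fit a PCA projection to ``target_dim`` components on the rows of X."""
    X = np.asarray(X, dtype=float)
    if target_dim > X.shape[1]:
        raise ValueError("target_dim exceeds the input dimensionality")
    pca = PCA(n_components=target_dim, svd_solver="full")
    pca.fit(X)
    return PCAReducer(_pca=pca, target_dim=target_dim)
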