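"""Splits, confusion-matrix metrics, ROC analysis and the experiment grid.

The positive class is HCC throughout.  CNN experiments use a stratified
60/15/25 train/validation/test split; conventional texture baselines use
75/25.  Classification threshold is 0.5 on the HCC probability, with
exact ties assigned to HCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import HCC, PAR

CNN_FRACTIONS = (0.60, 0.15, 0.25)
BASELINE_FRACTIONS = (0.75, 0.0, 0.25)


@dataclass
class Split:
    """Disjoint, exhaustive train/validation/test index lists."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple = CNN_FRACTIONS


def split_data(labels, fractions=CNN_FRACTIONS, seed: int = 0,
               group_ids=None) -> Split:
    """Stratified random split of patch indices.

    ``fractions`` are (train, validation, test) shares summing to 1.
    With ``group_ids``, whole groups (e.g. a source patch and all its
    augmented copies) are kept on one side of the split.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if group_ids is None:
        group_ids = np.arange(len(labels))
    group_ids = np.asarray(group_ids)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        cls_groups = np.unique(group_ids[labels == cls])
        rng.shuffle(cls_groups)
        n = len(cls_groups)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        chunks = (cls_groups[:n_train],
                  cls_groups[n_train:n_train + n_val],
                  cls_groups[n_train + n_val:])
        for part, grp in zip(parts, chunks):
            part.extend(np.flatnonzero(np.isin(group_ids, grp)))
    return Split(train=np.sort(np.array(parts[0], dtype=int)),
                 validation=np.sort(np.array(parts[1], dtype=int)),
                 test=np.sort(np.array(parts[2], dtype=int)),
                 fractions=tuple(fractions))


@dataclass
class ConfusionMatrix:
    """Counts with HCC as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_scores(hcc_scores, labels,
                          threshold: float = 0.5) -> ConfusionMatrix:
    """Threshold HCC probabilities (ties -> HCC) against true labels."""
    s = np.asarray(hcc_scores, dtype=float)
    y = np.asarray(labels)
    pred_hcc = s >= threshold
    is_hcc = y == HCC
    return ConfusionMatrix(tp=int((pred_hcc & is_hcc).sum()),
                           fn=int((~pred_hcc & is_hcc).sum()),
                           tn=int((~pred_hcc & ~is_hcc).sum()),
                           fp=int((pred_hcc & ~is_hcc).sum()))


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios return 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return (accuracy, sensitivity, specificity)


def roc_auc(hcc_scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over a sweep of unique scores; trapezoid AUC.

    Requires both classes among ``labels``.
    """
    s = np.asarray(hcc_scores, dtype=float)
    y = np.asarray(labels) == HCC
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Experiment grid

def _metrics_row(scores, labels) -> dict:
    cm = confusion_from_scores(scores, labels)
    acc, sens, spec = confusion_metrics(cm)
    _, auc = roc_auc(scores, labels)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "auc": auc}


def run_experiment_grid(patches, configs, seed: int = 0,
                        train_config=None, out_dir=None):
    """Train/evaluate a list of modality/fusion configurations.

    Each config is a dict with keys ``level`` (single | feature |
    classifier | decision), ``method`` (channel name for ``single``,
    fusion method otherwise) and optional ``backbone`` (default tiny)
    and ``head`` / ``kpca_dim``.  Branches are trained once per
    (backbone, channel) and shared across fusion configs.  Returns a
    pandas DataFrame with test and validation metrics per row; when
    ``out_dir`` is given, a CSV and an ROC overlay plot are written.
    """
    import pandas as pd

    from . import backbones as bb
    from . import fusion as fu

    labels = np.array([p.label for p in patches])
    split = split_data(labels, CNN_FRACTIONS, seed=seed)
    train_p = [patches[i] for i in split.train]
    val_p = [patches[i] for i in split.validation]
    test_p = [patches[i] for i in split.test]

    tc = train_config or bb.TrainConfig(seed=seed)
    branch_cache: dict = {}

    def trained_branch(name: str, channel: str):
        key = (name, channel)
        if key not in branch_cache:
            model = bb.build_backbone(name, seed=seed)
            bb.train_branch(model, train_p, channel, tc)
            branch_cache[key] = model
        return branch_cache[key]

    rows = []
    curves = {}
    for cfg in configs:
        level = cfg["level"]
        method = cfg["method"]
        name = cfg.get("backbone", "tiny")
        row = {"level": level, "method": method, "backbone": name}
        if level == "single":
            model = trained_branch(name, method)
            scores = {tag: bb.predict_probabilities(model, ps, method)[:, 0]
                      for tag, ps in (("test", test_p), ("val", val_p))}
        elif level == "feature":
            fused_train = [_fused_patch(p, method) for p in train_p]
            fused_val = [_fused_patch(p, method) for p in val_p]
            fused_test = [_fused_patch(p, method) for p in test_p]
            model = bb.build_backbone(name, seed=seed)
            bb.train_branch(model, fused_train, "bmode", tc)
            scores = {"test": bb.predict_probabilities(model, fused_test,
                                                       "bmode")[:, 0],
                      "val": bb.predict_probabilities(model, fused_val,
                                                      "bmode")[:, 0]}
        elif level == "classifier":
            m_c = trained_branch(name, "ceus")
            m_b = trained_branch(name, "bmode")
            feats = {tag: (bb.extract_features(m_c, ps, "ceus"),
                           bb.extract_features(m_b, ps, "bmode"))
                     for tag, ps in (("train", train_p), ("val", val_p),
                                     ("test", test_p))}
            kpca_model = None
            if method == "kpca":
                kpca_model = fu.fit_kpca_fusion(
                    *feats["train"], kernel=cfg.get("kernel", "linear"),
                    d=cfg.get("kpca_dim", 128))
            fused = {tag: np.array([
                fu.fuse_vectors(fc, fb, method, kpca=kpca_model)
                for fc, fb in zip(*feats[tag])])
                for tag in feats}
            head = fu.train_fusion_head(fused["train"],
                                        labels[split.train],
                                        head=cfg.get("head", "softmax"),
                                        seed=seed)
            scores = {"test": head.predict_hcc_scores(fused["test"]),
                      "val": head.predict_hcc_scores(fused["val"])}
        elif level == "decision":
            m_c = trained_branch(name, "ceus")
            m_b = trained_branch(name, "bmode")
            scores = {}
            for tag, ps in (("test", test_p), ("val", val_p)):
                p_c = bb.predict_probabilities(m_c, ps, "ceus")[:, 0]
                p_b = bb.predict_probabilities(m_b, ps, "bmode")[:, 0]
                scores[tag] = fu.fuse_decision_scores(p_c, p_b, method)
        else:
            raise ValueError(f"unknown experiment level {level!r}")

        row.update(_metrics_row(scores["test"], labels[split.test]))
        if len(val_p):
            val = _metrics_row(scores["val"], labels[split.validation])
            row.update({f"val_{k}": v for k, v in val.items()})
        rows.append(row)
        curves[f"{level}/{method}"] = roc_auc(scores["test"],
                                              labels[split.test])[0]

    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_grid_outputs(table, curves, out_dir)
    return table


def _fused_patch(patch, method):
    from .annotations import PairedPatch
    from .fusion import fuse_images
    fused = fuse_images(patch.bmode, patch.ceus, method)
    return PairedPatch(bmode=fused, ceus=fused, label=patch.label,
                       origin=patch.origin,
                       augmentation_tag=patch.augmentation_tag)


def _write_grid_outputs(table, curves, out_dir) -> None:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "results.csv", index=False)
    fig, ax = plt.subplots(figsize=(6, 5))
    for name, pts in curves.items():
        ax.plot(pts[:, 0], pts[:, 1], label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity (FPR)")
    ax.set_ylabel("sensitivity (TPR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "roc_overlay.png", dpi=120)
    plt.close(fig)
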