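"""Pixel-wise segmentation evaluation and PSNR.

Nine quantities compare a segmentation SG against a ground truth GT through
the confusion counts TP/FP/TN/FN:

    Acc = (TP+TN)/total          Se = TP/(TP+FN)        Sp = TN/(TN+FP)
    P   = TP/(TP+FP)             ER = (FP+FN)/total
    Vs  = 1 - |FN-FP| / (2TP+FP+FN)
    DSC = 2TP/(2TP+FP+FN) * 100%        JC = TP/(TP+FP+FN) * 100%

plus the area under the ROC curve of a soft score map, and PSNR in dB for
denoising assessment (peak 255, the nominal MR gray range).  Ratios that
degenerate to 0/0 are reported as 0 and flagged rather than raised.

Note the volumetric similarity uses the absolute difference |FN - FP| so
that Vs <= 1 always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METRIC_COLUMNS = ["Acc", "Se", "Sp", "P", "ER", "Vs", "DSC", "JC", "AUC", "PSNR"]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    Acc: float
    Se: float
    Sp: float
    P: float
    ER: float
    Vs: float
    DSC: float  # percent
    JC: float   # percent
    AUC: float | None = None
    PSNR: float | None = None
    degenerate: tuple = ()

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_COLUMNS}
        return {k: v for k, v in d.items() if v is not None}


def confusion(seg, gt) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    s = np.asarray(getattr(seg, "data", seg)).astype(bool)
    g = np.asarray(getattr(gt, "data", gt)).astype(bool)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {g.shape}")
    return ConfusionCounts(
        TP=int(np.sum(s & g)), FP=int(np.sum(s & ~g)),
        TN=int(np.sum(~s & ~g)), FN=int(np.sum(~s & g)),
    )


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """The eight count-based metrics; 0/0 ratios come back 0 and flagged."""
    if cc.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = cc.TP, cc.FP, cc.TN, cc.FN
    flags: list = []
    acc = (tp + tn) / cc.total
    er = (fp + fn) / cc.total
    se = _ratio(tp, tp + fn, "Se", flags)
    sp = _ratio(tn, tn + fp, "Sp", flags)
    p = _ratio(tp, tp + fp, "P", flags)
    denom = 2 * tp + fp + fn
    if denom == 0:
        flags.extend(["Vs", "DSC", "JC"])
        vs = dsc = jc = 0.0
    else:
        vs = 1.0 - abs(fn - fp) / denom
        dsc = 2 * tp / denom * 100.0
        jc = tp / (tp + fp + fn) * 100.0
    return MetricsReport(Acc=acc, Se=se, Sp=sp, P=p, ER=er, Vs=vs,
                         DSC=dsc, JC=jc, degenerate=tuple(flags))


def roc_auc(score_map, gt, n_thresholds: int = 256) -> float:
    """Trapezoidal area under the (FPR, TPR) curve over uniform thresholds.

    ``score_map`` is a real field in [0, 1]; the predicted mask at level t
    is ``score >= t``.  A constant score map yields 0.5 (chance) by
    convention.  Raises on a single-class ground truth.
    """
    s = np.asarray(getattr(score_map, "data", score_map), dtype=np.float64).ravel()
    g = np.asarray(getattr(gt, "data", gt)).astype(bool).ravel()
    if s.shape != g.shape:
        raise ValueError("score map and ground truth shapes differ")
    npos, nneg = int(g.sum()), int((~g).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("ground truth must contain both classes")
    if np.ptp(s) == 0:
        return 0.5
    # thresholds spanning [0, 1] plus a sentinel above the maximum so the
    # curve reaches (0, 0); t = 0 gives (1, 1)
    ts = np.concatenate([[np.inf], np.linspace(1.0, 0.0, int(n_thresholds))])
    tpr = np.empty(ts.size)
    fpr = np.empty(ts.size)
    for i, t in enumerate(ts):
        pred = s >= t
        tpr[i] = np.sum(pred & g) / npos
        fpr[i] = np.sum(pred & ~g) / nneg
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def psnr(reference, test, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE) in dB; inf at MSE=0."""
    a = np.asarray(getattr(reference, "data", reference), dtype=np.float64)
    b = np.asarray(getattr(test, "data", test), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def report_to_row(report: MetricsReport, case_id: str = "") -> dict:
    """One CSV/JSON row with the canonical column names."""
    row = {"case_id": case_id} if case_id else {}
    for k in METRIC_COLUMNS:
        v = getattr(report, k)
        row[k] = "" if v is None else v
    return row
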