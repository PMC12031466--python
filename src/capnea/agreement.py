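"""Model selection and device-agreement statistics.

ROC/AUC and the Youden operating point select the per-sample classifier and
its probability threshold θp; Pearson correlation, Bland–Altman limits of
agreement (mean difference ± 1.96 SD) and accuracy/sensitivity/specificity
at AHI cutoffs of 5, 15 and 30 events/h quantify night-level agreement
between the wearable's estimates and a reference device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocCurve",
    "BlandAltman",
    "DiagnosticReport",
    "roc_and_auc",
    "youden_threshold",
    "pearson_r",
    "bland_altman",
    "diagnostic_metrics",
    "select_model",
    "plot_correlation",
    "plot_bland_altman",
]


@dataclass
class RocCurve:
    """Threshold sweep with trapezoidal AUC (internal scale [0, 1])."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between two paired measurement series (differences a − b)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion counts and percent metrics at one AHI cutoff."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_and_auc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC sweep over unique scores, with trapezoidal AUC.

    Equal scores are grouped (one operating point per distinct score), so
    the curve and AUC match the pairwise-concordance (Mann–Whitney)
    statistic with the tie-splitting convention.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr,
                    auc=float(_sk_auc(fpr, tpr)))


def youden_threshold(roc: RocCurve) -> float:
    """θp maximizing Youden's J = TPR − FPR over the unique observed scores.

    Ties break toward the higher threshold (fewer positives).  The curve's
    sentinel point at (0, 0) — "no sample called apnea" — is not a usable
    operating threshold and is excluded from the argmax.
    """
    j = (roc.tpr - roc.fpr)[1:]  # drop the sentinel above all scores
    best = 1 + int(np.argmax(j))  # thresholds descend: first argmax = highest θ
    return float(roc.thresholds[best])


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two paired series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must be aligned")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(a, b).statistic)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Limits of agreement: mean difference ± 1.96 × sample SD (n−1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must be aligned")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(mean_diff=mean, sd_diff=sd,
                       loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                       n=a.size)


def diagnostic_metrics(ref_ahi: np.ndarray, est_ahi: np.ndarray,
                       cutoff: float) -> DiagnosticReport:
    """Accuracy/sensitivity/specificity at one AHI cutoff, in percent.

    A subject is positive iff AHI ≥ cutoff (closed on the left, matching the
    severity-band convention) on the respective device; the reference device
    defines ground truth.  Percentages are rounded to two decimals.
    """
    ref = np.asarray(ref_ahi, dtype=float)
    est = np.asarray(est_ahi, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("per-subject AHI lists must be aligned")
    rp, ep = ref >= cutoff, est >= cutoff
    tp = int(np.sum(rp & ep))
    fn = int(np.sum(rp & ~ep))
    tn = int(np.sum(~rp & ~ep))
    fp = int(np.sum(~rp & ep))
    n = ref.size
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return DiagnosticReport(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=round(100.0 * (tp + tn) / n, 2),
        sensitivity=round(sens, 2),
        specificity=round(spec, 2),
    )


def select_model(candidates: dict[str, tuple[np.ndarray, np.ndarray]]) -> tuple[str, dict[str, float]]:
    """Pick the candidate with the higher pooled validation AUC.

    ``candidates`` maps model name → (labels, scores) on pooled validation
    data.  Returns ``(chosen_name, {name: auc})``.  Exact AUC ties return
    the first candidate with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to select between")
    aucs = {name: roc_and_auc(lab, sc).auc for name, (lab, sc) in candidates.items()}
    best = max(aucs.values())
    winners = [name for name, a in aucs.items() if a == best]
    if len(winners) > 1:
        warnings.warn(f"AUC tie between {winners}; returning {winners[0]!r}")
    return winners[0], aucs


# ---------------------------------------------------------------------------
# Plots (correlation scatter with identity line; Bland–Altman with LOA lines)


def plot_correlation(a, b, labels: tuple[str, str] = ("reference", "estimate"), ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ax.scatter(a, b, s=24)
    lim = [min(a.min(), b.min()), max(a.max(), b.max())]
    ax.plot(lim, lim, linestyle=":", color="gray", label="identity")
    r = pearson_r(a, b)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.set_title(f"n = {a.size}, r = {r:.2f}")
    ax.legend()
    return ax


def plot_bland_altman(a, b, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b)
    mean_ab = (a + b) / 2.0
    ax.scatter(mean_ab, a - b, s=24)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, ":"), (ba.loa_high, ":")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of devices")
    ax.set_ylabel("difference")
    ax.set_title(
        f"mean diff {ba.mean_diff:.2f}, LOA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]"
    )
    return ax
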