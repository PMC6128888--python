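"""Epoch-by-epoch and parameter-level agreement statistics.

Confusion matrices and accuracy/kappa over the three macro stages (and their
sleep/wake collapse), Lin's concordance correlation for paired continuous
sleep parameters, and Bland–Altman bias/limits of agreement. Per-subject and
pooled aggregation are both supported and labeled explicitly; internal
computation is full precision, display rounding is one decimal for
percentages and three for kappa/CCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .staging import STAGES, stages_to_ints

SLEEP_WAKE = ("W", "S")


def confusion_matrix(ref, est) -> np.ndarray:
    """3×3 counts; rows = reference (PSG) W/R/N, columns = estimate."""
    r = stages_to_ints(ref)
    e = stages_to_ints(est)
    if r.shape != e.shape:
        raise ValueError("reference and estimate lengths differ")
    cm = np.zeros((3, 3), dtype=np.int64)
    np.add.at(cm, (r, e), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Percent agreement: 100 · trace / total."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(cm) / total)


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) from a count matrix.

    Expected agreement p_e comes from the row/column marginal products.
    Returns NaN when p_e == 1 (degenerate marginals make kappa undefined).
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total ** 2)
    if abs(1.0 - p_e) < 1e-15:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def collapse_sleep_wake(x):
    """Merge R and N into a single sleep class S.

    Accepts a hypnogram (returns labels in {W, S}) or a 3×3 count matrix
    (returns the additive 2×2 collapse, W first).
    """
    arr = np.asarray(x)
    if arr.ndim == 2 and arr.shape == (3, 3):
        cm = arr.astype(np.int64)
        out = np.zeros((2, 2), dtype=np.int64)
        out[0, 0] = cm[0, 0]
        out[0, 1] = cm[0, 1:].sum()
        out[1, 0] = cm[1:, 0].sum()
        out[1, 1] = cm[1:, 1:].sum()
        return out
    labels = np.asarray(x, dtype="<U1")
    stages_to_ints(labels)  # validates
    return np.where(labels == "W", "W", "S")


def per_class_rates(cm: np.ndarray, decimals: int | None = 1) -> np.ndarray:
    """Row-normalized percentages; rows with zero total are all-NaN."""
    cm = np.asarray(cm, dtype=np.float64)
    totals = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = 100.0 * cm / totals
    rates[np.asarray(totals == 0).reshape(-1)] = np.nan
    return np.round(rates, decimals) if decimals is not None else rates


def concordance_correlation(x, y) -> float:
    """Lin's CCC: 2·cov(x,y) / (var x + var y + (mean x − mean y)²)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0 and x.mean() == y.mean():
        raise ValueError("both series constant and equal: CCC undefined")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    lower_loa: float
    upper_loa: float
    sd_diff: float


def bland_altman(x, y) -> BlandAltman:
    """Bias = mean(y − x) and 95% limits of agreement bias ± 1.96·SD(y − x)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd)


@dataclass
class AgreementSummary:
    """Pooled + per-subject agreement for one estimation pass.

    ``aggregation`` records which numbers are which: pooled values come from
    the summed confusion matrix, per-subject values are means ± SD across
    subjects' individual accuracies/kappas.
    """

    pooled_matrix: np.ndarray
    pooled_accuracy_pct: float
    pooled_kappa: float
    per_subject_accuracy_mean: float
    per_subject_accuracy_sd: float
    per_subject_kappa_mean: float
    per_subject_kappa_sd: float
    pooled_accuracy_2class_pct: float
    pooled_kappa_2class: float
    n_subjects: int
    per_subject: list = None          # one {accuracy_pct, kappa} per subject
    aggregation: str = "pooled + per-subject mean±SD"

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pooled_matrix"] = self.pooled_matrix.tolist()
        return d


def summarize_agreement(pairs: list[tuple]) -> AgreementSummary:
    """Agreement over a list of (reference, estimate) hypnogram pairs."""
    if not pairs:
        raise ValueError("no subjects to evaluate")
    matrices = [confusion_matrix(r, e) for r, e in pairs]
    pooled = np.sum(matrices, axis=0)
    accs = np.array([accuracy(m) for m in matrices])
    kaps = np.array([cohens_kappa(m) for m in matrices])
    finite = np.isfinite(kaps)
    two = collapse_sleep_wake(pooled)
    return AgreementSummary(
        pooled_matrix=pooled,
        pooled_accuracy_pct=accuracy(pooled),
        pooled_kappa=cohens_kappa(pooled),
        per_subject_accuracy_mean=float(accs.mean()),
        per_subject_accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        per_subject_kappa_mean=float(kaps[finite].mean()) if finite.any()
        else float("nan"),
        per_subject_kappa_sd=float(kaps[finite].std(ddof=1))
        if finite.sum() > 1 else 0.0,
        pooled_accuracy_2class_pct=accuracy(two),
        pooled_kappa_2class=cohens_kappa(two),
        n_subjects=len(pairs),
        per_subject=[{"accuracy_pct": float(a), "kappa": float(k)}
                     for a, k in zip(accs, kaps)],
    )
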