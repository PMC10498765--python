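"""Diagnostic-performance statistics for paired FFR estimates.

The positive (diseased) class is reference FFR ≤ 0.8, the clinical
ischemia threshold; ties at exactly 0.8 are positive. Provided statistics:
the 2×2 cross-tabulation at the threshold, sensitivity / specificity /
PPV / NPV / accuracy, Bland–Altman limits of agreement (mean difference
± 1.96 sd), and ROC AUC as the Mann–Whitney pair probability (ties count
half), with an optional seeded bootstrap CI. Lesion-level and
patient-level (worst lesion per patient) aggregations are both supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError

ISCHEMIA_THRESHOLD = 0.8


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 counts; positive class = FFR ≤ threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages in [0, 100]; None marks a zero-denominator cell."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


@dataclass(frozen=True)
class BlandAltmanSummary:
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    n: int


def _paired(estimates, references) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise InputError(f"paired 1-D vectors required, got {est.shape} vs {ref.shape}")
    if est.size == 0:
        raise InputError("empty input")
    return est, ref


def confusion_at_threshold(estimates, references,
                           threshold: float = ISCHEMIA_THRESHOLD) -> ConfusionCounts:
    """Cross-tabulate estimate vs reference positivity at the threshold."""
    est, ref = _paired(estimates, references)
    est_pos = est <= threshold
    ref_pos = ref <= threshold
    return ConfusionCounts(
        tp=int(np.sum(est_pos & ref_pos)),
        fp=int(np.sum(est_pos & ~ref_pos)),
        fn=int(np.sum(~est_pos & ref_pos)),
        tn=int(np.sum(~est_pos & ~ref_pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy as percentages.

    A zero-denominator metric is reported as None (not available), never 0.
    """
    if counts.n == 0:
        raise InputError("empty confusion table")
    return DiagnosticMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.n),
    )


def bland_altman(estimates, references) -> BlandAltmanSummary:
    """Mean difference (estimate − reference) and 95% limits of agreement."""
    est, ref = _paired(estimates, references)
    if est.size < 2:
        raise InputError("Bland–Altman needs at least 2 pairs")
    d = est - ref
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanSummary(mean_difference=mean, sd_difference=sd,
                              lower_limit=mean - 1.96 * sd,
                              upper_limit=mean + 1.96 * sd, n=est.size)


def roc_auc(estimates, reference_binary) -> float:
    """AUC for detecting disease from the FFR estimate.

    Lower estimated FFR indicates disease, so scores are negated before
    ranking. AUC is the Mann–Whitney probability that a random diseased
    vessel scores above a random healthy one, ties counting 0.5, computed
    from the rank-sum statistic.
    """
    scores = -np.asarray(estimates, dtype=float)
    labels = np.asarray(reference_binary).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise InputError("paired 1-D score/label vectors required")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def roc_auc_ci(estimates, reference_binary, n_boot: int = 2000,
               seed: int = 0, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a seeded bootstrap percentile CI (resampling pairs)."""
    est = np.asarray(estimates, dtype=float)
    lab = np.asarray(reference_binary).astype(bool)
    point = roc_auc(est, lab)
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, est.size, est.size)
        if lab[idx].all() or not lab[idx].any():
            continue
        stats.append(roc_auc(est[idx], lab[idx]))
    lo, hi = np.quantile(stats, [(1 - level) / 2, (1 + level) / 2])
    return point, float(lo), float(hi)


def worst_per_patient(df: pd.DataFrame, value_columns: tuple[str, ...],
                      patient_column: str = "patient_id") -> pd.DataFrame:
    """Patient-level aggregation: the worst (minimum-FFR) lesion per patient.

    The row kept is the one minimising the first value column; an
    assumption flag is attached in ``DataFrame.attrs``.
    """
    idx = df.groupby(patient_column)[value_columns[0]].idxmin()
    out = df.loc[idx].reset_index(drop=True)
    out.attrs["aggregation"] = "worst-lesion-per-patient (assumption)"
    return out


def evaluate_pairs(estimates, references,
                   threshold: float = ISCHEMIA_THRESHOLD,
                   ci_seed: int | None = None) -> dict:
    """Full diagnostic report for one method against the reference."""
    est, ref = _paired(estimates, references)
    counts = confusion_at_threshold(est, ref, threshold)
    metrics = diagnostic_metrics(counts)
    ba = bland_altman(est, ref) if est.size >= 2 else None
    labels = ref <= threshold
    report = {
        "n": counts.n,
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "fn": counts.fn, "tn": counts.tn},
        "metrics": {k: getattr(metrics, k) for k in
                    ("sensitivity", "specificity", "ppv", "npv", "accuracy")},
    }
    if ba is not None:
        report["bland_altman"] = {
            "mean_difference": ba.mean_difference, "sd": ba.sd_difference,
            "limits": [ba.lower_limit, ba.upper_limit]}
    if labels.any() and not labels.all():
        if ci_seed is None:
            report["auc"] = roc_auc(est, labels)
        else:
            auc, lo, hi = roc_auc_ci(est, labels, seed=ci_seed)
            report["auc"] = auc
            report["auc_ci"] = [lo, hi]
    return report
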