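"""Confusion-matrix metrics, ROC/AUC with DeLong CIs, proportion CIs,
subgroup positive-rate reports, group tests and fragment-length profiling.

Percent values destined for tables are rounded half-up (integer percent for
sensitivity/specificity, two decimals for subgroup rates) so displayed values
match the usual clinical-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Half-up rounding on the decimal representation (0.5 -> 1,
    89.285 -> 89.29 at 2 digits), matching clinical-table display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    A zero denominator yields ``None`` (explicitly undefined), never 0.
    ``*_pct`` entries are integer percents rounded half-up for table display.
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_pct": int(round_half_up(100 * sens)) if sens is not None else None,
        "specificity_pct": int(round_half_up(100 * spec)) if spec is not None else None,
    }


def proportion_ci(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation interval p +/- 1.96*sqrt(p(1-p)/n), clipped to [0,1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> AucResult:
    """AUC via the rank statistic (Mann-Whitney with tie correction) and a 95%
    CI by the DeLong method.  Requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute AUC")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components: per-positive and per-negative placements.
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.96 * np.sqrt(var)
    return AucResult(
        auc=float(auc),
        ci_low=max(0.0, float(auc - half)),
        ci_high=min(1.0, float(auc + half)),
        n_pos=m,
        n_neg=n,
    )


def subgroup_positive_rates(
    predictions: Sequence[bool],
    subgroups: Sequence,
    subgroup_order: Sequence | None = None,
) -> pd.DataFrame:
    """Per-subgroup positives k, total n and percent (two decimals, half-up).

    Subgroups listed in ``subgroup_order`` but absent from the assignment are
    reported as 0/0 with an undefined (NaN) percent.
    """
    predictions = np.asarray(predictions, dtype=bool)
    subgroups = np.asarray(subgroups)
    if predictions.shape != subgroups.shape:
        raise ValueError("predictions and subgroup assignment must align")
    order = list(subgroup_order) if subgroup_order is not None else sorted(set(subgroups.tolist()))
    rows = []
    for grp in order:
        mask = subgroups == grp
        n = int(mask.sum())
        k = int(predictions[mask].sum())
        pct = round_half_up(100.0 * k / n, 2) if n else float("nan")
        rows.append({"subgroup": grp, "k": k, "n": n, "percent": pct})
    return pd.DataFrame(rows).set_index("subgroup")


def group_difference_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided equal-variance (Student's) two-sample t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
    return float(t_stat), float(p_val)


@dataclass(frozen=True)
class FragmentLengthProfile:
    bin_start: int
    counts: np.ndarray  # 1-bp bins starting at bin_start
    modal_length: int
    periodicity: float | None  # sub-peak spacing in bp, if detectable

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.bin_start, self.bin_start + len(self.counts))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def fragment_length_profile(
    lengths: Sequence[int],
    smooth_window: int = 5,
    periodicity_lags: tuple[int, int] = (5, 20),
) -> FragmentLengthProfile:
    """1-bp histogram, smoothed modal length, and the sub-peak spacing of the
    sub-modal region estimated by autocorrelation of the detrended counts."""
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        raise ValueError("fragment_length_profile requires at least one length")
    lo = int(lengths.min())
    counts = np.bincount(lengths - lo)
    smoothed = _moving_average(counts.astype(float), smooth_window)
    modal = lo + int(np.argmax(smoothed))
    periodicity = _submodal_periodicity(counts, modal - lo, periodicity_lags)
    return FragmentLengthProfile(
        bin_start=lo, counts=counts, modal_length=modal, periodicity=periodicity
    )


def _submodal_periodicity(
    counts: np.ndarray, mode_index: int, lags: tuple[int, int], min_autocorr: float = 0.25
) -> float | None:
    region = counts[:mode_index].astype(float)
    if region.size < lags[1] + 5:
        return None
    detrended = region - _moving_average(region, 11)
    full = np.correlate(detrended, detrended, mode="full")
    ac = full[region.size - 1 :]  # ac[k] = autocorrelation at lag k
    if ac[0] <= 0:
        return None
    lo, hi = lags
    hi = min(hi, ac.size - 1)
    if hi < lo:
        return None
    window = ac[lo : hi + 1] / ac[0]
    if window.max() < min_autocorr:  # no convincing sub-peak structure
        return None
    return float(lo + int(np.argmax(window)))
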