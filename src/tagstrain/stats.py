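"""Accuracy and agreement statistics.

Terminology follows the Bland-Altman convention: *bias* is the mean of the
paired differences and *precision* their sample standard deviation; the 95%
limits of agreement are bias +/- 1.96 * precision.  Group contrasts use
two-sided t tests (Student pooled-variance or Welch unequal-variance) with a
Bonferroni-adjusted significance threshold when several comparisons are made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import EvalReport, LandmarkGrid


def rms_position_error(pred: LandmarkGrid, truth: LandmarkGrid, t: int) -> float:
    """Root mean squared landmark position error (mm) at 1-based frame ``t``."""
    p, g = pred.frame(t), truth.frame(t)
    if p.shape != g.shape:
        raise ValueError("grids must have matching shapes")
    return float(np.sqrt(np.mean(((p - g) ** 2).sum(axis=-1))))


@dataclass
class BlandAltman:
    bias: float
    precision: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(a, b) -> BlandAltman:
    """Agreement between two paired measurement series.

    Differences are a - b; returns bias (mean), precision (sample SD, n-1
    denominator), 95% limits of agreement, and the (mean, difference) pairs
    for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    precision = float(d.std(ddof=1))
    return BlandAltman(bias, precision,
                       bias - 1.96 * precision, bias + 1.96 * precision,
                       (a + b) / 2.0, d)


def group_difference(values, labels, test: str = "welch",
                     alpha: float = 0.05):
    """Two-group mean difference with t test and confidence interval.

    ``labels`` holds exactly two distinct group labels; the difference is
    group0 - group1 in order of first appearance.  ``test`` selects the
    Student (pooled variance) or Welch (unequal variances,
    Welch-Satterthwaite degrees of freedom) flavor.

    Returns (mean_difference, (ci_low, ci_high), p_value).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(test == "student"))
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return (float(a.mean() - b.mean()),
            (float(ci.low), float(ci.high)),
            float(res.pvalue))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m for ``m`` tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def evaluate_slices(pred_es, truth_es, *, rms_ed=None, rms_es=None,
                    n_tests: int = 15, alpha: float = 0.05) -> EvalReport:
    """Summarize per-slice agreement of end-systolic strain estimates.

    ``pred_es`` / ``truth_es`` are per-slice values (e.g. midwall
    circumferential strain at ES).  RMS landmark errors at ED/ES may be
    supplied as per-slice arrays and are averaged.
    """
    ba = bland_altman(pred_es, truth_es)
    return EvalReport(
        bias=ba.bias,
        precision=ba.precision,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        rms_ed=float(np.mean(rms_ed)) if rms_ed is not None else None,
        rms_es=float(np.mean(rms_es)) if rms_es is not None else None,
        n=len(np.asarray(pred_es)),
        alpha_adjusted=bonferroni_threshold(alpha, n_tests),
    )
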