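"""High/low-risk dichotomization by log-rank-optimal cutpoint.

The threshold is chosen on the risk scores of the entire cohort by
maximizing the two-sample log-rank chi-square between the resulting
Kaplan-Meier curves, subject to a minimum group size (33% of the cohort
by default, matching the study design for lower-grade glioma where small
extreme-risk groups would be clinically uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank


def logrank_test(time, event, group):
    """Two-sample log-rank test; returns (chi-square statistic, p-value).

    ``group`` is a binary label per subject.  With no observed events the
    statistic is 0 by convention (no information against the null).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group).astype(bool)
    if not group.any() or group.all():
        raise ValueError("logrank_test: both groups must be nonempty")
    if event.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(time[group], time[~group], event[group], event[~group])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class Cutpoint:
    threshold: float
    high_risk: np.ndarray  # boolean labels, True = high risk (score > threshold)
    chi_square: float
    p_value: float


def find_cutpoint(risks, time, event, min_frac: float = 0.33) -> Cutpoint:
    """Log-rank-maximizing risk threshold with a minimum group size.

    Candidate thresholds are midpoints between consecutive sorted unique
    risk scores; candidates leaving either group smaller than
    ``ceil(min_frac * n)`` are discarded; among the rest the one with the
    largest log-rank chi-square wins, ties going to the smaller threshold.
    High risk = scores strictly above the threshold.
    """
    risks = np.asarray(risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not 0 < min_frac < 0.5:
        raise ValueError("min_frac must be in (0, 0.5)")
    uniq = np.unique(risks)
    if uniq.size < 2:
        raise ValueError("find_cutpoint: fewer than 2 distinct risk values")
    n = risks.size
    min_size = int(np.ceil(min_frac * n))
    best = None
    for thr in (uniq[:-1] + uniq[1:]) / 2:
        high = risks > thr
        if high.sum() < min_size or (~high).sum() < min_size:
            continue
        chi2, p = logrank_test(time, event, high)
        if best is None or chi2 > best.chi_square:
            best = Cutpoint(float(thr), high, chi2, p)
    if best is None:
        raise ValueError(
            "find_cutpoint: no admissible threshold satisfies the minimum "
            f"group size of {min_size}"
        )
    return best
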