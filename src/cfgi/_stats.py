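"""Vectorized two-group log-rank machinery shared by hot loops.

The gene-ranking and cutpoint scans evaluate thousands of two-group
log-rank tests per cohort; this module provides a numpy implementation
(cross-checked against lifelines in the test suite) plus the precomputed
risk-set structure that lets a whole scan of candidate dichotomizations
reuse one at-risk matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class RiskSets:
    """Risk-set structure for repeated two-group log-rank tests.

    Precomputes, for the distinct event times t_1 < ... < t_D:
    the at-risk indicator matrix (subjects x times) and the per-subject
    event-at-time matrix, so that group-wise d_i and n_i are matrix-vector
    products with the group mask.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(bool)
        if times.ndim != 1 or len(times) != len(events):
            raise ValueError("times and events must be 1-d and equal length")
        self.times = times
        self.events = events
        self.event_times = np.unique(times[events])
        self.d_total = (
            (times[:, None] == self.event_times[None, :]) & events[:, None]
        ).astype(float)  # subjects x D, 1 if subject has an event at t_j
        self.at_risk = (times[:, None] >= self.event_times[None, :]).astype(float)
        self.d_all = self.d_total.sum(axis=0)  # events at each distinct time
        self.n_all = self.at_risk.sum(axis=0)  # at risk at each distinct time

    @property
    def n_event_times(self) -> int:
        return len(self.event_times)

    def score(self, mask: np.ndarray) -> float:
        """Log-rank score statistic (observed - expected events in group 1)."""
        m = np.asarray(mask, dtype=float)
        d1 = m @ self.d_total
        n1 = m @ self.at_risk
        return float((d1 - self.d_all * n1 / self.n_all).sum())

    def statistic(self, mask: np.ndarray) -> tuple[float, float]:
        """Log-rank chi-square (1 df) and p-value for a two-group split."""
        m = np.asarray(mask, dtype=float)
        d1 = m @ self.d_total
        n1 = m @ self.at_risk
        expected = self.d_all * n1 / self.n_all
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (
                self.d_all
                * (n1 / self.n_all)
                * (1 - n1 / self.n_all)
                * (self.n_all - self.d_all)
                / np.maximum(self.n_all - 1, 1)
            )
        score = (d1 - expected).sum()
        v = var.sum()
        if v <= 0:
            return 0.0, 1.0
        chi2 = score * score / v
        return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_p(times, events, mask) -> float:
    """Two-group log-rank p-value; 1.0 when a group is empty or eventless."""
    mask = np.asarray(mask).astype(bool)
    if mask.all() or not mask.any():
        return 1.0
    return RiskSets(times, events).statistic(mask)[1]
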