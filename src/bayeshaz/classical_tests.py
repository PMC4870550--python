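"""Classical two-sample tests for equality of hazard functions.

Implements the log rank test, the Fleming-Harrington weighted log rank
tests with weights ``S(t-)`` (early differences) and ``1 - S(t-)``
(late differences) based on the pooled Kaplan-Meier estimate, and Renyi
(supremum) versions of the weighted statistics, which retain power when
the hazard ratio changes sign over time.

All statistics are built from the standard 2x2 table at each distinct
event time t: with ``d`` pooled deaths, ``d1`` group-1 deaths, ``Y``
subjects at risk and ``Y1`` of them in group 1, the increment is
``d1 - d Y1/Y`` with hypergeometric variance
``d (Y1/Y)(1 - Y1/Y)(Y - d)/(Y - 1)``.  Weights are evaluated at the
left limit S(t-) of the pooled Kaplan-Meier estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survival_data import SurvivalDataset

__all__ = [
    "TwoSampleTestResult",
    "log_rank",
    "weighted_log_rank",
    "renyi_test",
]


@dataclass(frozen=True)
class TwoSampleTestResult:
    statistic: float
    p_value: float
    weight_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _event_table(ds: SurvivalDataset):
    """Pooled per-event-time counts and left-limit KM weights.

    Returns distinct event times with (d, d1, Y, Y1, S_left) arrays.
    """
    if not ds.has_both_groups():
        raise ValueError("two-sample test requires subjects in both groups")
    if ds.n_events == 0:
        raise ValueError("no events: test undefined")
    ev_times = np.unique(ds.time[ds.event == 1])
    time, event, group = ds.time, ds.event, ds.group
    d = np.empty(ev_times.size)
    d1 = np.empty(ev_times.size)
    Y = np.empty(ev_times.size)
    Y1 = np.empty(ev_times.size)
    sorted_all = np.sort(time)
    sorted_g1 = np.sort(time[group == 1])
    for k, t in enumerate(ev_times):
        at = (time == t) & (event == 1)
        d[k] = at.sum()
        d1[k] = (at & (group == 1)).sum()
        Y[k] = time.size - np.searchsorted(sorted_all, t, side="left")
        Y1[k] = sorted_g1.size - np.searchsorted(sorted_g1, t, side="left")
    # pooled KM just before each event time: cumulative product of earlier factors
    factors = 1.0 - d / Y
    s_left = np.concatenate(([1.0], np.cumprod(factors)[:-1]))
    return ev_times, d, d1, Y, Y1, s_left


def _increments(d, d1, Y, Y1):
    obs_minus_exp = d1 - d * Y1 / Y
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (Y1 / Y) * (1.0 - Y1 / Y) * (Y - d) / (Y - 1.0)
    var = np.where(Y > 1, var, 0.0)
    return obs_minus_exp, var


def _weights(weight: str, s_left: np.ndarray) -> np.ndarray:
    if weight in ("unit", "1"):
        return np.ones_like(s_left)
    if weight in ("km", "early", "fh1"):
        return s_left
    if weight in ("one-minus-km", "late", "fh2"):
        return 1.0 - s_left
    raise ValueError(f"unknown weight {weight!r}")


def weighted_log_rank(ds: SurvivalDataset, weight: str = "unit") -> TwoSampleTestResult:
    """Weighted log rank test with chi-square(1) reference distribution.

    ``weight``: ``'unit'`` (ordinary log rank), ``'km'`` (pooled
    Kaplan-Meier left limit, emphasises early differences) or
    ``'one-minus-km'`` (emphasises late differences).
    """
    _, d, d1, Y, Y1, s_left = _event_table(ds)
    w = _weights(weight, s_left)
    ome, var = _increments(d, d1, Y, Y1)
    U = float((w * ome).sum())
    V = float((w**2 * var).sum())
    if V == 0.0:
        return TwoSampleTestResult(0.0, 1.0, weight)
    stat = U**2 / V
    return TwoSampleTestResult(stat, float(stats.chi2.sf(stat, df=1)), weight)


def log_rank(ds: SurvivalDataset) -> TwoSampleTestResult:
    """Ordinary (unweighted) log rank test."""
    return weighted_log_rank(ds, weight="unit")


def _sup_brownian_pvalue(q: float, tol: float = 1e-12) -> float:
    """P(sup_{0<=u<=1} |B(u)| >= q) for standard Brownian motion B.

    Uses the reflection series 4 sum_k (-1)^k Phibar((2k+1) q) for
    moderate-to-large q and the dual theta series
    1 - (4/pi) sum_k ((-1)^k/(2k+1)) exp(-(2k+1)^2 pi^2 / (8 q^2))
    for small q, where each converges fastest.
    """
    if q <= 0:
        return 1.0
    if q >= 1.0:
        total, k = 0.0, 0
        while True:
            term = 4.0 * stats.norm.sf((2 * k + 1) * q)
            total += (-1) ** k * term
            if term < tol or k > 1000:
                break
            k += 1
        return float(min(1.0, max(0.0, total)))
    total, k = 0.0, 0
    while True:
        term = (4.0 / np.pi) / (2 * k + 1) * np.exp(
            -((2 * k + 1) ** 2) * np.pi**2 / (8.0 * q**2)
        )
        total += (-1) ** k * term
        if term < tol or k > 1000:
            break
        k += 1
    return float(min(1.0, max(0.0, 1.0 - total)))


def renyi_test(ds: SurvivalDataset, weight: str = "early") -> TwoSampleTestResult:
    """Renyi supremum version of the weighted log rank test.

    The statistic is ``max_k |Z_k| / sqrt(V_total)`` where ``Z_k`` are
    the running partial sums of the weighted observed-minus-expected
    increments; the p-value comes from the boundary-crossing law of the
    supremum of |Brownian motion| on [0, 1].  ``weight='early'`` uses the
    pooled-KM left limit, ``'late'`` its complement.
    """
    _, d, d1, Y, Y1, s_left = _event_table(ds)
    w = _weights(weight, s_left)
    ome, var = _increments(d, d1, Y, Y1)
    partial = np.cumsum(w * ome)
    V = float((w**2 * var).sum())
    if V == 0.0:
        return TwoSampleTestResult(0.0, 1.0, weight)
    stat = float(np.max(np.abs(partial)) / np.sqrt(V))
    return TwoSampleTestResult(stat, _sup_brownian_pvalue(stat), weight)
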