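"""B-spline basis system for the time-varying log hazard ratio.

The coefficient function beta(t) is expanded as a linear combination of
``a_n`` B-spline basis functions of degree ``d`` with equally spaced
interior knots on a data-driven interval: the interior knots live on
``[l_n + eps, u_n - eps]`` where ``l_n`` is the larger of the two
group-wise minimum event times and ``u_n`` the smaller of the group-wise
maximum event times.  Outside that interval the two-sample comparison
carries no information about beta, so evaluation clamps t to the support
(beta is continued as a constant), which keeps risk-set sums well defined
at every event time and preserves the partition of unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .survival_data import SurvivalDataset

__all__ = [
    "KnotInterval",
    "SmoothnessClass",
    "SplineBasis",
    "knot_interval",
    "default_n_basis",
    "build_basis",
    "evaluate_basis",
]

#: degree and basis count used by default throughout the package
DEFAULT_DEGREE = 2
DEFAULT_N_BASIS = 5


@dataclass(frozen=True)
class KnotInterval:
    """Support ``[lo, hi] = [l_n + eps, u_n - eps]`` of the spline basis."""

    lo: float
    hi: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"degenerate knot interval [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class SmoothnessClass:
    """Smoothness assumption on beta: p-th derivative bounded by M.

    Informational; ``p`` enters only through :func:`default_n_basis`.
    """

    p: int = 2
    M: float = 10.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("derivative order p must be >= 1")
        if self.M <= 0:
            raise ValueError("bound M must be positive")


@dataclass(frozen=True)
class SplineBasis:
    """Open-uniform B-spline basis of ``n_basis`` functions.

    The knot vector repeats each endpoint ``degree + 1`` times and places
    ``n_basis - degree - 1`` equally spaced interior knots, so that
    ``len(knots) - degree - 1 == n_basis``.  The basis is nonnegative,
    locally supported and sums to one everywhere on ``[lo, hi]``.
    """

    degree: int
    n_basis: int
    knots: np.ndarray
    lo: float
    hi: float

    def __call__(self, t):
        return evaluate_basis(self, t)


def knot_interval(ds: SurvivalDataset, epsilon: float | None = None) -> KnotInterval:
    """Data-driven spline support from the group-wise event-time ranges.

    ``lo = max_g min{X_i : delta_i=1, z_i=g} + eps`` and
    ``hi = min_g max{X_i : delta_i=1, z_i=g} - eps``.  By default
    ``eps = 1e-6 (u_n - l_n)`` (any very small positive value works).
    Each group must contribute at least one event.
    """
    mins, maxs = [], []
    for g in (0, 1):
        ev = ds.event_times(g)
        if ev.size == 0:
            raise ValueError(
                f"group {g} has no uncensored events; the knot interval is undefined"
            )
        mins.append(ev.min())
        maxs.append(ev.max())
    l_n = max(mins)
    u_n = min(maxs)
    if l_n >= u_n:
        raise ValueError(
            f"event-time ranges barely overlap (l_n={l_n}, u_n={u_n}); "
            "too few events to place knots"
        )
    if epsilon is None:
        epsilon = 1e-6 * (u_n - l_n)
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    lo, hi = l_n + epsilon, u_n - epsilon
    if lo >= hi:
        raise ValueError(f"epsilon={epsilon} collapses the knot interval")
    return KnotInterval(lo, hi, epsilon)


def default_n_basis(n: int, p: int) -> int:
    """Rate-driven basis count ``floor((n / log n)^(1/(2p+1)))``, at least 1.

    This growth rate balances approximation and estimation error for
    coefficient functions with p bounded derivatives.  The package
    default is the fixed ``n_basis = 5`` instead; this rule is provided
    for users who want the sample-size-adaptive choice.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if p < 1:
        raise ValueError("p must be >= 1")
    return max(1, math.floor((n / math.log(n)) ** (1.0 / (2 * p + 1))))


def build_basis(
    interval: KnotInterval | tuple[float, float],
    degree: int = DEFAULT_DEGREE,
    n_basis: int = DEFAULT_N_BASIS,
) -> SplineBasis:
    """Construct the open-uniform basis on a knot interval."""
    if isinstance(interval, tuple):
        interval = KnotInterval(*interval)
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    if n_basis < degree + 1:
        raise ValueError(
            f"n_basis={n_basis} must be at least degree+1={degree + 1}"
        )
    n_interior = n_basis - degree - 1
    interior = np.linspace(interval.lo, interval.hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        (
            np.repeat(interval.lo, degree + 1),
            interior,
            np.repeat(interval.hi, degree + 1),
        )
    )
    return SplineBasis(
        degree=degree, n_basis=n_basis, knots=knots, lo=interval.lo, hi=interval.hi
    )


def evaluate_basis(basis: SplineBasis, t) -> np.ndarray:
    """Evaluate all basis functions at ``t`` (scalar or array).

    Times outside ``[lo, hi]`` are clamped to the nearest endpoint, so a
    spline expansion is continued as a constant outside its support.
    Returns shape ``(n_basis,)`` for a scalar, ``(len(t), n_basis)`` for
    an array; rows are nonnegative and sum to 1.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if tt.size == 0:
        return np.empty((0, basis.n_basis))
    tt = np.clip(tt, basis.lo, basis.hi)
    dm = BSpline.design_matrix(tt, basis.knots, basis.degree).toarray()
    return dm[0] if scalar else dm
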