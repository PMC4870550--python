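"""Two-group survival data generator with calibrated censoring.

Failure times follow a Cox model with baseline hazard ``lambda0`` and a
group-1 hazard ratio ``exp(beta(t))``; five named scenarios cover the
standard shapes used in the power study:

========  ==========================  ===========================
name      exp(beta(t))                character
========  ==========================  ===========================
``M0``    1                           equivalent hazards (null)
``M1``    2                           proportional hazards
``M2``    1 if t<0.7 else exp(-1.2)   step (change-point) ratio
``M3``    0.1 + 0.5 t                 crossing hazards
``M4``    3.0 + 1.5 t                 diverging hazards
========  ==========================  ===========================

The baseline rate is ``lambda0 = 0.25`` on the horizon ``tau = 6``,
except for the change-point scenario M2, which defaults to
``lambda0 = 0.5``: with the slower baseline, subjects surviving past
tau alone would censor 39% of the sample, so a 30% censoring target
would be unattainable.
Censoring is ``C = min(E, tau)`` with ``E ~ Exponential(theta)``: a
truncated exponential on [0, tau) plus an atom at tau (administrative
end of study), so the censoring distribution G satisfies G(tau) = 1.
The rate theta is calibrated numerically so the expected censored
fraction P(T > C) hits a requested target; a target of 0 disables the
exponential component entirely (C == tau, only subjects surviving past
tau are censored).

Failure times are drawn by inverting the cumulative hazard,
``T = Lambda_z^{-1}(-log U)``; the named scenarios invert in closed
form (linear / piecewise-linear / quadratic), custom hazard ratios fall
back to adaptive quadrature plus bracketed root finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .survival_data import SurvivalDataset

__all__ = [
    "HazardScenario",
    "cumulative_hazard",
    "sample_failure_time",
    "calibrate_censoring",
    "sample_dataset",
    "MODEL_NAMES",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("M0", "M1", "M2", "M3", "M4")

_STEP_T = 0.7          # M2 change point
_STEP_RATIO = np.exp(-1.2)


def _hr_m0(t):
    return np.ones_like(np.asarray(t, dtype=float))


def _hr_m1(t):
    return np.full_like(np.asarray(t, dtype=float), 2.0)


def _hr_m2(t):
    t = np.asarray(t, dtype=float)
    return np.where(t < _STEP_T, 1.0, _STEP_RATIO)


def _hr_m3(t):
    return 0.1 + 0.5 * np.asarray(t, dtype=float)


def _hr_m4(t):
    return 3.0 + 1.5 * np.asarray(t, dtype=float)


_NAMED_HR: dict[str, Callable] = {
    "M0": _hr_m0,
    "M1": _hr_m1,
    "M2": _hr_m2,
    "M3": _hr_m3,
    "M4": _hr_m4,
}


@dataclass
class HazardScenario:
    """A named data-generating model for the two-group comparison.

    ``hazard_ratio`` maps t to exp(beta(t)) and applies to group 1 only;
    group 0 always has hazard ``lambda0``.  For ``name='custom'`` supply
    ``hazard_ratio`` explicitly.
    """

    name: str = "M0"
    baseline_rate: float | None = None
    tau: float = 6.0
    censor_rate_target: float = 0.3
    hazard_ratio: Callable | None = field(default=None)

    def __post_init__(self) -> None:
        if self.baseline_rate is None:
            # M2 needs a faster baseline than the other scenarios: at 0.25
            # administrative censoring alone exceeds a 30% censoring target
            self.baseline_rate = 0.5 if self.name == "M2" else 0.25
        if self.name in _NAMED_HR:
            if self.hazard_ratio is None:
                self.hazard_ratio = _NAMED_HR[self.name]
        elif self.name == "custom":
            if self.hazard_ratio is None:
                raise ValueError("custom scenario requires a hazard_ratio function")
        else:
            raise ValueError(f"unknown scenario {self.name!r}; use {MODEL_NAMES} or 'custom'")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must be in [0, 1)")

    # -- closed-form cumulative hazards for group 1 ----------------------
    def _cumhaz1(self, t: np.ndarray) -> np.ndarray:
        lam = self.baseline_rate
        if self.name == "M0":
            return lam * t
        if self.name == "M1":
            return 2.0 * lam * t
        if self.name == "M2":
            return lam * np.where(
                t < _STEP_T, t, _STEP_T + _STEP_RATIO * (t - _STEP_T)
            )
        if self.name == "M3":
            return lam * (0.1 * t + 0.25 * t**2)
        if self.name == "M4":
            return lam * (3.0 * t + 0.75 * t**2)
        # custom: adaptive quadrature of exp(beta(s)) lambda0
        out = np.empty_like(t)
        for i, ti in np.ndenumerate(t):
            out[i] = lam * quad(self.hazard_ratio, 0.0, ti, epsabs=1e-10, limit=200)[0]
        return out

    def _inv_cumhaz1(self, u: np.ndarray) -> np.ndarray:
        """Solve Lambda_1(T) = u for T >= 0."""
        lam = self.baseline_rate
        v = u / lam
        if self.name == "M0":
            return v
        if self.name == "M1":
            return v / 2.0
        if self.name == "M2":
            return np.where(v < _STEP_T, v, _STEP_T + (v - _STEP_T) / _STEP_RATIO)
        if self.name == "M3":
            # 0.25 T^2 + 0.1 T - v = 0
            return (-0.1 + np.sqrt(0.01 + v)) / 0.5
        if self.name == "M4":
            # 0.75 T^2 + 3 T - v = 0
            return (-3.0 + np.sqrt(9.0 + 3.0 * v)) / 1.5
        out = np.empty_like(u)
        for i, ui in np.ndenumerate(u):
            out[i] = self._inv_numeric(ui)
        return out

    def _inv_numeric(self, u: float, tol: float = 1e-10) -> float:
        if u <= 0:
            return 0.0
        hi = max(self.tau, 1.0)
        while self._cumhaz1(np.array([hi]))[0] < u:
            hi *= 2.0
            if hi > 1e8:
                raise RuntimeError("cumulative hazard does not reach the target")
        return brentq(
            lambda t: self._cumhaz1(np.array([t]))[0] - u, 0.0, hi, xtol=tol
        )

    def survival(self, group: int, t) -> np.ndarray:
        """Closed-form S_z(t) = exp(-Lambda_z(t))."""
        return np.exp(-cumulative_hazard(self, group, t))


def cumulative_hazard(scn: HazardScenario, group: int, t) -> np.ndarray | float:
    """Cumulative hazard Lambda_z(t) of the scenario for one group."""
    scalar = np.isscalar(t) or np.ndim(t) == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("t must be nonnegative")
    if group == 0:
        out = scn.baseline_rate * tt
    else:
        out = scn._cumhaz1(tt)
    return float(out[0]) if scalar else out


def sample_failure_time(
    scn: HazardScenario, group: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Inverse-transform draw(s) of the latent failure time T."""
    u = -np.log(rng.random(size if size is not None else 1))
    if group == 0:
        t = u / scn.baseline_rate
    else:
        t = scn._inv_cumhaz1(u)
    return float(t[0]) if size is None else t


def _expected_censored_fraction(scn: HazardScenario, theta: float) -> float:
    """P(T > C) for C = min(Exp(theta), tau), T mixed 50/50 over groups."""

    def pooled_survival(c):
        return 0.5 * (scn.survival(0, c) + scn.survival(1, c))

    tau = scn.tau
    admin = float(pooled_survival(tau)) * np.exp(-theta * tau)
    if theta == 0:
        return float(pooled_survival(tau))
    integral = quad(
        lambda c: float(pooled_survival(c)) * theta * np.exp(-theta * c),
        0.0,
        tau,
        epsabs=1e-10,
        limit=200,
    )[0]
    return integral + admin


def calibrate_censoring(scn: HazardScenario) -> float:
    """Exponential rate theta hitting the scenario's censoring target.

    Returns 0.0 when the target is 0 (exponential component disabled;
    only administrative censoring at tau remains).  The achievable range
    is [P(T > tau), 1); targets below the administrative floor raise.
    """
    target = scn.censor_rate_target
    if target == 0.0:
        return 0.0
    floor = _expected_censored_fraction(scn, 0.0)
    if target <= floor:
        raise ValueError(
            f"censoring target {target} is unachievable: administrative "
            f"censoring at tau={scn.tau} already censors a fraction "
            f"{floor:.4f}; achievable targets lie in ({floor:.4f}, 1)"
        )
    lo, hi = 1e-8, 1.0
    while _expected_censored_fraction(scn, hi) < target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket the censoring rate")
    return float(
        brentq(lambda th: _expected_censored_fraction(scn, th) - target, lo, hi, xtol=1e-6)
    )


def sample_dataset(
    scn: HazardScenario,
    n: int,
    rng: np.random.Generator | int,
    theta: float | None = None,
) -> SurvivalDataset:
    """Simulate a balanced two-group dataset of size n from the scenario.

    ``X = min(T, C)``, ``delta = I(T <= C)``; all observed times are
    bounded by tau.  Pass a precalibrated ``theta`` to skip the (cached
    elsewhere) calibration step.  Odd n puts the extra subject in
    group 0.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if theta is None:
        theta = calibrate_censoring(scn)
    n0 = (n + 1) // 2
    n1 = n // 2
    if n % 2:
        logger.info("odd n=%d: using group sizes %d/%d", n, n0, n1)
    t_fail = np.concatenate(
        (
            sample_failure_time(scn, 0, rng, size=n0),
            sample_failure_time(scn, 1, rng, size=n1),
        )
    )
    group = np.concatenate((np.zeros(n0, dtype=int), np.ones(n1, dtype=int)))
    if theta > 0:
        cens = np.minimum(rng.exponential(1.0 / theta, size=n), scn.tau)
    else:
        cens = np.full(n, scn.tau)
    time = np.minimum(t_fail, cens)
    event = (t_fail <= cens).astype(int)
    return SurvivalDataset(time=time, event=event, group=group, tau=scn.tau)
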