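"""Two-group right-censored survival data.

Containers, delimited-text I/O, risk-set machinery and Kaplan-Meier
estimation for datasets of the form ``(X_i, delta_i, z_i)`` where
``X_i = min(T_i, C_i)`` is the observed time, ``delta_i = I(T_i <= C_i)``
the event indicator and ``z_i`` a binary group label (0 = control,
1 = treatment).  All observed times are bounded by the study horizon
``tau``.

Tie policy
----------
Failure-time models here assume continuous event times, so ties have
probability zero in simulated data.  For imported real data the canonical
sort orders events before censorings at equal times, and tied event times
are handled downstream with the Breslow convention (shared risk set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "Observation",
    "SurvivalDataset",
    "StepFunction",
    "read_dataset",
    "write_dataset",
    "risk_set",
    "kaplan_meier",
]


class DataValidationError(ValueError):
    """Raised when survival records violate the data model."""


@dataclass(frozen=True)
class Observation:
    """A single right-censored record ``(X_i, delta_i, z_i)``."""

    time: float
    event: int
    group: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataValidationError(f"negative time {self.time}")
        if self.event not in (0, 1):
            raise DataValidationError(f"event must be 0/1, got {self.event}")
        if self.group not in (0, 1):
            raise DataValidationError(f"group must be 0/1, got {self.group}")


@dataclass
class SurvivalDataset:
    """Validated, canonically sorted two-group right-censored sample.

    Parameters
    ----------
    time, event, group
        Equal-length 1-D arrays.  ``event`` and ``group`` must be binary.
    tau
        Study horizon; every observed time must satisfy ``time <= tau``.
        Defaults to 6 time units, the horizon used throughout the
        bundled simulation scenarios.

    The constructor sorts records by time, events before censorings at
    ties (stable, hence deterministic for a fixed input).
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray
    tau: float = 6.0
    _sorted: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.group = np.asarray(self.group)
        if not (self.time.shape == self.event.shape == self.group.shape):
            raise DataValidationError("time/event/group must have equal length")
        if self.time.ndim != 1:
            raise DataValidationError("expected 1-D arrays")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise DataValidationError("times must be finite and nonnegative")
        for name, arr in (("event", self.event), ("group", self.group)):
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise DataValidationError(f"{name} must be binary 0/1, got values {vals}")
        self.event = self.event.astype(np.int8)
        self.group = self.group.astype(np.int8)
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise DataValidationError(f"tau must be positive, got {self.tau}")
        if np.any(self.time > self.tau):
            raise DataValidationError(
                f"observed times exceed the study horizon tau={self.tau}"
            )
        # canonical order: time ascending, events before censorings at ties
        order = np.lexsort((-self.event, self.time))
        self.time = self.time[order]
        self.event = self.event[order]
        self.group = self.group[order]
        self._sorted = True

    def __len__(self) -> int:
        return self.time.size

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(float(t), int(e), int(g))
            for t, e, g in zip(self.time, self.event, self.group)
        ]

    def group_mask(self, g: int) -> np.ndarray:
        return self.group == g

    def event_times(self, g: int | None = None) -> np.ndarray:
        """Uncensored times, optionally restricted to one group."""
        mask = self.event == 1
        if g is not None:
            mask &= self.group == g
        return self.time[mask]

    def has_both_groups(self) -> bool:
        return bool((self.group == 0).any() and (self.group == 1).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event, "group": self.group}
        )


class StepFunction:
    """Right-continuous step function with a left-limit accessor."""

    def __init__(self, x: np.ndarray, y: np.ndarray, y0: float = 1.0):
        # x strictly increasing jump locations; y value on [x_k, x_{k+1})
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.y0 = float(y0)

    def __call__(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([self.y0], self.y))
        return vals[idx]

    def left_limit(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate(([self.y0], self.y))
        return vals[idx]


def read_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
    tau: float = 6.0,
    sep: str | None = None,
) -> SurvivalDataset:
    """Read a delimited table into a :class:`SurvivalDataset`.

    The file must contain a header with the three configured column names;
    the delimiter is sniffed unless ``sep`` is given.  Records violating
    the data model (negative times, non-binary flags, times above ``tau``)
    raise :class:`DataValidationError`.
    """
    if sep is None:
        df = pd.read_csv(path, sep=sep, engine="python")
    else:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in (time_col, event_col, group_col) if c not in df.columns]
    if missing:
        raise KeyError(f"missing column(s) {missing}; found {list(df.columns)}")
    return SurvivalDataset(
        time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(),
        group=df[group_col].to_numpy(),
        tau=tau,
    )


def write_dataset(
    ds: SurvivalDataset,
    path,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
    sep: str = ",",
) -> None:
    """Write the dataset as a delimited table with a header row."""
    df = ds.to_frame().rename(
        columns={"time": time_col, "event": event_col, "group": group_col}
    )
    # %.17g keeps float64 times exact across a write/read cycle
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def risk_set(ds: SurvivalDataset, t: float) -> np.ndarray:
    """Indices (1-based, canonical order) of subjects at risk at ``t``.

    The risk set is ``R(t) = {k : X_k >= t}``: subjects still under
    observation just before time ``t``, including any censored exactly
    at ``t``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    return np.flatnonzero(ds.time >= t) + 1


def kaplan_meier(ds: SurvivalDataset, pooled: bool = True):
    """Product-limit estimate of the survival function.

    With ``pooled=True`` returns a single :class:`StepFunction` for the
    combined sample; otherwise a dict ``{0: S0, 1: S1}`` of per-group
    estimators.  The estimate is right-continuous, starts at 1 and drops
    only at uncensored times; after the last event it carries its last
    value (no drop at censored-only tails).  A sample with zero events
    yields the constant-1 function with a warning.
    """
    if pooled:
        return _km_one(ds.time, ds.event)
    return {
        0: _km_one(ds.time[ds.group == 0], ds.event[ds.group == 0]),
        1: _km_one(ds.time[ds.group == 1], ds.event[ds.group == 1]),
    }


def _km_one(time: np.ndarray, event: np.ndarray) -> StepFunction:
    if time.size == 0:
        raise ValueError("empty sample")
    if event.sum() == 0:
        warnings.warn("no events: Kaplan-Meier estimate is constant 1")
        return StepFunction(np.array([]), np.array([]), y0=1.0)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    x = sf.index.to_numpy(dtype=float)
    y = sf.iloc[:, 0].to_numpy(dtype=float)
    # keep only genuine drops (event times); the estimate is flat elsewhere
    keep = np.concatenate(([False], np.diff(y) < 0)) if x.size else np.array([])
    return StepFunction(x[keep], y[keep], y0=1.0)
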