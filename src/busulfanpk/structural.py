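"""Structural concentration-time model.

One-compartment disposition with zero-order (infusion) input and first-order
elimination, superposed over all past infusions of a twice-daily schedule.
The elimination rate constant is not constant over therapy: it moves
exponentially from its baseline value ``k`` at the first infusion towards
``k * (1 + d_k)`` with rate ``kappa_k``,

    k*(t) = k * (1 + d_k * (1 - exp(-kappa_k * t))).

Within one dosing interval the model uses a single effective rate constant
``k'``: the time-average of ``k*`` from the start of therapy to the interval's
mid-time point.  ``k'`` therefore changes from interval to interval but never
within an interval, which keeps the washout mono-exponential inside each
interval and prevents the time trend from mimicking a second compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import DoseEvent


@dataclass
class IndividualParameters:
    """PK parameters of one subject (random effects already applied)."""

    v: float          # distribution volume, L
    k: float          # baseline elimination rate constant, 1/h
    d_k: float = 0.0  # fractional amplitude of the change in k
    kappa_k: float = 0.03  # rate of the change in k, 1/h

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"V must be positive, got {self.v!r}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k!r}")
        if not self.kappa_k > 0:
            raise ValueError(f"kappa_k must be positive, got {self.kappa_k!r}")
        if not 1.0 + self.d_k > 0:
            raise ValueError(
                f"1 + d_k must be positive so elimination stays positive, "
                f"got d_k={self.d_k!r}"
            )


@dataclass
class DoseSchedule:
    """An ordered infusion schedule with per-interval mid-time points.

    Dosing interval ``j`` is the half-open window [t0_j, t0_{j+1}); the final
    interval extends indefinitely, and its mid point is its start plus half
    the subject's median inter-dose gap.
    """

    doses: list[DoseEvent]
    t_mid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError("schedule must contain at least one dose")
        starts = np.array([d.t0 for d in self.doses], dtype=float)
        if np.any(np.diff(starts) <= 0):
            raise ValueError("dose start times must be strictly increasing")
        gaps = np.diff(starts)
        half_gap = float(np.median(gaps)) / 2.0 if gaps.size else 6.0
        mids = np.empty_like(starts)
        mids[:-1] = (starts[:-1] + starts[1:]) / 2.0
        mids[-1] = starts[-1] + half_gap
        self.t_mid = mids

    @property
    def starts(self) -> np.ndarray:
        return np.array([d.t0 for d in self.doses], dtype=float)

    def interval_of(self, t: float) -> int:
        """1-based index of the dosing interval containing time ``t``.

        Times before the first dose map to interval 1 (where the model
        predicts zero concentration anyway).
        """
        j = int(np.searchsorted(self.starts, t, side="right"))
        return max(j, 1)


def k_inst(p: IndividualParameters, t):
    """Instantaneous elimination rate constant ``k*`` at time ``t`` (h)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return p.k * (1.0 + p.d_k * -np.expm1(-p.kappa_k * t))


def _avg_factor(x):
    """(1 - exp(-x)) / x, continuous at 0; x >= 0."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-8
    safe = np.where(small, 1.0, x)
    out = -np.expm1(-safe) / safe
    return np.where(small, 1.0 - x / 2.0, out)


def k_avg(p: IndividualParameters, t):
    """Time-average of ``k*`` over [0, t]; equals ``k`` at t = 0.

    Closed form of (1/t) * integral of k*(s) ds:
    ``k * (1 + d_k * (1 - (1 - exp(-kappa_k t)) / (kappa_k t)))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return p.k * (1.0 + p.d_k * (1.0 - _avg_factor(p.kappa_k * t)))


def concentration(p: IndividualParameters, sched: DoseSchedule, t: float) -> float:
    """Plasma concentration (mg/L) at time ``t`` (h from first infusion start).

    The effective rate constant ``k'`` is ``k_avg`` evaluated at the mid-time
    point of the interval containing ``t`` and is held constant across the
    superposition sum.  Infusions that have not started contribute zero, so
    times before the first dose return 0.
    """
    return float(predict_profile(p, sched, [t])[0])


def predict_profile(p: IndividualParameters, sched: DoseSchedule, times) -> np.ndarray:
    """Vectorized :func:`concentration` over a sequence of times."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(0)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    starts = sched.starts
    idx = np.maximum(np.searchsorted(starts, times, side="right"), 1) - 1
    kprime = k_avg(p, sched.t_mid[idx])  # (m,)
    rates = np.array([d.rate for d in sched.doses])
    tinfs = np.array([d.duration for d in sched.doses])
    dt = times[:, None] - starts[None, :]              # (m, d)
    t_el = np.clip(dt - tinfs[None, :], 0.0, None)     # time after infusion end
    t_on = np.clip(dt, 0.0, None)                      # elapsed since start
    kp = kprime[:, None]
    # (1 - exp(-k' t_inf)) exp(-k' t_el) == exp(-k' t_el) - exp(-k' (t_el + t_inf))
    contrib = rates[None, :] / (kp * p.v) * (np.exp(-kp * t_el) - np.exp(-kp * t_on))
    return contrib.sum(axis=1)
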