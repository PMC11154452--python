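"""Non-compartmental (non-parametric) per-interval exposure estimation.

For every dosing interval with concentration measurements the module
estimates the elimination rate constant ``k_ij`` from the terminal slope of
``ln C`` vs ``t``, the interval AUC and AUMC by the linear trapezoidal rule,
and the derived quantities C_max, CL = dose/AUC, V = dose/(AUC * k),
t_1/2 = ln2/k and MRT = AUMC/AUC.

The first dosing interval is integrated from the pre-dose sample through the
last measurement and extrapolated to infinity with the mono-exponential tail
``C(t_n)/k_n`` (AUMC tail ``C(t_n) t_n / k_n + C(t_n)/k_n^2``), where ``k_n``
is the slope through the last three log-concentrations.  Subsequent intervals
are assumed to be at steady state and integrated between two infusion starts;
a missing end-of-interval sample is filled by log-linear extrapolation from
the last three measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import StudyDataset, Subject

log = logging.getLogger(__name__)


class NCAError(ValueError):
    """An interval does not support the requested estimate."""


@dataclass
class NCAIntervalResult:
    """Exposure metrics of one measured dosing interval."""

    subject_id: str
    interval: int
    dose: float          # mg
    k: float             # terminal slope, 1/h
    auc: float           # mg*h/L
    aumc: float          # mg*h^2/L
    cmax: float          # mg/L
    cl: float            # L/h
    v: float             # L
    t_half: float        # h
    mrt: float           # h
    n_points: int
    extrapolated_fraction: float


def slope_k(times, concs) -> float:
    """Minus the OLS slope of ln(conc) vs time over a descending phase.

    Non-positive concentrations cannot be log-transformed and are excluded
    with a warning; at least two usable points are required.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    keep = concs > 0
    if not keep.all():
        log.warning("excluding %d non-positive concentration(s) from slope fit",
                    int((~keep).sum()))
    times, concs = times[keep], concs[keep]
    if times.size < 2:
        raise NCAError("need at least 2 positive concentrations for the slope")
    slope, _ = np.polyfit(times, np.log(concs), 1)
    return float(-slope)


def _trapz(times: np.ndarray, values: np.ndarray) -> float:
    return float(np.trapezoid(values, times))


def _terminal_slope(times: np.ndarray, concs: np.ndarray, n_tail: int = 3) -> float:
    if times.size < n_tail:
        raise NCAError(f"need at least {n_tail} points for the terminal slope")
    return slope_k(times[-n_tail:], concs[-n_tail:])


def interval_auc_first(times, concs) -> tuple[float, float, float, float]:
    """AUC and AUMC of the first dosing interval, extrapolated to infinity.

    ``times``/``concs`` are the interval's samples from the pre-dose anchor at
    t = 0 through the last measurement t_n.  Returns
    ``(auc, aumc, auc_tail, aumc_tail)`` where the tails are the extrapolated
    parts beyond t_n.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 3:
        raise NCAError("first interval needs at least 3 samples")
    k_n = _terminal_slope(times, concs)
    if k_n <= 0:
        raise NCAError(f"non-positive terminal slope k_n={k_n:.4g}; "
                       "cannot extrapolate to infinity")
    c_n, t_n = float(concs[-1]), float(times[-1])
    auc_tail = c_n / k_n
    aumc_tail = c_n * t_n / k_n + c_n / k_n**2
    auc = _trapz(times, concs) + auc_tail
    aumc = _trapz(times, concs * times) + aumc_tail
    return auc, aumc, auc_tail, aumc_tail


def interval_auc_ss(times, concs, interval_start, next_start) -> tuple[float, float]:
    """Steady-state AUC and AUMC of a later interval between two infusion starts.

    If the last sample precedes the next infusion start, the end-point
    concentration is extrapolated log-linearly from the last three samples
    (exact for a mono-exponential decline).
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.size < 3:
        raise NCAError("steady-state interval needs at least 3 samples")
    if times[-1] < next_start:
        k_n = _terminal_slope(times, concs)
        c_end = float(concs[-1]) * math.exp(-k_n * (next_start - times[-1]))
        times = np.append(times, next_start)
        concs = np.append(concs, c_end)
    keep = (times >= interval_start) & (times <= next_start)
    times, concs = times[keep], concs[keep]
    auc = _trapz(times, concs)
    # first moment relative to the interval start, so MRT stays interpretable
    aumc = _trapz(times, concs * (times - interval_start))
    return auc, aumc


def _interval_result(subject: Subject, j: int, times, concs) -> NCAIntervalResult:
    doses = subject.doses
    dose = doses[j - 1].amount
    start = doses[j - 1].t0
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    order = np.argsort(times)
    times, concs = times[order], concs[order]
    cmax_idx = int(np.argmax(concs))
    cmax = float(concs[cmax_idx])
    desc_t, desc_c = times[cmax_idx + 1:], concs[cmax_idx + 1:]
    if desc_t.size < 2:
        raise NCAError(f"subject {subject.subject_id} interval {j}: "
                       "fewer than 2 descending-phase points")
    k_ij = slope_k(desc_t, desc_c)
    if k_ij <= 0:
        raise NCAError(f"subject {subject.subject_id} interval {j}: "
                       f"non-positive k estimate ({k_ij:.4g})")
    if j == 1:
        auc, aumc, auc_tail, _ = interval_auc_first(times, concs)
        extrap = auc_tail / auc
        # AUMC of the first interval measures residence from a single dose.
        mrt = aumc / auc
    else:
        if j < len(doses):
            next_start = doses[j].t0
        else:
            gaps = np.diff([d.t0 for d in doses])
            next_start = start + float(np.median(gaps))
        auc, aumc = interval_auc_ss(times, concs, start, next_start)
        extrap = 0.0
        mrt = aumc / auc
    cl = dose / auc
    v = dose / (auc * k_ij)
    return NCAIntervalResult(
        subject_id=subject.subject_id, interval=j, dose=dose, k=k_ij,
        auc=auc, aumc=aumc, cmax=cmax, cl=cl, v=v,
        t_half=math.log(2) / k_ij, mrt=mrt,
        n_points=int(times.size), extrapolated_fraction=extrap,
    )


def nca_all(ds: StudyDataset) -> pd.DataFrame:
    """NCA for every measured dosing interval of every subject.

    Intervals that fail the point-count or slope rules are reported via a
    warning and skipped, never fatal.  Returns one row per usable
    (subject, interval).
    """
    rows = []
    for subject in ds.subjects:
        by_interval: dict[int, list] = {}
        for obs in subject.observations:
            by_interval.setdefault(obs.dosing_interval, []).append(obs)
        for j, obs_list in sorted(by_interval.items()):
            times = [o.t for o in obs_list]
            concs = [o.conc for o in obs_list]
            # the pre-dose sample of the next interval is this interval's trough
            nxt = by_interval.get(j + 1)
            if nxt is not None and j + 1 <= len(subject.doses):
                t_next = subject.doses[j].t0
                for o in nxt:
                    if o.t == t_next:
                        times.append(o.t)
                        concs.append(o.conc)
            if len(times) < 3:
                log.warning("subject %s interval %d: only %d samples, skipped",
                            subject.subject_id, j, len(times))
                continue
            try:
                rows.append(_interval_result(subject, j, times, concs))
            except NCAError as exc:
                log.warning("%s", exc)
    return pd.DataFrame([r.__dict__ for r in rows])
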