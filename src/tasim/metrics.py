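"""Transient-response metrics.

Two numbers summarize the protein response to an event (plasmid loss or
competitor induction):

* ``R`` — peak fold-increase: maximum post-event protein concentration
  divided by the level immediately before the event.  ``R = 0`` encodes
  "no transient peak": the post-event maximum sits at the event time
  itself, i.e. the protein only decays.
* ``T_p`` — full width of the peak at half maximum (absolute half level
  ``p_peak/2``), with crossing times located by linear interpolation.

The discrete maximum is refined by a local quadratic (three-point) fit, so
metrics are insensitive to the sampling interval at second order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .integrate import Trajectory

__all__ = ["PeakMetrics", "PeakNotResolvedError", "peak_metrics", "steady_fold_increase"]

#: relative margin by which an interior maximum must exceed the pre-event
#: level to count as a genuine peak.  Circuits just past the peak-abolishing
#: thresholds (e.g. mRNA synthesis above sRNA synthesis) still show a
#: micro-bump of a few 1e-6 relative immediately after the event from the
#: residual complex; the margin is set above that scale so such circuits
#: report R = 0, matching the field's reading of "no peak".
PEAK_RTOL = 1e-4


class PeakNotResolvedError(RuntimeError):
    """The protein never falls back below half maximum within the horizon."""


@dataclass(frozen=True)
class PeakMetrics:
    """Peak fold-increase and width of a post-event protein transient.

    ``R == 0`` encodes "no peak"; then ``T_p`` is NaN.  ``T_p`` is NaN with
    ``resolved=False`` when the protein has not fallen below the half level
    within the horizon.  ``flagged`` marks widths measured above an elevated
    baseline (partial-loss events where the post-event steady level exceeds
    ``p_peak/2``); such rows are excluded from sweep tables.
    """

    R: float
    T_p: float
    t_peak: float
    p_pre: float
    p_peak: float
    resolved: bool = True
    flagged: bool = False


def _quad_refine(t: np.ndarray, p: np.ndarray, i: int):
    """Quadratic vertex through points (i-1, i, i+1); falls back to sample i."""
    if i == 0 or i == len(t) - 1:
        return t[i], p[i]
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = p[i - 1], p[i], p[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    if denom == 0:
        return t1, y1
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2 * t2 * (y0 - y1) + t1 * t1 * (y2 - y0) + t0 * t0 * (y1 - y2)) / denom
    if a >= 0:
        return t1, y1
    tv = -b / (2.0 * a)
    if not (min(t0, t2) <= tv <= max(t0, t2)):
        return t1, y1
    c0 = y1 - a * t1 * t1 - b * t1
    pv = a * tv * tv + b * tv + c0
    return tv, max(pv, y1)


def _cross_time(t0, p0, t1, p1, level):
    """Linear interpolation of the time where p crosses ``level``."""
    if p1 == p0:
        return t0
    return t0 + (level - p0) * (t1 - t0) / (p1 - p0)


def peak_metrics(
    traj: Trajectory,
    t_event: float,
    require_resolved: bool = True,
    steady_check: Optional[float] = None,
) -> PeakMetrics:
    """Measure the post-event protein transient of a trajectory.

    Parameters
    ----------
    traj : Trajectory
        Must span ``t_event`` with a post-event horizon.
    t_event : float
        Time of the perturbation (plasmid loss / induction).
    require_resolved : bool
        If True (default), raise :class:`PeakNotResolvedError` when the
        protein never falls back below the half level within the horizon;
        if False, return metrics with ``T_p = NaN`` and ``resolved=False``.
    steady_check : float, optional
        Expected pre-event steady protein level; a warning is emitted when
        the trajectory value deviates from it by more than 1% relative.
    """
    t = traj.times
    p = traj.column("p")
    i_ev = traj.index_before(t_event)
    if i_ev >= len(t) - 2:
        raise ValueError("trajectory does not extend beyond t_event")
    p_pre = float(p[i_ev])
    if steady_check is not None and steady_check > 0:
        if abs(p_pre - steady_check) > 0.01 * steady_check:
            warnings.warn(
                f"pre-event protein level {p_pre:.6g} differs from the expected "
                f"steady value {steady_check:.6g} by more than 1%: the run may "
                "not have equilibrated", stacklevel=2)

    tp = t[i_ev:]
    pp = p[i_ev:]
    i_max = int(np.argmax(pp))
    t_peak, p_peak = _quad_refine(tp, pp, i_max)
    p_peak = float(p_peak)

    no_peak = i_max == 0 or p_peak <= p_pre * (1.0 + PEAK_RTOL)
    if no_peak and pp[-1] <= p_pre * (1.0 + PEAK_RTOL):
        return PeakMetrics(R=0.0, T_p=math.nan, t_peak=float(tp[0]),
                           p_pre=p_pre, p_peak=p_pre)
    if p_pre == 0:
        raise ValueError("pre-event protein level is zero; fold-increase undefined")
    R = p_peak / p_pre

    half = 0.5 * p_peak
    flagged = False
    p_end = float(pp[-1])
    if p_end > half:
        if i_max == len(pp) - 1:
            # still rising (or plateauing upward) at the horizon
            msg = "peak not resolved; extend t_end"
            if require_resolved:
                raise PeakNotResolvedError(msg)
            return PeakMetrics(R=R, T_p=math.nan, t_peak=float(t_peak),
                               p_pre=p_pre, p_peak=p_peak, resolved=False)
        # post-event baseline sits above half maximum (partial loss):
        # measure the width above the midpoint between peak and baseline
        half = 0.5 * (p_peak + p_end)
        flagged = True

    above = pp > half
    # rising crossing: last sample below half before the peak
    i_rise = None
    for i in range(i_max, 0, -1):
        if not above[i - 1] and above[i]:
            i_rise = i
            break
    t_rise = tp[0] if i_rise is None else _cross_time(
        tp[i_rise - 1], pp[i_rise - 1], tp[i_rise], pp[i_rise], half)
    # falling crossing: first sample below half after the peak
    i_fall = None
    for i in range(max(i_max, 1), len(pp)):
        if above[i - 1] and not above[i]:
            i_fall = i
            break
    if i_fall is None:
        msg = "peak not resolved; extend t_end"
        if require_resolved:
            raise PeakNotResolvedError(msg)
        return PeakMetrics(R=R, T_p=math.nan, t_peak=float(t_peak),
                           p_pre=p_pre, p_peak=p_peak, resolved=False,
                           flagged=flagged)
    t_fall = _cross_time(tp[i_fall - 1], pp[i_fall - 1], tp[i_fall], pp[i_fall], half)
    return PeakMetrics(R=R, T_p=float(t_fall - t_rise), t_peak=float(t_peak),
                       p_pre=p_pre, p_peak=p_peak, flagged=flagged)


def steady_fold_increase(p_before: float, p_after: float) -> float:
    """Ratio of steady protein levels after/before a sustained perturbation."""
    if p_before <= 0:
        raise ValueError("p_before must be positive for a fold-increase")
    return p_after / p_before
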