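"""Event-driven integration of the circuit ODEs.

The canonical numerical experiment starts a plasmid-bearing cell from zero
concentrations, lets the circuit equilibrate, and sets the plasmid copy
number ``g`` to zero at a prescribed loss time (default 150 min of a 300 min
horizon), producing the transient toxin peak that the metrics module
quantifies.  Arbitrary stepwise copy-number schedules (sequential plasmid
loss) and competitor induction are expressed through :class:`EventSchedule`.

Integration is classical fixed-step RK4 (base step ``dt``, default 1e-4 min)
with an ad-hoc adaptive refinement: steps producing negative concentrations
are rejected and retried at half size, down to ``dt_min``; the step is
doubled back toward the base step after 100 consecutive accepted reduced
steps.  Event times are hit exactly by shortening the step that would cross
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .params import CircuitParams, CompetitorParams, CircuitState, ExtendedState

__all__ = [
    "EventSchedule",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "run_loss_experiment",
    "run_sequential_loss",
]

BASE_COLUMNS = ("m", "s", "c", "p")
EXT_COLUMNS = ("m", "s", "c", "p", "m2", "c2")

_ZERO_COMP = np.zeros(5)


class IntegrationError(RuntimeError):
    """Raised when the adaptive RK4 scheme cannot complete a run."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (at t = {t:.6g} min)")
        self.t = t


@dataclass(frozen=True)
class EventSchedule:
    """Timed changes applied during integration.

    ``g_steps`` is an ordered list of ``(time, new_g)`` pairs; ``competitor_on``
    optionally gives the induction time of the competitor mRNA gene (before
    it the competitor synthesis is off and its species are held at zero).
    """

    g_steps: tuple = ()
    competitor_on: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "g_steps",
                           tuple((float(t), float(g)) for t, g in self.g_steps))
        times = [t for t, _ in self.g_steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(t <= 0 for t in times):
            raise ValueError("event times must be positive")
        if any(g < 0 or not math.isfinite(g) for _, g in self.g_steps):
            raise ValueError("scheduled g values must be finite and >= 0")
        if self.competitor_on is not None and self.competitor_on <= 0:
            raise ValueError("competitor_on must be positive")

    def validate_horizon(self, t_end: float) -> None:
        if any(t > t_end for t, _ in self.g_steps):
            raise ValueError("event times must lie within [0, t_end]")
        if self.competitor_on is not None and self.competitor_on > t_end:
            raise ValueError("competitor_on must lie within [0, t_end]")


@dataclass
class Trajectory:
    """Recorded time series of an integration run."""

    times: np.ndarray
    states: np.ndarray
    columns: tuple
    events: EventSchedule = field(default_factory=EventSchedule)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.float64)
        if self.states.shape != (self.times.size, len(self.columns)):
            raise ValueError("times/states shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("recorded concentrations must be non-negative")

    @property
    def extended(self) -> bool:
        return "m2" in self.columns

    def __len__(self) -> int:
        return self.times.size

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def final_state(self):
        y = self.states[-1]
        cls = ExtendedState if self.extended else CircuitState
        return cls.from_array(y)

    def index_before(self, t: float) -> int:
        """Index of the last sample with time <= t."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        if i < 0:
            raise ValueError(f"no sample at or before t = {t}")
        return i

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _segments(schedule: EventSchedule, t_end: float, g0: float):
    """Yield (t_start, t_stop, g, competitor_active) pieces."""
    marks = sorted({t for t, _ in schedule.g_steps}
                   | ({schedule.competitor_on} if schedule.competitor_on is not None else set())
                   | {t_end})
    g_map = dict(schedule.g_steps)
    g = g0
    active = schedule.competitor_on is None
    t_prev = 0.0
    out = []
    for t in marks:
        if t > t_prev:
            out.append((t_prev, t, g, active))
        if t in g_map:
            g = g_map[t]
        if schedule.competitor_on is not None and t == schedule.competitor_on:
            active = True
        t_prev = t
    return out


def integrate(
    params: CircuitParams,
    comp: Optional[CompetitorParams] = None,
    init=None,
    schedule: Optional[EventSchedule] = None,
    t_end: float = 300.0,
    dt: float = 1e-4,
    record_every: float = 0.01,
    dt_min: float = 1e-9,
    max_steps: int = 200_000_000,
) -> Trajectory:
    """Integrate the base (or competitor-extended) circuit and record samples.

    Parameters
    ----------
    params : CircuitParams
        Circuit rates; ``params.g`` is the initial copy number.
    comp : CompetitorParams, optional
        When given, the six-species extended system is integrated.  If the
        schedule carries a ``competitor_on`` time, competitor synthesis and
        binding act only after it, with the competitor species reset to zero
        at induction.
    init : state or array, optional
        Initial concentrations (default: all zero).
    schedule : EventSchedule, optional
        Stepwise copy-number changes and/or competitor induction.
    t_end, dt, record_every, dt_min, max_steps :
        Horizon, base RK4 step, sampling interval, smallest admissible step,
        and a hard cap on the number of accepted steps.

    Returns
    -------
    Trajectory
    """
    if dt <= 0 or t_end <= 0 or record_every <= 0:
        raise ValueError("dt, t_end and record_every must be positive")
    schedule = schedule or EventSchedule()
    schedule.validate_horizon(t_end)
    if schedule.competitor_on is not None and comp is None:
        raise ValueError("schedule sets competitor_on but no CompetitorParams given")

    n_species = 6 if comp is not None else 4
    columns = EXT_COLUMNS if comp is not None else BASE_COLUMNS
    if init is None:
        y = np.zeros(6)
    else:
        y0 = init.to_array() if hasattr(init, "to_array") else np.asarray(init, dtype=np.float64)
        if y0.size not in (4, 6):
            raise ValueError("init must have 4 or 6 components")
        if y0.size == 6 and comp is None:
            raise ValueError("extended initial state requires CompetitorParams")
        if not np.all(np.isfinite(y0)) or np.any(y0 < 0):
            raise ValueError("initial state must be finite and non-negative")
        y = np.zeros(6)
        y[: y0.size] = y0

    pr = params.to_array()
    cp_on = comp.to_array() if comp is not None else _ZERO_COMP

    n_rec_max = int(t_end / record_every) + len(schedule.g_steps) + 4
    rec_t = np.empty(n_rec_max)
    rec_y = np.empty((n_rec_max, 6))
    kk, irec, steps = 0, 0, 0

    for t0, t1, g, active in _segments(schedule, t_end, params.g):
        if schedule.competitor_on is not None and t0 == schedule.competitor_on:
            y[4] = 0.0
            y[5] = 0.0
        pr_seg = pr.copy()
        pr_seg[9] = g
        cp_seg = cp_on if active else _ZERO_COMP
        status, t_fail, kk, irec, steps = _kernels.rk4_segment(
            y, pr_seg, cp_seg, t0, t1, dt, dt_min, record_every, kk,
            rec_t, rec_y, irec, max_steps, steps)
        if status == _kernels.STATUS_DT_UNDERFLOW:
            raise IntegrationError(
                f"step size underflow below dt_min = {dt_min:g} min", t_fail)
        if status == _kernels.STATUS_MAX_STEPS:
            raise IntegrationError(
                f"exceeded max_steps = {max_steps}", t_fail)
        if status == _kernels.STATUS_RECORD_OVERFLOW:  # pragma: no cover
            raise IntegrationError("record buffer overflow", t_fail)

    if irec == 0 or rec_t[irec - 1] < t_end - 1e-12:
        rec_t[irec] = t_end
        rec_y[irec] = y
        irec += 1

    return Trajectory(times=rec_t[:irec].copy(),
                      states=rec_y[:irec, :n_species].copy(),
                      columns=columns, events=schedule)


def run_loss_experiment(
    params: CircuitParams,
    t_loss: float = 150.0,
    t_end: float = 300.0,
    **kwargs,
) -> Trajectory:
    """Zero initial state, equilibrate, set g to 0 at ``t_loss`` (total plasmid loss)."""
    if not 0 < t_loss < t_end:
        raise ValueError("require 0 < t_loss < t_end")
    schedule = EventSchedule(g_steps=((t_loss, 0.0),))
    return integrate(params, schedule=schedule, t_end=t_end, **kwargs)


def run_sequential_loss(
    params: CircuitParams,
    copy_sequence: Sequence[float],
    step_times: Sequence[float],
    t_end: float = 300.0,
    **kwargs,
) -> Trajectory:
    """Stepwise plasmid loss: copy number drops through ``copy_sequence`` at ``step_times``.

    ``params.g`` is the initial copy number; ``copy_sequence[i]`` becomes the
    copy number at ``step_times[i]``.  The sequence must be non-increasing
    starting from ``params.g``.
    """
    if len(copy_sequence) != len(step_times):
        raise ValueError("copy_sequence and step_times must have equal length")
    gs = [params.g, *map(float, copy_sequence)]
    if any(b > a for a, b in zip(gs, gs[1:])):
        raise ValueError("copy_sequence must be non-increasing from params.g")
    schedule = EventSchedule(g_steps=tuple(zip(step_times, copy_sequence)))
    return integrate(params, schedule=schedule, t_end=t_end, **kwargs)
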