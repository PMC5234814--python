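"""Competitor-mRNA (antibacterial crosstalk) analysis.

A second, induced mRNA competes for the antitoxin sRNA through its own
complex.  The interesting readout is no longer a transient but the new
steady state: sequestering sRNA lets toxin mRNA escape silencing, raising
the steady toxin level by a fold-increase R~ = p2*/p*.

Eliminating s, c, m2 and c2 from the six fixed-point conditions in favor of
the toxin mRNA level m gives a cubic.  With

    K1 = beta_c * h+ / (h- + beta_c),    K2 = beta_c2 * k+ / (k- + beta_c2),
    U = alpha_m*g,  V = alpha_s*g,  W = alpha_2*g,
    s(m) = (U - beta_m*m) / (K1*m),
    E = beta_2*K1 - K2*beta_m,           F = K2*U,

the sRNA balance  V = beta_s*s + (U - beta_m*m) + W*K2*s/(beta_2 + K2*s)
multiplied through by K1*m*(beta_2*K1*m + K2*(U - beta_m*m)) becomes

    A3*m^3 + A2*m^2 + A1*m + A0 = 0,
    A3 = -K1*beta_m*E
    A2 = K1*(U*E - beta_m*F) - beta_s*beta_m*E - W*K2*K1*beta_m - V*K1*E
    A1 = K1*U*F + beta_s*(U*E - beta_m*F) + W*K2*K1*U - V*K1*F
    A0 = beta_s*U*F.

Real roots in (0, U/beta_m] (the no-repression bound on m) are located by
sign-change scanning plus bisection; a root is physical iff every
back-substituted concentration is non-negative and the full residual check
passes.  If several roots qualify, a short confirmation integration is the
arbiter — never a silent pick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .integrate import EventSchedule, Trajectory, integrate
from .model import rhs_extended
from .params import CircuitParams, CompetitorParams
from .steady import RESIDUAL_RTOL, solve_steady

__all__ = [
    "ExtendedSteadyState",
    "solve_competitor_steady",
    "competitor_fold_increase",
    "run_competitor_experiment",
]

#: number of uniform subintervals scanned for sign changes
_N_BRACKETS = 10_000


@dataclass(frozen=True)
class ExtendedSteadyState:
    """Fixed point of the six-species competitor-extended circuit."""

    m_star: float
    s_star: float
    c_star: float
    p_star: float
    m2_star: float
    c2_star: float

    def to_array(self) -> np.ndarray:
        return np.array([self.m_star, self.s_star, self.c_star,
                         self.p_star, self.m2_star, self.c2_star])


def _residual_ext(params, comp, y) -> float:
    return float(np.max(np.abs(rhs_extended(y, params, comp))))


def _back_substitute(m, params, comp, K1, K2):
    U = params.alpha_m * params.g
    W = comp.alpha_2 * params.g
    s = (U - params.beta_m * m) / (K1 * m)
    c = params.h_plus * m * s / (params.h_minus + params.beta_c)
    m2 = W / (comp.beta_2 + K2 * s)
    c2 = comp.k_plus * m2 * s / (comp.k_minus + comp.beta_c2)
    p = params.alpha_p * m / params.beta_p
    return np.array([m, s, c, p, m2, c2])


def solve_competitor_steady(
    params: CircuitParams,
    comp: CompetitorParams,
    _arbiter_t: float = 400.0,
) -> ExtendedSteadyState:
    """Analytic steady state of the circuit with an active competitor gene.

    Requires ``beta_p > 0``.  Decoupled special cases (``g = 0``,
    ``alpha_2 = 0``, ``k_plus = 0``) bypass the cubic.

    Raises
    ------
    ValueError
        If no physical root exists in the admissible interval (an
        internal-consistency failure for valid parameters).
    """
    if params.beta_p <= 0:
        raise ValueError("beta_p must be positive for a protein fixed point")

    if params.g == 0:
        # both genes scale with g, so g = 0 silences the competitor too
        return ExtendedSteadyState(0, 0, 0, 0, 0, 0)

    if comp.alpha_2 == 0 or comp.k_plus == 0:
        base = solve_steady(params)
        if comp.alpha_2 == 0:
            m2 = 0.0
        elif comp.beta_2 > 0:
            m2 = comp.alpha_2 * params.g / comp.beta_2
        else:
            raise ValueError("alpha_2 > 0 with beta_2 = k_plus = 0: "
                             "competitor mRNA grows without bound")
        c2 = 0.0 if comp.k_plus == 0 else (
            comp.k_plus * m2 * base.s_star / (comp.k_minus + comp.beta_c2))
        return ExtendedSteadyState(base.m_star, base.s_star, base.c_star,
                                   base.p_star, m2, c2)

    if params.beta_m == 0 or params.beta_s == 0:
        raise ValueError("beta_m = 0 or beta_s = 0 with g > 0: no finite fixed point")
    K1 = params.beta_c * params.h_plus / (params.h_minus + params.beta_c) \
        if (params.h_minus + params.beta_c) > 0 else 0.0
    if K1 == 0:
        raise ValueError("h+ = 0 or beta_c = 0: cubic elimination degenerate; "
                         "no closed-form route implemented for this case")
    K2 = comp.beta_c2 * comp.k_plus / (comp.k_minus + comp.beta_c2) \
        if (comp.k_minus + comp.beta_c2) > 0 else 0.0

    U = params.alpha_m * params.g
    V = params.alpha_s * params.g
    W = comp.alpha_2 * params.g
    bm, bs = params.beta_m, params.beta_s
    E = comp.beta_2 * K1 - K2 * bm
    F = K2 * U

    a3 = -K1 * bm * E
    a2 = K1 * (U * E - bm * F) - bs * bm * E - W * K2 * K1 * bm - V * K1 * E
    a1 = K1 * U * F + bs * (U * E - bm * F) + W * K2 * K1 * U - V * K1 * F
    a0 = bs * U * F

    def cubic(m):
        return ((a3 * m + a2) * m + a1) * m + a0

    m_upper = U / bm
    grid = np.linspace(0.0, m_upper, _N_BRACKETS + 1)
    vals = cubic(grid)
    roots = []
    for i in range(_N_BRACKETS):
        lo, hi = grid[i], grid[i + 1]
        if vals[i] == 0.0 and lo > 0:
            roots.append(lo)
        elif vals[i] * vals[i + 1] < 0:
            roots.append(bisect(cubic, lo, hi, xtol=1e-12 * m_upper))
    if vals[-1] == 0.0:
        roots.append(m_upper)

    candidates = []
    for m in roots:
        if m <= 0:
            continue
        y = _back_substitute(m, params, comp, K1, K2)
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            continue
        scale = max(1.0, float(np.max(y)))
        if _residual_ext(params, comp, y) <= RESIDUAL_RTOL * scale:
            candidates.append(y)

    if not candidates:
        raise ValueError("no physical root of the steady-state cubic in "
                         f"[0, {m_upper:g}]; internal-consistency failure")
    if len(candidates) > 1:
        # dynamics as arbiter: integrate toward the attracting fixed point
        traj = integrate(params, comp=comp, t_end=_arbiter_t,
                         schedule=EventSchedule(competitor_on=_arbiter_t / 2))
        m_final = traj.final_state.m
        dists = [abs(y[0] - m_final) for y in candidates]
        order = sorted(range(len(candidates)), key=dists.__getitem__)
        if dists[order[0]] > 0.1 * max(m_final, 1e-6):
            raise ValueError(
                "multiple physical roots and the confirmation integration is "
                f"inconclusive; candidate m values: {[y[0] for y in candidates]}")
        candidates = [candidates[order[0]]]
    return ExtendedSteadyState(*candidates[0])


def competitor_fold_increase(params: CircuitParams, comp: CompetitorParams) -> float:
    """Steady-state toxin fold-increase R~ = p2*/p* caused by the competitor."""
    base = solve_steady(params)
    if not (base.p_star > 0) or not math.isfinite(base.p_star):
        raise ValueError("base steady state must have finite p* > 0")
    ext = solve_competitor_steady(params, comp)
    return ext.p_star / base.p_star


def run_competitor_experiment(
    params: CircuitParams,
    comp: CompetitorParams,
    t_induce: float = 150.0,
    t_end: float = 300.0,
    **kwargs,
) -> Trajectory:
    """Equilibrate the base circuit, induce the competitor gene at ``t_induce``.

    The competitor species start at zero at the induction time; the plasmid
    is never lost, so the system relaxes to the competitor-shifted steady
    state rather than producing a decaying transient.
    """
    if not 0 < t_induce < t_end:
        raise ValueError("require 0 < t_induce < t_end")
    schedule = EventSchedule(competitor_on=t_induce)
    return integrate(params, comp=comp, schedule=schedule, t_end=t_end, **kwargs)
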