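"""Closed-form fixed points of the base circuit.

At a fixed point the nonlinear binding terms cancel between the mRNA and
sRNA balance equations, leaving a quadratic for the steady sRNA level s*.
With K = h+ * beta_c / (h- + beta_c) (the effective rate at which bound
mRNA is destroyed per unit of free mRNA and sRNA), summing the mRNA and
complex balances gives

    alpha_m*g = beta_m*m* + beta_c*c*,      c* = h+ m* s* / (h- + beta_c),

so m* = (alpha_m*g - alpha_s*g + beta_s*s*)/beta_m and s* solves

    (K*beta_s) s*^2 + (beta_s*beta_m + (alpha_m - alpha_s)*g*K) s*
        - alpha_s*g*beta_m = 0.

Only the "+" branch of the quadratic is non-negative (the discriminant
exceeds the square of the linear coefficient), so it is taken always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import rhs
from .params import CircuitParams, CircuitState

__all__ = ["SteadyState", "solve_steady", "residual"]

#: relative residual accepted at a solved fixed point
RESIDUAL_RTOL = 1e-8


@dataclass(frozen=True)
class SteadyState:
    """Fixed-point concentrations of the base circuit.

    ``p_star`` is ``inf`` when ``beta_p == 0`` with a non-zero mRNA level
    (the protein has no fixed point); all other fields are finite.
    """

    m_star: float
    s_star: float
    c_star: float
    p_star: float

    def to_array(self) -> np.ndarray:
        return np.array([self.m_star, self.s_star, self.c_star, self.p_star])

    def to_state(self) -> CircuitState:
        if not math.isfinite(self.p_star):
            raise ValueError("p_star is infinite (beta_p = 0); no protein fixed point")
        return CircuitState(self.m_star, self.s_star, self.c_star, self.p_star)


def residual(params: CircuitParams, state) -> float:
    """Max-abs component of the RHS at ``state`` (0 exactly at a fixed point)."""
    return float(np.max(np.abs(rhs(state, params))))


def solve_steady(params: CircuitParams) -> SteadyState:
    """Analytic fixed point of the base circuit.

    Raises
    ------
    ValueError
        If ``g > 0`` with ``beta_m == 0`` or ``beta_s == 0`` (no finite fixed
        point is guaranteed), or if the quadratic yields no non-negative root
        (unreachable for valid parameters; an internal-consistency failure).
    """
    a_m, b_m = params.alpha_m, params.beta_m
    a_s, b_s = params.alpha_s, params.beta_s
    g = params.g

    if g == 0:
        return SteadyState(0.0, 0.0, 0.0, 0.0)
    if b_m == 0 or b_s == 0:
        raise ValueError("beta_m = 0 or beta_s = 0 with g > 0: no finite fixed point")

    K = params.h_plus * params.beta_c / (params.h_minus + params.beta_c) \
        if (params.h_minus + params.beta_c) > 0 else 0.0

    if K == 0.0:
        # decoupled birth-death (h+ = 0 or beta_c = 0): no net complex sink
        s = a_s * g / b_s
        m = a_m * g / b_m
    else:
        qa = K * b_s
        qb = b_s * b_m + (a_m - a_s) * g * K
        qc = -a_s * g * b_m
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:  # pragma: no cover - disc = qb^2 + positive for valid params
            raise ValueError("steady-state quadratic has no real root")
        s = (-qb + math.sqrt(disc)) / (2.0 * qa)
        if s < 0:  # pragma: no cover
            raise ValueError("steady-state quadratic has no non-negative root")
        m = ((a_m - a_s) * g + b_s * s) / b_m

    m = max(m, 0.0)
    denom = params.h_minus + params.beta_c
    if denom > 0:
        c = params.h_plus * m * s / denom
    elif params.h_plus * m * s > 0:
        raise ValueError("h- = beta_c = 0 with binding flux: complex grows without bound")
    else:
        c = 0.0
    if params.beta_p > 0:
        p = params.alpha_p * m / params.beta_p
    else:
        p = math.inf if params.alpha_p * m > 0 else 0.0

    st = SteadyState(m, s, c, p)
    if math.isfinite(p):
        scale = max(1.0, float(np.max(st.to_array())))
        if residual(params, st.to_array()) > RESIDUAL_RTOL * scale:
            raise ValueError("fixed-point residual check failed")  # pragma: no cover
    return st
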