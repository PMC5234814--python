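"""Closed-form post-loss dynamics under the instant-release simplification.

After plasmid loss the binding dynamics are dropped and all complexed mRNA
is assumed to be released at once: the free mRNA pool starts at m* + c*
and simply decays, driving the protein through a double-exponential

    m(t) = m2* + (m* + c* - m2*) e^(-beta_m t)
    p(t) = p2* - B e^(-beta_m t) + (p* - p2* + B) e^(-beta_p t),
    B = (m* + c* - m2*) * alpha_p / (beta_m - beta_p),

where starred quantities are the pre-loss steady state and the "2*" ones
the post-loss steady state (zero for total loss).  The peak of p(t) has a
closed form and strongly overestimates the simulated peak, because in the
full model the complex releases its mRNA gradually.  The fraction ``phi``
of the complex pool released at t=0 is exposed as a knob (default 1, the
plain formula); lowering it mimics the gradual release.
"""

from __future__ import annotations

import math
from typing import Tuple

from .params import CircuitParams
from .steady import SteadyState

__all__ = ["approx_post_loss", "approx_peak"]

_ZERO = SteadyState(0.0, 0.0, 0.0, 0.0)


def _released(pre: SteadyState, phi: float) -> float:
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return pre.m_star + phi * pre.c_star


def approx_post_loss(
    params: CircuitParams,
    pre: SteadyState,
    post: SteadyState = _ZERO,
    t: float = 0.0,
    phi: float = 1.0,
) -> Tuple[float, float]:
    """Approximate (m, p) at time ``t`` after plasmid loss.

    ``pre``/``post`` are the steady states before and after the loss event
    (``post`` defaults to the total-loss case, all zero).  Requires
    ``beta_m != beta_p`` (the confluent double-exponential case is not
    treated) and a finite pre-loss protein level.
    """
    bm, bp = params.beta_m, params.beta_p
    if bm == bp:
        raise ValueError("beta_m == beta_p: degenerate double exponential")
    if t < 0:
        raise ValueError("t must be >= 0")
    if not math.isfinite(pre.p_star):
        raise ValueError("pre-loss protein level is infinite (beta_p = 0)")
    dm = _released(pre, phi) - post.m_star
    B = dm * params.alpha_p / (bm - bp)
    m = post.m_star + dm * math.exp(-bm * t)
    p = (post.p_star - B * math.exp(-bm * t)
         + (pre.p_star - post.p_star + B) * math.exp(-bp * t))
    return m, p


def approx_peak(
    params: CircuitParams,
    pre: SteadyState,
    phi: float = 1.0,
) -> Tuple[float, float, float]:
    """Closed-form peak of the approximate protein transient after total loss.

    Setting dp/dt = 0 gives the peak time

        t_peak = ln(B*beta_m / (C*beta_p)) / (beta_m - beta_p),
        C = p* + B,

    returned with the peak height and ``R_approx = p_max / p*``.  When the
    derivative has no positive root (the approximation only decays),
    ``(0, p*, 1)`` is returned.  With ``beta_p == 0`` the protein rises
    monotonically to its asymptote C, returned as ``(inf, C, C/p*)``.
    """
    bm, bp = params.beta_m, params.beta_p
    if bm == bp:
        raise ValueError("beta_m == beta_p: degenerate double exponential")
    if not math.isfinite(pre.p_star):
        raise ValueError("pre-loss protein level is infinite (beta_p = 0)")
    if pre.p_star <= 0:
        raise ValueError("pre-loss protein level must be positive")
    B = _released(pre, phi) * params.alpha_p / (bm - bp)
    C = pre.p_star + B
    if bp == 0.0:
        return math.inf, C, C / pre.p_star
    arg = B * bm / (C * bp)
    if arg <= 0:
        return 0.0, pre.p_star, 1.0
    t_peak = math.log(arg) / (bm - bp)
    if t_peak <= 0:
        return 0.0, pre.p_star, 1.0
    p_max = -B * math.exp(-bm * t_peak) + C * math.exp(-bp * t_peak)
    return t_peak, p_max, p_max / pre.p_star
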