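"""Right-hand sides of the circuit ODEs.

Base system (species m, s, c, p; plasmid copy number g):

    dm/dt = alpha_m*g - beta_m*m - h+ * m*s + h- * c
    ds/dt = alpha_s*g - beta_s*s - h+ * m*s + h- * c
    dc/dt = h+ * m*s - h- * c - beta_c*c
    dp/dt = alpha_p*m - beta_p*p

The competitor extension adds a second mRNA (m2) competing for the same
sRNA pool through its own complex (c2) with rates k+, k-, beta_c2; the
sRNA equation gains the corresponding sink/source terms.
"""

from __future__ import annotations

import numpy as np

from .params import CircuitParams, CompetitorParams, CircuitState, ExtendedState

__all__ = ["rhs", "rhs_extended"]


def _as_state_array(state, n: int) -> np.ndarray:
    if isinstance(state, CircuitState):  # covers ExtendedState too
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=np.float64)
    if y.shape != (n,):
        raise ValueError(f"state must have {n} components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state contains non-finite values: {y}")
    return y


def rhs(state, params: CircuitParams) -> np.ndarray:
    """Time derivatives (dm, ds, dc, dp) of the base circuit.

    Pure function; accepts a :class:`CircuitState` or a length-4 array.
    """
    m, s, c, p = _as_state_array(state, 4)
    bind = params.h_plus * m * s
    unbind = params.h_minus * c
    return np.array([
        params.alpha_m * params.g - params.beta_m * m - bind + unbind,
        params.alpha_s * params.g - params.beta_s * s - bind + unbind,
        bind - unbind - params.beta_c * c,
        params.alpha_p * m - params.beta_p * p,
    ])


def rhs_extended(state, params: CircuitParams, comp: CompetitorParams) -> np.ndarray:
    """Time derivatives (dm, ds, dc, dp, dm2, dc2) of the competitor-extended circuit.

    With ``comp.alpha_2 == 0`` and ``m2 == c2 == 0`` the first four components
    reduce exactly to :func:`rhs` on the embedded base state.
    """
    m, s, c, p, m2, c2 = _as_state_array(state, 6)
    bind = params.h_plus * m * s
    unbind = params.h_minus * c
    bind2 = comp.k_plus * m2 * s
    unbind2 = comp.k_minus * c2
    return np.array([
        params.alpha_m * params.g - params.beta_m * m - bind + unbind,
        params.alpha_s * params.g - params.beta_s * s - bind + unbind - bind2 + unbind2,
        bind - unbind - params.beta_c * c,
        params.alpha_p * m - params.beta_p * p,
        comp.alpha_2 * params.g - comp.beta_2 * m2 - bind2 + unbind2,
        bind2 - unbind2 - comp.beta_c2 * c2,
    ])
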