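"""Compiled RK4 integration kernels.

One kernel integrates the six-species competitor-extended system; the base
four-species circuit is the special case with all competitor rates and
species zero, for which the extra terms vanish identically (so base results
are bit-identical to a dedicated four-species integrator).

Adaptivity follows the negative-concentration heuristic: a classical RK4
step whose result has a component below ``-NEG_TOL`` is rejected and retried
at half the step size; after a clean streak of accepted steps at a reduced
size the step is doubled back toward the base size.  The required streak
starts at 100 and doubles (up to 10^6) every time a rejection follows
shortly after a doubling: for marginally stiff parameter sets the base step
sits just past the RK4 stability boundary, and without this backoff the
integrator would re-enter the weakly unstable regime every 100 steps, whose
truncated oscillations bias the fast species downward.  Round-off negatives
in ``(-NEG_TOL, 0)`` are clamped to zero.

In addition the step is capped by a stability bound 2/L, where L sums the
state-dependent first-order rates (binding ``h+ (m+s)``, unbinding,
degradation, and the competitor analogues).  L bounds the Jacobian's
spectral radius from above, so the cap keeps classical RK4 well inside its
real-axis stability interval (~2.79/lambda): without it, stiff-but-stable
parameter sets (large ``h+ s``) sit marginally outside the stable region at
the base step, where slowly growing oscillations in the fast species evade
the negativity trigger for long stretches and bias the averages the slow
species integrate.  For the default parameter set the cap (~3e-3 min) is
far above the base step and has no effect.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: magnitude below which a negative concentration is treated as round-off
NEG_TOL = 1e-12

STATUS_OK = 0
STATUS_DT_UNDERFLOW = 1
STATUS_MAX_STEPS = 2
STATUS_RECORD_OVERFLOW = 3


@njit(cache=True)
def _deriv(y, pr, cp, dy):
    # pr: [alpha_m, beta_m, alpha_s, beta_s, alpha_p, beta_p,
    #      h_plus, h_minus, beta_c, g];  cp: [alpha_2, beta_2, k_plus, k_minus, beta_c2]
    m = y[0]
    s = y[1]
    c = y[2]
    p = y[3]
    m2 = y[4]
    c2 = y[5]
    bind = pr[6] * m * s
    unb = pr[7] * c
    bind2 = cp[2] * m2 * s
    unb2 = cp[3] * c2
    dy[0] = pr[0] * pr[9] - pr[1] * m - bind + unb
    dy[1] = pr[2] * pr[9] - pr[3] * s - bind + unb - bind2 + unb2
    dy[2] = bind - unb - pr[8] * c
    dy[3] = pr[4] * m - pr[5] * p
    dy[4] = cp[0] * pr[9] - cp[1] * m2 - bind2 + unb2
    dy[5] = bind2 - unb2 - cp[4] * c2


@njit(cache=True)
def _rk4_step(y, pr, cp, h, k1, k2, k3, k4, yt, out):
    _deriv(y, pr, cp, k1)
    for i in range(6):
        yt[i] = y[i] + 0.5 * h * k1[i]
    _deriv(yt, pr, cp, k2)
    for i in range(6):
        yt[i] = y[i] + 0.5 * h * k2[i]
    _deriv(yt, pr, cp, k3)
    for i in range(6):
        yt[i] = y[i] + h * k3[i]
    _deriv(yt, pr, cp, k4)
    for i in range(6):
        out[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def rk4_segment(y, pr, cp, t0, t1, dt_base, dt_min, rec_every, kk,
                rec_t, rec_y, irec, max_steps, steps_done):
    """Integrate ``y`` in place from ``t0`` to ``t1`` with constant parameters.

    Records the state at every absolute time ``kk*rec_every, (kk+1)*rec_every,
    ...`` that falls inside the segment (the grid is anchored at t=0 so record
    times never drift).  Returns ``(status, t, kk, irec, steps)``.
    """
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    yt = np.empty(6)
    ynew = np.empty(6)
    t = t0
    dt_cur = dt_base
    streak = 0
    streak_needed = 100
    since_double = 1 << 40
    steps = steps_done
    while t < t1 - 1e-12:
        next_rec = kk * rec_every
        target = next_rec if next_rec < t1 else t1
        while t < target - 1e-13:
            lam = (pr[1] + pr[3] + pr[5] + pr[7] + pr[8]
                   + pr[6] * (y[0] + y[1])
                   + cp[1] + cp[3] + cp[4] + cp[2] * (y[4] + y[1]))
            h = dt_cur
            if lam * h > 2.0:
                h = 2.0 / lam
            exact = False
            if h >= target - t:
                h = target - t
                exact = True
            _rk4_step(y, pr, cp, h, k1, k2, k3, k4, yt, ynew)
            bad = False
            for i in range(6):
                if ynew[i] < -NEG_TOL:
                    bad = True
                    break
            if bad:
                dt_cur *= 0.5
                streak = 0
                if since_double < 1000 and streak_needed < 1_000_000:
                    streak_needed *= 2  # premature doubling: back off
                since_double = 1 << 40
                if dt_cur < dt_min:
                    return STATUS_DT_UNDERFLOW, t, kk, irec, steps
                continue
            for i in range(6):
                y[i] = ynew[i] if ynew[i] > 0.0 else 0.0
            t = target if exact else t + h
            steps += 1
            if steps > max_steps:
                return STATUS_MAX_STEPS, t, kk, irec, steps
            if dt_cur < dt_base:
                streak += 1
                since_double += 1
                if streak >= streak_needed:
                    dt_cur = min(2.0 * dt_cur, dt_base)
                    streak = 0
                    since_double = 0
        t = target
        if abs(target - next_rec) <= 1e-12:
            if irec >= rec_t.shape[0]:
                return STATUS_RECORD_OVERFLOW, t, kk, irec, steps
            rec_t[irec] = t
            for i in range(6):
                rec_y[irec, i] = y[i]
            irec += 1
            kk += 1
    return STATUS_OK, t1, kk, irec, steps
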