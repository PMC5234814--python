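import numpy as np
import pytest

from tasim import (
    DEFAULT_PARAMS,
    CircuitParams,
    CompetitorParams,
    run_loss_experiment,
)


@pytest.fixture(scope="session")
def default_loss_traj():
    """Canonical run: defaults, zero init, loss at 150 min, 300 min horizon."""
    return run_loss_experiment(DEFAULT_PARAMS)


def draw_circuit(rng: np.random.Generator) -> CircuitParams:
    """Random plausible circuit with all relaxation rates >= 0.1/min.

    Rates are log-uniform inside literature-plausible ranges; the lower
    bound on degradation rates guarantees the circuit equilibrates to well
    under 1e-4 relative within the standard 150 min, so trajectories are a
    valid oracle for the analytic fixed point.
    """
    bounds = dict(alpha_m=(0.5, 2), beta_m=(0.1, 0.7), alpha_s=(2, 12),
                  beta_s=(0.35, 1.4), alpha_p=(1, 7), beta_p=(0.1, 0.5),
                  h_plus=(5, 100), h_minus=(0.1, 5), beta_c=(0.1, 0.5))
    kw = {k: float(np.exp(rng.uniform(np.log(a), np.log(b))))
          for k, (a, b) in bounds.items()}
    return CircuitParams(g=float(rng.integers(1, 11)), **kw)


def draw_competitor(rng: np.random.Generator) -> CompetitorParams:
    bounds = dict(alpha_2=(0.5, 8), beta_2=(0.1, 1.4), k_plus=(5, 100),
                  k_minus=(0.1, 5), beta_c2=(0.1, 0.5))
    return CompetitorParams(**{k: float(np.exp(rng.uniform(np.log(a), np.log(b))))
                               for k, (a, b) in bounds.items()})
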