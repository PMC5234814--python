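"""Competitor-mRNA steady states, fold-increase and induction dynamics."""

import numpy as np
import pytest

from tasim import (
    DEFAULT_COMPETITOR,
    DEFAULT_PARAMS,
    CompetitorParams,
    EventSchedule,
    competitor_fold_increase,
    integrate,
    run_competitor_experiment,
    solve_competitor_steady,
    solve_steady,
)
from tasim.model import rhs_extended

from conftest import draw_circuit, draw_competitor


def test_silent_competitor_reduces_to_base_steady():
    comp0 = DEFAULT_COMPETITOR.replace(alpha_2=0.0)
    ext = solve_competitor_steady(DEFAULT_PARAMS, comp0)
    base = solve_steady(DEFAULT_PARAMS)
    np.testing.assert_allclose(
        ext.to_array()[:4], base.to_array(), rtol=1e-12)
    assert ext.m2_star == ext.c2_star == 0.0


def test_non_binding_competitor_decouples():
    comp = DEFAULT_COMPETITOR.replace(k_plus=0.0)
    ext = solve_competitor_steady(DEFAULT_PARAMS, comp)
    base = solve_steady(DEFAULT_PARAMS)
    np.testing.assert_allclose(ext.to_array()[:4], base.to_array(), rtol=1e-12)
    assert ext.m2_star == pytest.approx(
        comp.alpha_2 * DEFAULT_PARAMS.g / comp.beta_2, rel=1e-12)
    assert ext.c2_star == 0.0


def test_cubic_root_matches_long_time_integration():
    ext = solve_competitor_steady(DEFAULT_PARAMS, DEFAULT_COMPETITOR)
    traj = integrate(DEFAULT_PARAMS, comp=DEFAULT_COMPETITOR, t_end=600.0,
                     schedule=EventSchedule(competitor_on=150.0),
                     record_every=10.0)
    y = traj.states[-1]
    rel = np.abs(y - ext.to_array()) / np.maximum(ext.to_array(), 1e-12)
    assert np.max(rel) < 1e-6
    resid = np.max(np.abs(rhs_extended(ext.to_array(), DEFAULT_PARAMS,
                                       DEFAULT_COMPETITOR)))
    assert resid < 1e-8 * max(1.0, float(np.max(ext.to_array())))


@pytest.mark.parametrize("seed", range(6))
def test_analytic_vs_numeric_for_random_pairs(seed):
    rng = np.random.default_rng(200 + seed)
    p, comp = draw_circuit(rng), draw_competitor(rng)
    ext = solve_competitor_steady(p, comp)
    traj = integrate(p, comp=comp, t_end=220.0,
                     schedule=EventSchedule(competitor_on=20.0),
                     record_every=10.0)
    rel = np.abs(traj.states[-1] - ext.to_array()) / np.maximum(ext.to_array(), 1e-12)
    assert np.max(rel) < 1e-4


def test_fold_increase_trivial_and_active():
    assert competitor_fold_increase(
        DEFAULT_PARAMS, DEFAULT_COMPETITOR.replace(alpha_2=0.0)) == pytest.approx(1.0)
    assert competitor_fold_increase(DEFAULT_PARAMS, DEFAULT_COMPETITOR) > 1.0


def test_fold_increase_independent_of_translation_rate():
    rs = [competitor_fold_increase(DEFAULT_PARAMS.replace(alpha_p=ap),
                                   DEFAULT_COMPETITOR)
          for ap in (1.0, 5.0, 30.0)]
    np.testing.assert_allclose(rs, rs[0], rtol=1e-9)


def test_fold_increase_monotone_in_competitor_synthesis():
    vals = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
    rs = [competitor_fold_increase(DEFAULT_PARAMS,
                                   DEFAULT_COMPETITOR.replace(alpha_2=v))
          for v in vals]
    assert all(b >= a - 1e-9 for a, b in zip(rs, rs[1:]))
    # once the sRNA pool is saturated, the marginal gain per unit alpha_2 drops
    gain_mid = (rs[6] - rs[5]) / (vals[6] - vals[5])
    gain_late = (rs[7] - rs[6]) / (vals[7] - vals[6])
    assert gain_late < gain_mid


def test_fold_increase_nondecreasing_in_complex_degradation():
    rs = [competitor_fold_increase(DEFAULT_PARAMS,
                                   DEFAULT_COMPETITOR.replace(beta_c2=v))
          for v in (0.02, 0.05, 0.1, 0.2, 0.5, 1.0)]
    assert all(b >= a - 1e-9 for a, b in zip(rs, rs[1:]))


def test_induction_experiment_settles_at_shifted_steady():
    traj = run_competitor_experiment(DEFAULT_PARAMS, DEFAULT_COMPETITOR,
                                     t_induce=150.0, t_end=600.0,
                                     record_every=1.0)
    ext = solve_competitor_steady(DEFAULT_PARAMS, DEFAULT_COMPETITOR)
    rel = np.abs(traj.final_state.to_array() - ext.to_array()) \
        / np.maximum(ext.to_array(), 1e-12)
    assert np.max(rel) < 1e-4
    # steady toxin level after induction is non-zero and elevated
    assert traj.final_state.p > solve_steady(DEFAULT_PARAMS).p_star
    # free toxin mRNA stays low throughout (complexes hold the template)
    assert np.max(traj.column("m")) < 1.0


def test_silent_competitor_trajectory_matches_no_event_run():
    comp0 = DEFAULT_COMPETITOR.replace(alpha_2=0.0)
    a = run_competitor_experiment(DEFAULT_PARAMS, comp0, t_induce=50.0,
                                  t_end=100.0, dt=1e-3)
    b = integrate(DEFAULT_PARAMS, t_end=100.0, dt=1e-3)
    np.testing.assert_allclose(a.states[:, :4], b.states, rtol=1e-10, atol=1e-12)
    assert np.all(a.states[:, 4:] == 0.0)


def test_guards():
    with pytest.raises(ValueError, match="beta_p"):
        solve_competitor_steady(DEFAULT_PARAMS.replace(beta_p=0.0),
                                DEFAULT_COMPETITOR)
    with pytest.raises(ValueError):
        solve_competitor_steady(DEFAULT_PARAMS,
                                CompetitorParams(alpha_2=1.0, beta_2=0.0,
                                                 k_plus=0.0))
    assert solve_competitor_steady(DEFAULT_PARAMS.with_g(0.0),
                                   DEFAULT_COMPETITOR).to_array().tolist() == [0.0] * 6
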