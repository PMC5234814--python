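"""Event-driven RK4 integration."""

import numpy as np
import pytest

from tasim import (
    DEFAULT_PARAMS,
    CircuitParams,
    EventSchedule,
    integrate,
    peak_metrics,
    run_loss_experiment,
    run_sequential_loss,
    solve_steady,
)


def test_zero_state_absorbing_without_plasmid():
    traj = integrate(DEFAULT_PARAMS.with_g(0.0), t_end=50.0, dt=1e-3)
    assert np.all(traj.states == 0.0)


def test_state_before_loss_matches_analytic_steady(default_loss_traj):
    st = solve_steady(DEFAULT_PARAMS).to_array()
    i = default_loss_traj.index_before(150.0)
    assert default_loss_traj.times[i] == 150.0
    rel = np.abs(default_loss_traj.states[i] - st) / np.maximum(st, 1e-12)
    # RNA species relax within minutes; the protein mode (1/beta_p ~ 29 min)
    # has only completed ~5 e-foldings by t = 150, hence the looser bound
    assert np.max(rel[:3]) < 1e-4
    assert rel[3] < 1e-2


def test_step_halving_agreement():
    a = integrate(DEFAULT_PARAMS, t_end=30.0, dt=1e-4, record_every=30.0).states[-1]
    b = integrate(DEFAULT_PARAMS, t_end=30.0, dt=5e-5, record_every=30.0).states[-1]
    np.testing.assert_allclose(a, b, rtol=1e-8)


def test_rk4_fourth_order_convergence():
    """Global error shrinks ~16x per step halving on a smooth stretch."""
    p = DEFAULT_PARAMS.replace(h_plus=0.5)
    init = [1.0, 1.0, 0.5, 1.0]
    ref = integrate(p, init=init, t_end=5.0, dt=1e-3, record_every=5.0).states[-1]
    errs = [np.max(np.abs(
        integrate(p, init=init, t_end=5.0, dt=dt, record_every=5.0).states[-1] - ref))
        for dt in (0.05, 0.025)]
    assert 12.0 < errs[0] / errs[1] < 20.0


def test_rna_totals_conserved_without_degradation():
    """With g = 0 and no degradation, m+c and s+c are constants of motion."""
    p = CircuitParams(alpha_m=1, beta_m=0, alpha_s=1, beta_s=0, alpha_p=2,
                      beta_p=0.1, h_plus=5, h_minus=0.5, beta_c=0, g=0)
    traj = integrate(p, init=[2.0, 1.5, 0.5, 1.0], t_end=20.0, dt=1e-3)
    mc = traj.column("m") + traj.column("c")
    sc = traj.column("s") + traj.column("c")
    np.testing.assert_allclose(mc, mc[0], rtol=1e-10)
    np.testing.assert_allclose(sc, sc[0], rtol=1e-10)


def test_recorded_concentrations_nonnegative(default_loss_traj):
    assert np.all(default_loss_traj.states >= 0.0)
    assert np.all(np.diff(default_loss_traj.times) > 0)


def test_no_template_no_protein():
    traj = run_loss_experiment(DEFAULT_PARAMS.replace(alpha_m=0.0),
                               t_loss=20.0, t_end=40.0, dt=1e-3)
    assert np.all(traj.column("p") == 0.0)
    assert np.all(traj.column("m") == 0.0)


def test_rapid_equilibrium_runs_to_completion():
    p = DEFAULT_PARAMS.replace(h_plus=1000.0, h_minus=10.0)
    traj = run_loss_experiment(p)
    assert traj.times[-1] == 300.0


def test_single_step_sequence_equals_loss_experiment():
    a = run_sequential_loss(DEFAULT_PARAMS, [0.0], [150.0])
    b = run_loss_experiment(DEFAULT_PARAMS)
    np.testing.assert_array_equal(a.states, b.states)
    np.testing.assert_array_equal(a.times, b.times)


def test_sequential_loss_peak_below_all_at_once():
    p7 = DEFAULT_PARAMS.with_g(7.0)
    seq = run_sequential_loss(p7, [6, 3, 1, 0], [60, 100, 150, 200], t_end=400.0)
    pm_seq = peak_metrics(seq, 200.0, require_resolved=False)
    pm_all = peak_metrics(run_loss_experiment(p7, t_loss=200.0, t_end=400.0), 200.0)
    assert pm_seq.p_peak < pm_all.p_peak


def test_constant_copy_number_converges_to_steady_and_stays():
    st = solve_steady(DEFAULT_PARAMS).to_array()
    traj = integrate(DEFAULT_PARAMS, t_end=600.0, record_every=1.0)
    late = traj.states[traj.times >= 450.0]
    rel = np.abs(late - st) / np.maximum(st, 1e-12)
    assert np.max(rel) < 1e-6


def test_schedule_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        EventSchedule(g_steps=((10.0, 3.0), (10.0, 1.0)))
    with pytest.raises(ValueError, match=">= 0"):
        EventSchedule(g_steps=((10.0, -1.0),))
    with pytest.raises(ValueError, match="t_end"):
        integrate(DEFAULT_PARAMS, schedule=EventSchedule(g_steps=((50.0, 0.0),)),
                  t_end=40.0)
    with pytest.raises(ValueError, match="non-increasing"):
        run_sequential_loss(DEFAULT_PARAMS, [3.0, 5.0], [10.0, 20.0])


def test_trajectory_tsv_roundtrip(tmp_path, default_loss_traj):
    path = tmp_path / "traj.tsv"
    default_loss_traj.to_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["time", "m", "s", "c", "p"]
    assert len(df) == len(default_loss_traj)
    np.testing.assert_allclose(df["p"].to_numpy(),
                               default_loss_traj.column("p"), rtol=1e-9)
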