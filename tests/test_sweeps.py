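"""Single-parameter scans, constrained random sampling, region filtering."""

import io

import numpy as np
import pytest

from tasim import (
    DEFAULT_COMPETITOR,
    DEFAULT_PARAMS,
    SampleSpec,
    ScanSpec,
    SweepTable,
    TABLE_RANGES,
    filter_region,
    peak_metrics,
    random_sample,
    single_parameter_scan,
)
from tasim.sweeps import draw_parameter_sets


def test_scan_of_single_value_equals_direct_run(default_loss_traj):
    table = single_parameter_scan(ScanSpec(parameter_name="g", values=(6.0,)))
    pm = peak_metrics(default_loss_traj, 150.0)
    row = table.data.iloc[0]
    assert row["R"] == pytest.approx(pm.R, rel=1e-12)
    assert row["T_p"] == pytest.approx(pm.T_p, rel=1e-12)
    assert row["status"] == "ok"


def test_mrna_synthesis_above_srna_synthesis_kills_the_peak():
    """Raising alpha_m past the sRNA synthesis rate (6/min/copy) removes the
    transient entirely."""
    table = single_parameter_scan(
        ScanSpec(parameter_name="alpha_m", values=(6.5, 9.0)))
    assert (table.data["R"] == 0.0).all()


def test_translation_rate_scan_leaves_R_unchanged():
    table = single_parameter_scan(
        ScanSpec(parameter_name="alpha_p", values=(1.0, 5.0, 30.0)))
    rs = table.data["R"].to_numpy()
    np.testing.assert_allclose(rs, rs[1], rtol=1e-6)


def test_competitor_scan_uses_steady_fold_increase():
    table = single_parameter_scan(
        ScanSpec(parameter_name="alpha_2", values=(0.0, 4.0),
                 comp=DEFAULT_COMPETITOR, experiment="competitor"))
    rs = table.data["R"].to_numpy()
    assert rs[0] == pytest.approx(1.0)
    assert rs[1] > 1.0


def test_scan_records_failures_per_row():
    # beta_m = beta_s = 0 has no finite steady state but must not kill the scan
    table = single_parameter_scan(
        ScanSpec(parameter_name="beta_2", values=(0.6,),
                 base=DEFAULT_PARAMS.replace(beta_m=0.0),
                 comp=DEFAULT_COMPETITOR, experiment="competitor"))
    assert table.data["status"].str.startswith("failed").all()
    assert np.isnan(table.data["R"]).all()


def test_scan_spec_validation():
    with pytest.raises(ValueError, match="unknown parameter"):
        ScanSpec(parameter_name="gamma", values=(1.0,))
    with pytest.raises(ValueError, match="non-empty"):
        ScanSpec(parameter_name="g", values=())
    with pytest.raises(ValueError, match="requires CompetitorParams"):
        ScanSpec(parameter_name="g", values=(1.0,), experiment="competitor")


def test_draws_respect_constraints_and_grid():
    spec = SampleSpec(n_samples=200, seed=11)
    sets = draw_parameter_sets(spec, np.random.default_rng(spec.seed))
    assert len(sets) == 200
    for p in sets:
        assert p.alpha_m > p.beta_m and p.alpha_s > p.beta_s
        assert p.g == 6.0
        for name, (lo, hi, res) in TABLE_RANGES.items():
            v = getattr(p, name)
            assert lo - 1e-12 <= v <= hi + 1e-12
            k = (v - lo) / res
            assert abs(k - round(k)) < 1e-6 or v in (lo, hi)


def test_log_ratio_sampling_spans_both_sides():
    spec = SampleSpec(n_samples=300, seed=5)
    sets = draw_parameter_sets(spec, np.random.default_rng(spec.seed))
    ratios = np.array([p.alpha_m / p.alpha_s for p in sets])
    assert (ratios > 1).any() and (ratios < 1).any()
    # log-ratio distribution is roughly centered (uniform over log range,
    # thinned asymmetrically only by the alpha > beta rejection)
    assert 0.2 < np.mean(ratios > 1) < 0.8


def test_random_sample_deterministic_and_serializable(tmp_path):
    spec = SampleSpec(n_samples=8, seed=3)
    a, b = random_sample(spec), random_sample(spec)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    a.data.to_csv(buf_a, sep="\t", index=False)
    b.data.to_csv(buf_b, sep="\t", index=False)
    assert buf_a.getvalue() == buf_b.getvalue()

    path = tmp_path / "sweep.tsv"
    a.to_tsv(path)
    back = SweepTable.from_tsv(path)
    assert back.meta["seed"] == "3"
    assert len(back) == 8
    np.testing.assert_allclose(back.data["alpha_m"].to_numpy(),
                               a.data["alpha_m"].to_numpy(), rtol=1e-9)


def test_infeasible_sample_spec_rejected():
    ranges = dict(TABLE_RANGES)
    ranges["alpha_m"] = (0.001, 0.01, 0.0005)
    ranges["beta_m"] = (1.0, 14.0, 0.0005)
    with pytest.raises(ValueError, match="feasible"):
        SampleSpec(n_samples=10, ranges=ranges)


@pytest.fixture(scope="module")
def small_table():
    return random_sample(SampleSpec(n_samples=40, seed=17))


def test_filter_region(small_table):
    ident = filter_region(small_table, [])
    assert len(ident) == len(small_table)

    sub = filter_region(small_table, [("alpha_m/alpha_s", "<", 0.8),
                                      ("beta_m/beta_s", "<", 4.0)])
    d = small_table.data
    expected = ((d["alpha_m"] / d["alpha_s"] < 0.8)
                & (d["beta_m"] / d["beta_s"] < 4.0)).sum()
    assert len(sub) == expected

    scaled = filter_region(small_table, [("1.5*beta_c", "<", 1.0)])
    assert len(scaled) == (1.5 * d["beta_c"] < 1.0).sum()

    empty = filter_region(small_table, [("beta_c", "<", 0.0),
                                        ("beta_c", ">", 1.0)])
    assert len(empty) == 0

    with pytest.raises(ValueError, match="unknown column"):
        filter_region(small_table, [("nope/beta_c", "<", 1.0)])
    with pytest.raises(ValueError, match="unknown comparison"):
        filter_region(small_table, [("beta_c", "~", 1.0)])
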