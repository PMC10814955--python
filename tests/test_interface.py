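"""Config round-trips, experiment harnesses, fixtures and the CLI."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import fbstev as fb
from fbstev.interface import RunConfig, ResultRecord


def test_fixture_generators_are_deterministic(tmp_path):
    a = fb.generate_fixture("logistic-separated", 7)
    b = fb.generate_fixture("logistic-separated", 7)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    out = tmp_path / "fix.csv"
    fb.generate_fixture("skewnormal-basic", 11, out_path=out)
    assert out.exists() and out.with_suffix(".json").exists()
    meta = json.loads(out.with_suffix(".json").read_text())
    assert meta["seed"] == 11


def test_separated_fixture_structure(separated_logistic):
    model, data = separated_logistic
    assert len(data) == 79
    nv = data.frame["nv"].to_numpy()
    y = data.frame["y"].to_numpy()
    assert set(np.unique(nv)) == {0.0, 1.0}
    assert np.all(y[nv == 1.0] == 1.0)  # quasi-complete separation
    assert 0 < y[nv == 0.0].mean() < 1


def test_bivariate_fixture_residual_correlation():
    data = fb.generate_fixture("bivariate-regression", 13)
    f = data.frame
    theta = data.provenance["theta"]
    eta = theta[0] + theta[1] * f["x1"] + theta[2] * f["x2"]
    corr = np.corrcoef(f["y1"] - eta, f["y2"] - eta)[0, 1]
    assert corr > 0.85  # single n = 20 draw at ρ = 0.95


def test_run_single_analysis_separated_median(separated_logistic, tmp_path):
    _, data = separated_logistic
    cfg = RunConfig(model="logistic", covariates=("nv", "pi", "eh"),
                    interest="nv", null_values=(0.0,), prior_kind="median",
                    method="exact-grid", cumulant_replicates=100,
                    grid_points=101, profile_cache_points=13, seed=11,
                    out=str(tmp_path / "rec.json"))
    record = fb.run_single_analysis(cfg, data)
    assert record.error is None
    assert np.isfinite(record.map_estimate) and record.map_estimate > 0
    assert any("monotone" in w for w in record.warnings)
    assert "0.0" in record.evalues
    assert (tmp_path / "rec.json").exists()
    reloaded = ResultRecord.from_json(tmp_path / "rec.json")
    assert reloaded.map_estimate == pytest.approx(record.map_estimate)


def test_run_single_analysis_flat_prior_structured_error(separated_logistic):
    _, data = separated_logistic
    cfg = RunConfig(model="logistic", covariates=("nv", "pi", "eh"),
                    interest="nv", null_values=(0.0,), prior_kind="flat",
                    method="exact-grid", grid_points=101, seed=1)
    record = fb.run_single_analysis(cfg, data)
    assert record.error is not None
    assert "median" in record.error["guidance"]


def test_run_single_analysis_rerun_identical(flat_exp_data):
    cfg = RunConfig(model="exponential-scale", null_values=(2.0,),
                    prior_kind="median", method="exact-grid", seed=5)
    r1 = fb.run_single_analysis(cfg, flat_exp_data)
    r2 = fb.run_single_analysis(cfg, flat_exp_data)
    d1, d2 = r1.to_json(), r2.to_json()
    d1 = json.loads(d1); d2 = json.loads(d2)
    d1.pop("timestamp"); d2.pop("timestamp")
    assert d1 == d2


def test_null_calibration_single_row_and_theory():
    res = fb.run_null_calibration("skew-normal", 3.0, 20, 1, seed=2)
    assert len(res.table) == 1
    # d = 1 theory: V(c) = c, e-values asymptotically uniform
    for c in (0.1, 0.5, 0.9):
        assert fb.evalue_null_cdf(c, d=1, h=0) == pytest.approx(c)


def test_null_calibration_ks_decreases_with_n():
    r20 = fb.run_null_calibration("skew-normal", 3.0, 20, 300, seed=17)
    r200 = fb.run_null_calibration("skew-normal", 3.0, 200, 300, seed=17)
    assert r200.ks_distance["median_score"] < r20.ks_distance["median_score"]
    assert r200.ks_distance["median_wald"] < r20.ks_distance["median_wald"]


def test_null_calibration_flat_arm_counts_monotone_samples():
    """At n = 20 a material fraction of samples is all-positive: the flat
    (unpenalized) estimate is infinite there and the e-value is recorded 0."""
    res = fb.run_null_calibration("skew-normal", 3.0, 20, 200, seed=17)
    assert res.infinite_estimates > 0
    flat_wald = res.table["flat_wald"].to_numpy()
    assert (flat_wald == 0.0).sum() >= res.infinite_estimates


def test_table1_schema_and_determinism():
    table = fb.run_table1_experiment(seed=5, sizes=(20,), n_draws=3000)
    assert len(table) == 1 * 4
    assert set(table.columns) == {"n", "prior", "map", "ev_H0_3", "ev_H0_4"}
    assert table["ev_H0_3"].between(0, 1).all()
    again = fb.run_table1_experiment(seed=5, sizes=(20,), n_draws=3000)
    pd.testing.assert_frame_equal(table, again)


def test_config_yaml_roundtrip(tmp_path):
    cfg = RunConfig(model="skew-normal", null_values=(3.0, 4.0),
                    prior_kind="median", method="score", seed=9)
    path = tmp_path / "cfg.yaml"
    import yaml
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    loaded = RunConfig.from_yaml(path)
    assert loaded == cfg
    assert loaded.digest() == cfg.digest()
    with pytest.raises(ValueError):
        RunConfig(model="no-such-model", seed=1)
    with pytest.raises(ValueError):
        RunConfig(model="skew-normal", method="abc", seed=None)


def test_load_endometrial_validates_columns(tmp_path):
    bad = tmp_path / "bad.csv"
    pd.DataFrame({"HG": [0, 1], "NV": [0, 1]}).to_csv(bad, index=False)
    with pytest.raises(ValueError):
        fb.load_endometrial(bad)
    good = tmp_path / "good.csv"
    pd.DataFrame({"HG": [0.0, 1.0, 0.0, 1.0], "NV": [0.0, 1.0, 0.0, 0.0],
                  "PI": [1.0, 2.0, 1.5, 0.5],
                  "EH": [1.0, 0.5, 2.0, 1.0]}).to_csv(good, index=False)
    data, model = fb.load_endometrial(good)
    assert model.interest_index == 1
    assert len(data) == 4


def test_cli_fit_and_fixture(tmp_path):
    from click.testing import CliRunner
    from fbstev.cli import main

    runner = CliRunner()
    fix = tmp_path / "exp.csv"
    fb.Dataset.from_values([2.0] * 10).to_csv(fix)
    result = runner.invoke(main, ["fit", "--model", "exponential-scale",
                                  "--data", str(fix), "--null", "2.0",
                                  "--prior", "median", "--seed", "3"])
    assert result.exit_code == 0, result.output
    payload = json.loads(result.output)
    assert payload["map_estimate"] == pytest.approx(60 / 29, abs=1e-4)

    out = tmp_path / "fixture.csv"
    result = runner.invoke(main, ["fixture", "--name", "logistic-separated",
                                  "--seed", "7", "--out", str(out)])
    assert result.exit_code == 0
    assert out.exists()
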