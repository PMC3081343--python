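"""Report writers and the command-line interface."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from csmsim import StrategyName, TBICategory, config_hash, default_config, run_baseline_report
from csmsim.cli import main
from csmsim.engine import simulate_cohort
from csmsim.outcomes import OutcomeClass, decompose_losses
from csmsim.reporting import decomposition_table, outcome_table

REPORT_FILES = (
    "outcomes_per_1000.csv",
    "outcomes_per_1000.txt",
    "qaly_losses_p025.csv",
    "qaly_losses_p025.txt",
    "qaly_losses_p050.csv",
    "qaly_losses_p050.txt",
    "config_used.yaml",
    "manifest.json",
)


def test_config_hash_stable_and_sensitive(calibrated_config):
    h1 = config_hash(calibrated_config)
    assert h1 == config_hash(calibrated_config.model_copy(deep=True))
    assert h1 != config_hash(calibrated_config.model_copy(update={"p_csi": 0.05}))
    assert len(h1) == 64


def test_outcome_table_values_match_results(calibrated_config):
    results = [
        simulate_cohort(cat, strat, calibrated_config, n=2_000, seed=17)
        for strat in StrategyName for cat in TBICategory
    ]
    table = outcome_table(results)
    r = next(x for x in results
             if x.strategy is StrategyName.ECR and x.category is TBICategory.STABLE)
    col = table[("ECR", "S")]
    assert col["FS"] == r.counts_per_1000[OutcomeClass.FUNCTIONAL_SURVIVAL]
    assert col["Quad"] == r.counts_per_1000[OutcomeClass.QUADRIPLEGIC]
    assert col["QALYs"] == round(r.mean_qaly, 2)


def test_decomposition_table_ranks(calibrated_config):
    rows = [
        decompose_losses("unstable", s, calibrated_config, n=2_000, seed=17)
        for s in (StrategyName.ECR, StrategyName.LCR, StrategyName.ECR_MRI, StrategyName.LCR_MRI)
    ]
    df = decomposition_table(rows)
    assert set(df["rank"]) <= {1, 2, 3, 4}
    best = df.loc[df["rank"] == 1, "net_qaly"].iloc[0]
    assert best == df["net_qaly"].max()


def test_report_bundle_complete_and_reproducible(tmp_path, calibrated_config):
    out1 = tmp_path / "a"
    out2 = tmp_path / "b"
    run_baseline_report(calibrated_config, n=2_000, seed=17, out_dir=out1)
    run_baseline_report(calibrated_config, n=2_000, seed=17, out_dir=out2)
    for name in REPORT_FILES:
        assert (out1 / name).exists()
        if name != "manifest.json":  # manifest carries a timestamp
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert manifest["seed"] == 17
    assert manifest["config_hash"] == config_hash(calibrated_config)
    assert any(p.endswith("outcomes_per_1000.csv") for p in manifest["outputs"])
    table = pd.read_csv(out1 / "outcomes_per_1000.csv", header=[0, 1], index_col=0)
    assert list(table.index) == ["FS", "Quad", "SBD", "Dead", "QALYs"]
    assert len(table.columns) == 15


def test_report_refuses_uncalibrated_config(tmp_path):
    with pytest.raises(ValueError):
        run_baseline_report(default_config(), n=100, seed=1, out_dir=tmp_path)


# -- CLI -----------------------------------------------------------------------

def test_cli_simulate(tmp_path, calibrated_config_file):
    runner = CliRunner()
    result = runner.invoke(main, [
        "simulate", "--config", str(calibrated_config_file),
        "--category", "stable", "--strategy", "ECR",
        "--n", "2000", "--seed", "17", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    payload = json.loads((tmp_path / "cohort_stable_ECR.json").read_text())
    assert payload["n"] == 2000
    assert sum(payload["raw_counts"].values()) == 2000


def test_cli_simulate_histories(tmp_path, calibrated_config_file):
    runner = CliRunner()
    result = runner.invoke(main, [
        "simulate", "--config", str(calibrated_config_file),
        "--category", "unstable", "--strategy", "LCR", "--histories",
        "--n", "500", "--seed", "17", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    hist = pd.read_csv(tmp_path / "histories_unstable_LCR.csv")
    assert len(hist) == 500
    assert {"case_id", "total_injury", "outcome", "qaly"} <= set(hist.columns)


def test_cli_report(tmp_path, calibrated_config_file):
    runner = CliRunner()
    result = runner.invoke(main, [
        "report", "--config", str(calibrated_config_file),
        "--n", "1000", "--seed", "17", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    for name in REPORT_FILES:
        assert (tmp_path / name).exists()


def test_cli_sensitivity_one_and_two_way(tmp_path, calibrated_config_file):
    runner = CliRunner()
    result = runner.invoke(main, [
        "sensitivity", "--config", str(calibrated_config_file),
        "--category", "stable", "--x", "p_csi:0:0.05:3",
        "--n", "1000", "--seed", "17", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    df = pd.read_csv(tmp_path / "one_way_stable_p_csi.csv")
    assert len(df) == 15  # 3 points x (4 strategies + benchmark)
    result = runner.invoke(main, [
        "sensitivity", "--config", str(calibrated_config_file),
        "--category", "stable", "--x", "p_csi:0:0.05:3", "--y", "collar_vap:0:0.3:3",
        "--n", "1000", "--seed", "17", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    df = pd.read_csv(tmp_path / "two_way_stable_p_csi_collar_vap.csv")
    assert len(df) == 9


def test_cli_sensitivity_bad_axis(calibrated_config_file, tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, [
        "sensitivity", "--config", str(calibrated_config_file),
        "--category", "stable", "--x", "p_csi", "--out", str(tmp_path),
    ])
    assert result.exit_code != 0


def test_cli_fixtures(tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, [
        "fixtures", "--n", "50", "--total-injury", "0.6", "--out", str(tmp_path),
    ])
    assert result.exit_code == 0, result.output
    df = pd.read_csv(tmp_path / "fixture_histories.csv")
    assert len(df) == 50
    assert (df["outcome"] == "severe_brain_disability").all()


def test_cli_invalid_config_fails(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("p_csi: -1\n")
    runner = CliRunner()
    result = runner.invoke(main, [
        "simulate", "--config", str(bad),
        "--category", "stable", "--strategy", "ECR", "--out", str(tmp_path),
    ])
    assert result.exit_code != 0
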