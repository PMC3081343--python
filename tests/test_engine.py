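"""Cohort engine: reproducibility, common random numbers, chance-tree logic."""

import numpy as np
import pytest

from csmsim import (
    CaseOverrides,
    OutcomeClass,
    StrategyName,
    TBICategory,
    generate_fixture_histories,
    simulate_case,
    simulate_cohort,
)
from csmsim.engine import ComplicationEvent, draw_cohort, histories_frame, run_strategy
from csmsim.calibration import outcome_fractions

N = 20_000
SEED = 421


def test_worked_case_late_collar_removal():
    """A stable case with forced draws: injuries 0.5311 + 0.0182 + delirium
    0.0214 sum to 0.5707, which is severe brain disability (QALY 20 x 0.1)."""
    from csmsim import default_config

    cfg = default_config()
    case = simulate_case(
        100,
        cfg.category(TBICategory.STABLE),
        cfg.strategy(StrategyName.LCR),
        cfg.valuation,
        p_csi=0.025,
        forced=CaseOverrides(
            primary=0.5311,
            secondary=0.0182,
            complication_injuries={"collar_delirium": 0.0214, "collar_iicp": 0.0, "collar_vap": 0.0},
            csi=False,
        ),
    )
    assert case.total_injury == pytest.approx(0.5707, abs=1e-12)
    assert case.outcome is OutcomeClass.SEVERE_BRAIN_DISABILITY
    assert case.qaly == 2.0
    assert not case.quadriplegia
    delirium = next(c for c in case.complications if c.source == "collar_delirium")
    assert delirium.occurred and delirium.injury == 0.0214


def test_benchmark_case_has_no_management_events(calibrated_config):
    case = simulate_case(
        0,
        calibrated_config.category(TBICategory.UNSTABLE),
        calibrated_config.strategy(StrategyName.BENCHMARK),
        calibrated_config.valuation,
        p_csi=0.5,
        seed=7,
    )
    assert all(not c.occurred and c.injury == 0.0 for c in case.complications)
    assert not case.quadriplegia  # full protection
    assert case.total_injury == case.primary_injury + case.secondary_injury


def test_forcing_unexposed_complication_rejected(calibrated_config):
    with pytest.raises(ValueError):
        simulate_case(
            0,
            calibrated_config.category(TBICategory.STABLE),
            calibrated_config.strategy(StrategyName.ECR),  # no collar exposure
            calibrated_config.valuation,
            p_csi=0.0,
            forced=CaseOverrides(complication_injuries={"collar_delirium": 0.01}),
        )


def test_complication_event_consistency():
    with pytest.raises(ValueError):
        ComplicationEvent("collar_delirium", occurred=False, injury=0.01)
    with pytest.raises(ValueError):
        ComplicationEvent("nonsense", occurred=True, injury=0.01)


def test_same_seed_reproduces_cohort(calibrated_config):
    a = simulate_cohort("stable", "LCR", calibrated_config, n=N, seed=SEED)
    b = simulate_cohort("stable", "LCR", calibrated_config, n=N, seed=SEED)
    assert a == b
    c = simulate_cohort("stable", "LCR", calibrated_config, n=N, seed=SEED + 1)
    assert c.raw_counts != a.raw_counts or c.mean_qaly != a.mean_qaly


def test_common_random_numbers_across_strategies(calibrated_config):
    """Strategies compared at one seed share the identical primary/secondary
    injuries and instability draws case-for-case."""
    frames = {}
    for strat in (StrategyName.ECR, StrategyName.LCR_MRI, StrategyName.BENCHMARK):
        _, frames[strat] = simulate_cohort(
            "unstable", strat, calibrated_config, n=2_000, seed=SEED, return_histories=True
        )
    base = frames[StrategyName.ECR]
    for other in (frames[StrategyName.LCR_MRI], frames[StrategyName.BENCHMARK]):
        np.testing.assert_array_equal(base["primary_injury"], other["primary_injury"])
        np.testing.assert_array_equal(base["secondary_injury"], other["secondary_injury"])
        np.testing.assert_array_equal(base["csi"], other["csi"])


def test_outcome_counts_conserved(calibrated_config):
    for strat in StrategyName:
        r = simulate_cohort("high_risk", strat, calibrated_config, n=N, seed=SEED)
        assert sum(r.raw_counts.values()) == N
        assert abs(sum(r.counts_per_1000.values()) - 1000) <= 1


def test_zero_instability_means_no_quadriplegia(calibrated_config):
    r, hist = simulate_cohort(
        "stable", "ECR", calibrated_config, n=N, seed=SEED, p_csi=0.0, return_histories=True
    )
    assert r.raw_counts[OutcomeClass.QUADRIPLEGIC] == 0
    assert not hist["csi"].any() and not hist["quadriplegia"].any()


@pytest.mark.parametrize("strat", [StrategyName.ECR_MRI, StrategyName.LCR_MRI, StrategyName.BENCHMARK])
def test_full_protection_prevents_all_quadriplegia(calibrated_config, strat):
    r = simulate_cohort("unstable", strat, calibrated_config, n=N, seed=SEED, p_csi=0.05)
    assert r.raw_counts[OutcomeClass.QUADRIPLEGIC] == 0


def test_quadriplegia_monotone_in_instability(calibrated_config):
    counts = [
        simulate_cohort("stable", "ECR", calibrated_config, n=N, seed=SEED, p_csi=p)
        .raw_counts[OutcomeClass.QUADRIPLEGIC]
        for p in (0.0, 0.01, 0.025, 0.05)
    ]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_degenerate_parameters_reduce_every_strategy_to_benchmark(calibrated_config):
    """With all complication probabilities and instability zeroed, every
    strategy's cases coincide with the benchmark's, case for case."""
    cfg = calibrated_config.model_copy(deep=True)
    for cp in cfg.categories.values():
        for table in (cp.collar_marginal_probs, cp.mri_probs_early, cp.mri_probs_late):
            for k in table:
                table[k] = 0.0
    _, bench = simulate_cohort(
        "stable", "BENCHMARK", cfg, n=5_000, seed=SEED, p_csi=0.0, return_histories=True
    )
    for strat in (StrategyName.ECR, StrategyName.LCR, StrategyName.ECR_MRI, StrategyName.LCR_MRI):
        _, hist = simulate_cohort(
            "stable", strat, cfg, n=5_000, seed=SEED, p_csi=0.0, return_histories=True
        )
        np.testing.assert_array_equal(hist["total_injury"], bench["total_injury"])
        np.testing.assert_array_equal(hist["outcome"], bench["outcome"])
        np.testing.assert_array_equal(hist["qaly"], bench["qaly"])


def test_ecr_quadriplegia_rate_matches_closed_form(fitted):
    """Early collar removal adds no management injury, so its quadriplegic
    fraction is p_csi x P(total < 0.56), with P from the deterministic
    convolution — the Monte Carlo estimate must agree within 3 SE."""
    cfg = fitted.config
    n = 200_000
    for cat in TBICategory:
        cp = cfg.category(cat)
        p_fs = outcome_fractions(cp.primary_injury, cp.secondary_injury)[0]
        expected = cfg.p_csi * p_fs
        r = simulate_cohort(cat, "ECR", cfg, n=n, seed=SEED)
        est = r.raw_counts[OutcomeClass.QUADRIPLEGIC] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(est - expected) < 3 * se


def test_history_table_additivity(calibrated_config):
    _, hist = simulate_cohort(
        "unstable", "LCR_MRI", calibrated_config, n=2_000, seed=SEED, return_histories=True
    )
    inj_cols = [c for c in hist.columns if c.startswith("inj_")]
    recomputed = hist["primary_injury"] + hist["secondary_injury"] + hist[inj_cols].sum(axis=1)
    np.testing.assert_allclose(hist["total_injury"], recomputed, rtol=0, atol=1e-12)
    occ_cols = [c for c in hist.columns if c.startswith("occ_")]
    for occ, inj in zip(occ_cols, inj_cols):
        assert ((hist[inj] > 0) <= hist[occ]).all()
    assert (hist["quadriplegia"] <= hist["csi"]).all()


# -- fixture generator ---------------------------------------------------------

def test_fixture_forced_totals_classify_uniformly():
    t = generate_fixture_histories(500, total_injury=0.60)
    assert (t["outcome"] == "severe_brain_disability").all()
    assert (t["qaly"] == 2.0).all()


def test_fixture_forced_quadriplegia_qaly():
    t = generate_fixture_histories(100, total_injury=0.10, quadriplegia=True)
    assert (t["outcome"] == "quadriplegic").all()
    assert (t["qaly"] == 4.0).all()
    assert t["csi"].all()  # quadriplegia implies instability


def test_fixture_empty_and_inconsistent():
    assert len(generate_fixture_histories(0)) == 0
    with pytest.raises(ValueError):
        generate_fixture_histories(10, quadriplegia=True, csi=False)
    with pytest.raises(ValueError):
        generate_fixture_histories(10, total_injury=-0.1)


def test_uncalibrated_config_refuses_to_simulate():
    from csmsim import default_config

    with pytest.raises(ValueError, match="uncalibrated"):
        simulate_cohort("stable", "ECR", default_config(), n=10, seed=0)


def test_substream_isolation(calibrated_config):
    """Per-node substreams: identical primary draws regardless of which other
    nodes are consumed (the draws object is seed-determined, not order-determined)."""
    cp = calibrated_config.category(TBICategory.STABLE)
    val = calibrated_config.valuation
    d1 = draw_cohort(cp, val, 100, seed=5)
    d2 = draw_cohort(cp, val, 100, seed=5)
    np.testing.assert_array_equal(d1.primary, d2.primary)
    np.testing.assert_array_equal(d1.u_occ["mri_vap"], d2.u_occ["mri_vap"])
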