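"""Report writers: outcome tables, loss decompositions, run manifests.

The text renderings mirror the published layout (rows of clinical outcomes
per 1,000 and mean QALYs; strategy x category columns) for eyeball
comparison; CSV/JSON versions carry the same numbers machine-readably.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import __version__
from .calibration import CalibrationResult
from .engine import CohortResult
from .outcomes import LossDecomposition
from .params import ModelConfig, OutcomeClass, StrategyName, TBICategory

log = logging.getLogger("csmsim")

_OUTCOME_ROWS = (
    (OutcomeClass.FUNCTIONAL_SURVIVAL, "FS"),
    (OutcomeClass.QUADRIPLEGIC, "Quad"),
    (OutcomeClass.SEVERE_BRAIN_DISABILITY, "SBD"),
    (OutcomeClass.DEAD, "Dead"),
)
_CAT_LABEL = {TBICategory.UNSTABLE: "US", TBICategory.HIGH_RISK: "HR", TBICategory.STABLE: "S"}
_STRATEGY_ORDER = (
    StrategyName.BENCHMARK, StrategyName.LCR, StrategyName.LCR_MRI,
    StrategyName.ECR_MRI, StrategyName.ECR,
)
_CAT_ORDER = (TBICategory.UNSTABLE, TBICategory.HIGH_RISK, TBICategory.STABLE)


def config_hash(config: ModelConfig) -> str:
    """Platform-stable SHA-256 of the canonical JSON rendering of a config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every report."""

    config_hash: str
    seed: int
    version: str
    timestamp: str
    command: str
    outputs: list[str]

    @classmethod
    def create(cls, config: ModelConfig, seed: int, outputs: Iterable[Path]) -> "RunManifest":
        return cls(
            config_hash=config_hash(config),
            seed=seed,
            version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            command=" ".join(sys.argv),
            outputs=[str(p) for p in outputs],
        )

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def outcome_table(results: Iterable[CohortResult]) -> pd.DataFrame:
    """Wide outcome table: rows FS/Quad/SBD/Dead/QALYs, (strategy, category) columns."""
    by_key = {(r.strategy, r.category): r for r in results}
    columns = pd.MultiIndex.from_tuples(
        [
            (s.value, _CAT_LABEL[c])
            for s in _STRATEGY_ORDER for c in _CAT_ORDER
            if (s, c) in by_key
        ]
    )
    rows = {}
    for oc, label in _OUTCOME_ROWS:
        rows[label] = [by_key[(StrategyName(s), _inv_cat(cl))].counts_per_1000[oc] for s, cl in columns]
    rows["QALYs"] = [round(by_key[(StrategyName(s), _inv_cat(cl))].mean_qaly, 2) for s, cl in columns]
    return pd.DataFrame(rows, index=columns).T


def _inv_cat(label: str) -> TBICategory:
    return {v: k for k, v in _CAT_LABEL.items()}[label]


def decomposition_table(rows: Iterable[LossDecomposition]) -> pd.DataFrame:
    """Loss-decomposition table with per-category rank by net QALYs."""
    recs = []
    for d in rows:
        recs.append({
            "category": d.category.value,
            "strategy": d.strategy.value,
            "net_qaly": round(d.net_qaly, 2),
            "lost_to_quad": round(d.lost_to_quad, 2),
            "lost_to_csm_injury": round(d.lost_to_csm_injury, 2),
            "total_lost": round(d.total_lost, 2),
            "benchmark_qaly": round(d.benchmark_qaly, 2),
        })
    df = pd.DataFrame(recs)
    df["rank"] = (
        df.groupby("category")["net_qaly"].rank(ascending=False, method="min").astype(int)
    )
    return df


def calibration_table(results: dict[TBICategory, CalibrationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "category": c.value,
            "policy": r.policy,
            "primary_mean": r.primary_mean,
            "primary_shape": r.primary_shape,
            "secondary_mean": r.secondary_mean,
            "secondary_shape": r.secondary_shape,
            "achieved_fs": r.achieved_fs,
            "achieved_sbd": r.achieved_sbd,
            "achieved_dead": r.achieved_dead,
            "target_fs": r.target_fs,
            "target_dead": r.target_dead,
            "residual_fs": r.residual_fs,
            "residual_dead": r.residual_dead,
        }
        for c, r in results.items()
    ])


def run_baseline_report(
    config: ModelConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    out_dir: str | Path = "results",
) -> list[Path]:
    """Write the full baseline report bundle into ``out_dir``.

    Contents: the strategy x category outcome table, the QALY loss
    decompositions at instability probabilities 0.025 and 0.05, the config
    actually used, and a run manifest.  Byte-identical across reruns at the
    same (config, n, seed).
    """
    from . import engine, outcomes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = config.cohort_size if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    if not config.is_calibrated():
        raise ValueError("config must be calibrated before reporting")
    written: list[Path] = []

    results = [
        engine.simulate_cohort(cat, strat, config, n=n, seed=seed)
        for strat in _STRATEGY_ORDER for cat in _CAT_ORDER
    ]
    table = outcome_table(results)
    table.to_csv(out / "outcomes_per_1000.csv")
    written.append(out / "outcomes_per_1000.csv")
    txt = [
        f"Expected clinical outcomes per 1,000 and QALYs (n={n:,}, seed={seed}, "
        f"p_csi={config.p_csi})",
        table.to_string(),
    ]
    (out / "outcomes_per_1000.txt").write_text("\n".join(txt) + "\n")
    written.append(out / "outcomes_per_1000.txt")

    for p_csi, tag in ((0.025, "p025"), (0.05, "p050")):
        decomp = []
        for cat in _CAT_ORDER:
            for strat in _STRATEGY_ORDER:
                if strat is StrategyName.BENCHMARK:
                    bench = outcomes.decompose_losses(cat, StrategyName.ECR, config, n=n, seed=seed, p_csi=p_csi)
                    decomp.append(outcomes.LossDecomposition(
                        category=cat, strategy=StrategyName.BENCHMARK,
                        net_qaly=bench.benchmark_qaly, lost_to_quad=0.0,
                        lost_to_csm_injury=0.0, benchmark_qaly=bench.benchmark_qaly,
                    ))
                else:
                    decomp.append(outcomes.decompose_losses(cat, strat, config, n=n, seed=seed, p_csi=p_csi))
        df = decomposition_table(decomp)
        path = out / f"qaly_losses_{tag}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        tpath = out / f"qaly_losses_{tag}.txt"
        tpath.write_text(
            f"QALY losses to quadriplegia and management injury (p_csi={p_csi})\n"
            + df.to_string(index=False) + "\n"
        )
        written.append(tpath)

    cfg_path = out / "config_used.yaml"
    config.save(cfg_path)
    written.append(cfg_path)
    manifest = RunManifest.create(config, seed, written + [out / "manifest.json"])
    manifest.write(out / "manifest.json")
    written.append(out / "manifest.json")
    log.info("baseline report written to %s (%d files)", out, len(written))
    return written
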