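"""Monte Carlo cohort engine.

Simulates cohorts of severe-TBI cases through the strategy-specific chance
trees: sample primary and secondary brain injury from the category's gamma
distributions, draw each complication the strategy is exposed to (adding a
gamma-distributed injury when it occurs), draw cervical spine instability and
its possible progression to quadriplegia, then classify the total injury and
score QALYs.

Randomness is organised as one named substream per chance node (primary,
secondary, instability, progression, and an occurrence + injury stream for
each of the six complication sources).  All draws for a cohort are generated
up front from the seed alone, so strategies compared at the same seed share
identical case-level draws (common random numbers): the only differences
between strategies are which nodes they are exposed to and how the shared
uniforms are thresholded.  This makes paired strategy differences low
variance and regression tests stable.

The module doubles as the package's synthetic-data generator:
:func:`generate_fixture_histories` emits case-history tables with arbitrary
forced components so the scoring and reporting stages can be tested in
isolation from the engine's stochasticity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import outcomes as _outcomes
from .params import (
    COMPLICATION_SOURCES,
    CategoryParams,
    ModelConfig,
    MriTiming,
    OutcomeClass,
    OutcomeValuation,
    StrategyName,
    StrategySpec,
    TBICategory,
)

# Fixed substream order; appending new nodes never perturbs existing draws.
_NODES = (
    "primary",
    "secondary",
    "csi",
    "quad_progression",
    *(f"occ_{s}" for s in COMPLICATION_SOURCES),
    *(f"inj_{s}" for s in COMPLICATION_SOURCES),
)
_NODE_INDEX = {name: i for i, name in enumerate(_NODES)}


def node_rng(seed: int, node: str) -> np.random.Generator:
    """Independent generator for one chance node of one cohort run."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_NODE_INDEX[node],))
    )


@dataclasses.dataclass(frozen=True)
class CohortDraws:
    """All random draws for one (category, seed, n) cohort, strategy-agnostic.

    Complication injuries are drawn for every case and source; a strategy
    only *uses* the ones whose occurrence fires under its exposure, which is
    what keeps draws common across strategies.
    """

    n: int
    seed: int
    category: TBICategory
    primary: np.ndarray
    secondary: np.ndarray
    u_csi: np.ndarray
    u_quad: np.ndarray
    u_occ: dict[str, np.ndarray]
    comp_injury: dict[str, np.ndarray]


def draw_cohort(
    category_params: CategoryParams,
    valuation: OutcomeValuation,
    n: int,
    seed: int,
) -> CohortDraws:
    """Generate the shared draws for ``n`` cases of one category."""
    if n < 0:
        raise ValueError("n must be non-negative")
    prim = category_params.primary_injury
    sec = category_params.secondary_injury
    k_c = valuation.complication_injury_shape
    s_c = valuation.complication_injury_mean / k_c
    return CohortDraws(
        n=n,
        seed=seed,
        category=category_params.category,
        primary=node_rng(seed, "primary").gamma(prim.shape, prim.scale, n),
        secondary=node_rng(seed, "secondary").gamma(sec.shape, sec.scale, n),
        u_csi=node_rng(seed, "csi").random(n),
        u_quad=node_rng(seed, "quad_progression").random(n),
        u_occ={s: node_rng(seed, f"occ_{s}").random(n) for s in COMPLICATION_SOURCES},
        comp_injury={s: node_rng(seed, f"inj_{s}").gamma(k_c, s_c, n) for s in COMPLICATION_SOURCES},
    )


@dataclasses.dataclass(frozen=True)
class StrategyRun:
    """Vectorized per-case results of one strategy applied to shared draws."""

    strategy: StrategyName
    occurred: dict[str, np.ndarray]  # per exposed source
    csi: np.ndarray
    quadriplegia: np.ndarray
    total_injury: np.ndarray
    outcome: np.ndarray  # OutcomeClass codes, see outcomes module
    qaly: np.ndarray


def run_strategy(
    draws: CohortDraws,
    category_params: CategoryParams,
    strategy: StrategySpec,
    valuation: OutcomeValuation,
    p_csi: float,
    prob_overrides: Optional[Mapping[str, float]] = None,
    disable_quad: bool = False,
    disable_csm: bool = False,
) -> StrategyRun:
    """Apply one strategy's chance tree to pre-generated cohort draws.

    ``prob_overrides`` maps complication source names (e.g. ``collar_delirium``)
    to replacement probabilities; it only affects sources the strategy is
    actually exposed to.  ``disable_quad`` / ``disable_csm`` switch off the
    quadriplegia mechanism or all management complications (used by the QALY
    loss decomposition and by benchmark equivalence checks).
    """
    if not 0.0 <= p_csi <= 1.0:
        raise ValueError(f"p_csi = {p_csi} outside [0, 1]")
    overrides = dict(prob_overrides or {})
    total = draws.primary + draws.secondary
    occurred: dict[str, np.ndarray] = {}
    if not disable_csm:
        for source in strategy.exposed_sources():
            p = overrides.get(source, category_params.complication_prob(source, strategy.mri_timing))
            occ = draws.u_occ[source] < p
            occurred[source] = occ
            total = total + np.where(occ, draws.comp_injury[source], 0.0)
    csi = draws.u_csi < p_csi
    if disable_quad:
        quad = np.zeros(draws.n, dtype=bool)
    else:
        quad = csi & (draws.u_quad >= strategy.quad_protection)
    outcome = _outcomes.classify_outcomes(total, quad, valuation)
    qaly = _outcomes.qaly_from_outcome(outcome, valuation)
    return StrategyRun(
        strategy=strategy.name,
        occurred=occurred,
        csi=csi,
        quadriplegia=quad,
        total_injury=total,
        outcome=outcome,
        qaly=qaly,
    )


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CohortResult:
    """Aggregate outcome counts and mean QALYs of one strategy x category run."""

    category: TBICategory
    strategy: StrategyName
    n: int
    seed: int
    raw_counts: dict[OutcomeClass, int]
    mean_qaly: float

    @property
    def counts_per_1000(self) -> dict[OutcomeClass, int]:
        return {
            k: int(np.rint(v * 1000.0 / self.n)) for k, v in self.raw_counts.items()
        }

    def to_dict(self) -> dict:
        return {
            "category": self.category.value,
            "strategy": self.strategy.value,
            "n": self.n,
            "seed": self.seed,
            "raw_counts": {k.value: v for k, v in self.raw_counts.items()},
            "counts_per_1000": {k.value: v for k, v in self.counts_per_1000.items()},
            "mean_qaly": self.mean_qaly,
        }


def aggregate(run: StrategyRun, draws: CohortDraws) -> CohortResult:
    counts = {
        oc: int((run.outcome == _outcomes.OUTCOME_CODE[oc]).sum()) for oc in OutcomeClass
    }
    mean_qaly = float(run.qaly.mean()) if draws.n else float("nan")
    return CohortResult(
        category=draws.category,
        strategy=run.strategy,
        n=draws.n,
        seed=draws.seed,
        raw_counts=counts,
        mean_qaly=mean_qaly,
    )


def histories_frame(draws: CohortDraws, run: StrategyRun) -> pd.DataFrame:
    """Full per-case history table (one row per case, documented column order)."""
    data: dict[str, np.ndarray | str] = {
        "case_id": np.arange(draws.n),
        "category": draws.category.value,
        "strategy": run.strategy.value,
        "primary_injury": draws.primary,
        "secondary_injury": draws.secondary,
    }
    for source in COMPLICATION_SOURCES:
        occ = run.occurred.get(source, np.zeros(draws.n, dtype=bool))
        data[f"occ_{source}"] = occ
        data[f"inj_{source}"] = np.where(occ, draws.comp_injury[source], 0.0)
    data["csi"] = run.csi
    data["quadriplegia"] = run.quadriplegia
    data["total_injury"] = run.total_injury
    data["outcome"] = _outcomes.decode_outcomes(run.outcome)
    data["qaly"] = run.qaly
    return pd.DataFrame(data)


def simulate_cohort(
    category: TBICategory | str,
    strategy: StrategyName | str,
    config: ModelConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    return_histories: bool = False,
    prob_overrides: Optional[Mapping[str, float]] = None,
    p_csi: Optional[float] = None,
):
    """Simulate one cohort; returns :class:`CohortResult` (and optionally the
    case-history table).  Identical (config, n, seed) give identical results.
    """
    cat = TBICategory(category)
    strat = config.strategy(strategy)
    cp = config.category(cat)
    if not (cp.primary_injury.is_calibrated and cp.secondary_injury.is_calibrated):
        raise ValueError(
            f"category {cat.value} has uncalibrated injury distributions; "
            "run calibration first (csmsim.calibration.calibrate_all)"
        )
    n = config.cohort_size if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    p = config.p_csi if p_csi is None else float(p_csi)
    draws = draw_cohort(cp, config.valuation, n, seed)
    run = run_strategy(draws, cp, strat, config.valuation, p, prob_overrides=prob_overrides)
    result = aggregate(run, draws)
    if return_histories:
        return result, histories_frame(draws, run)
    return result


# --------------------------------------------------------------------------
# Single-case walkthrough
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ComplicationEvent:
    source: str
    occurred: bool
    injury: float

    def __post_init__(self):
        if self.source not in COMPLICATION_SOURCES:
            raise ValueError(f"unknown complication source {self.source!r}")
        if self.injury < 0:
            raise ValueError("complication injury cannot be negative")
        if self.injury > 0 and not self.occurred:
            raise ValueError(f"{self.source}: injury > 0 requires occurred=True")


@dataclasses.dataclass(frozen=True)
class CaseHistory:
    """One simulated case from sampling to outcome."""

    case_id: int
    category: TBICategory
    strategy: StrategyName
    primary_injury: float
    secondary_injury: float
    complications: tuple[ComplicationEvent, ...]
    csi: bool
    quadriplegia: bool
    total_injury: float
    outcome: OutcomeClass
    qaly: float

    def __post_init__(self):
        if self.quadriplegia and not self.csi:
            raise ValueError("quadriplegia requires cervical spine instability")
        expected = self.primary_injury + self.secondary_injury + sum(
            c.injury for c in self.complications
        )
        if self.total_injury != expected:
            raise ValueError(
                f"total_injury {self.total_injury} != sum of components {expected}"
            )


@dataclasses.dataclass
class CaseOverrides:
    """Forced values for a single-case walkthrough (None = sample randomly)."""

    primary: Optional[float] = None
    secondary: Optional[float] = None
    #: source -> injury amount (> 0 means the complication occurred with that
    #: injury; 0 or absence under an exposed source means it did not occur).
    complication_injuries: Optional[dict[str, float]] = None
    csi: Optional[bool] = None
    quadriplegia: Optional[bool] = None


def simulate_case(
    case_id: int,
    category_params: CategoryParams,
    strategy: StrategySpec,
    valuation: OutcomeValuation,
    p_csi: float,
    seed: int = 0,
    forced: Optional[CaseOverrides] = None,
) -> CaseHistory:
    """Run a single case through a strategy's tree, optionally with forced draws.

    Used for worked examples and golden tests; cohort statistics should use
    :func:`simulate_cohort`, which is vectorized.
    """
    forced = forced or CaseOverrides()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(case_id),)))
    prim = category_params.primary_injury
    sec = category_params.secondary_injury
    primary = forced.primary if forced.primary is not None else float(rng.gamma(prim.shape, prim.scale))
    secondary = forced.secondary if forced.secondary is not None else float(rng.gamma(sec.shape, sec.scale))
    k_c = valuation.complication_injury_shape
    s_c = valuation.complication_injury_mean / k_c
    exposed = strategy.exposed_sources()
    forced_inj = dict(forced.complication_injuries or {})
    for src in forced_inj:
        if src not in COMPLICATION_SOURCES:
            raise ValueError(f"unknown complication source {src!r}")
        if src not in exposed and forced_inj[src] > 0:
            raise ValueError(f"strategy {strategy.name.value} is not exposed to {src}")
    events = []
    total = primary + secondary
    for source in COMPLICATION_SOURCES:
        if source not in exposed:
            events.append(ComplicationEvent(source, False, 0.0))
            continue
        if source in forced_inj:
            inj = float(forced_inj[source])
            occ = inj > 0
        else:
            p = category_params.complication_prob(source, strategy.mri_timing)
            occ = bool(rng.random() < p)
            inj = float(rng.gamma(k_c, s_c)) if occ else 0.0
        events.append(ComplicationEvent(source, occ, inj))
        total += inj
    csi = forced.csi if forced.csi is not None else bool(rng.random() < p_csi)
    if forced.quadriplegia is not None:
        quad = bool(forced.quadriplegia)
        if quad and not csi:
            raise ValueError("cannot force quadriplegia without cervical spine instability")
    else:
        quad = csi and bool(rng.random() >= strategy.quad_protection)
    outcome = _outcomes.classify_outcome(total, quad, valuation)
    qaly = _outcomes.case_qaly(_outcomes.base_class(total, valuation), quad, valuation)
    return CaseHistory(
        case_id=case_id,
        category=category_params.category,
        strategy=strategy.name,
        primary_injury=primary,
        secondary_injury=secondary,
        complications=tuple(events),
        csi=csi,
        quadriplegia=quad,
        total_injury=total,
        outcome=outcome,
        qaly=qaly,
    )


# --------------------------------------------------------------------------
# Fixture generator
# --------------------------------------------------------------------------

def generate_fixture_histories(
    n: int,
    seed: int = 0,
    category: TBICategory | str = TBICategory.STABLE,
    strategy: StrategyName | str = StrategyName.BENCHMARK,
    valuation: Optional[OutcomeValuation] = None,
    total_injury: Optional[float | Iterable[float]] = None,
    quadriplegia: Optional[bool | Iterable[bool]] = None,
    csi: Optional[bool | Iterable[bool]] = None,
) -> pd.DataFrame:
    """Emit a case-history table with forced components for stage isolation.

    Totals can be pinned to a scalar or per-case values (recorded entirely as
    primary injury, with zero secondary and complication injury so the
    additivity invariant holds).  Quadriplegia can be forced on or off; forcing
    it on also forces instability (quadriplegia implies instability).  The
    outcome and QALY columns are recomputed from the forced components with
    the same scoring code the engine uses.
    """
    valuation = valuation or OutcomeValuation()
    rng = np.random.default_rng(seed)
    if total_injury is None:
        totals = rng.gamma(4.0, 0.52 / 4.0, n)
    else:
        totals = np.broadcast_to(np.asarray(total_injury, dtype=float), (n,)).copy()
    if np.any(totals < 0):
        raise ValueError("total injury cannot be negative")
    if quadriplegia is None:
        quad = np.zeros(n, dtype=bool)
    else:
        quad = np.broadcast_to(np.asarray(quadriplegia, dtype=bool), (n,)).copy()
    if csi is None:
        csi_arr = quad.copy()
    else:
        csi_arr = np.broadcast_to(np.asarray(csi, dtype=bool), (n,)).copy()
    if np.any(quad & ~csi_arr):
        raise ValueError("inconsistent forcing: quadriplegia without cervical spine instability")
    outcome = _outcomes.classify_outcomes(totals, quad, valuation)
    qaly = _outcomes.qaly_from_outcome(outcome, valuation)
    data: dict[str, np.ndarray | str] = {
        "case_id": np.arange(n),
        "category": TBICategory(category).value,
        "strategy": StrategyName(strategy).value,
        "primary_injury": totals,
        "secondary_injury": np.zeros(n),
    }
    for source in COMPLICATION_SOURCES:
        data[f"occ_{source}"] = np.zeros(n, dtype=bool)
        data[f"inj_{source}"] = np.zeros(n)
    data["csi"] = csi_arr
    data["quadriplegia"] = quad
    data["total_injury"] = totals
    data["outcome"] = _outcomes.decode_outcomes(outcome)
    data["qaly"] = qaly
    return pd.DataFrame(data)
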