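"""Outcome classification, QALY scoring, and the QALY loss decomposition.

Classification: total brain injury below 0.56 on the relative scale is
functional survival (FS), strictly above 0.65 death, the closed band in
between severe brain disability (SBD).  Quadriplegia is recorded as the
case's outcome class only when the brain outcome alone would have been FS --
the published outcome tables satisfy "quadriplegics = instability share of
benchmark FS" exactly, while FS drops by the same amount and SBD/death are
unchanged, which identifies this convention.  Valuation still honours
quadriplegia in every stratum through the lesser-utility rule: a quadriplegic
case takes the lower of its brain-outcome utility and the quadriplegia
utility, with the life expectancy of that governing state.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .params import ModelConfig, OutcomeClass, OutcomeValuation, StrategyName, TBICategory

#: Stable integer coding used in vectorized paths and history tables.
OUTCOME_CODE = {
    OutcomeClass.FUNCTIONAL_SURVIVAL: 0,
    OutcomeClass.QUADRIPLEGIC: 1,
    OutcomeClass.SEVERE_BRAIN_DISABILITY: 2,
    OutcomeClass.DEAD: 3,
}
_CODE_TO_OUTCOME = {v: k for k, v in OUTCOME_CODE.items()}
_OUTCOME_VALUES = np.array([o.value for o in sorted(OUTCOME_CODE, key=OUTCOME_CODE.get)])


def base_class(total_injury: float, valuation: OutcomeValuation) -> OutcomeClass:
    """Brain-injury outcome ignoring quadriplegia (boundaries belong to SBD)."""
    if total_injury < 0:
        raise ValueError("total injury cannot be negative")
    if total_injury < valuation.fs_upper:
        return OutcomeClass.FUNCTIONAL_SURVIVAL
    if total_injury > valuation.death_lower:
        return OutcomeClass.DEAD
    return OutcomeClass.SEVERE_BRAIN_DISABILITY


def classify_outcome(
    total_injury: float, quadriplegia: bool, valuation: OutcomeValuation
) -> OutcomeClass:
    """Reported outcome class of one case."""
    base = base_class(total_injury, valuation)
    if quadriplegia and base is OutcomeClass.FUNCTIONAL_SURVIVAL:
        return OutcomeClass.QUADRIPLEGIC
    return base


def classify_outcomes(
    totals: np.ndarray, quadriplegia: np.ndarray, valuation: OutcomeValuation
) -> np.ndarray:
    """Vectorized :func:`classify_outcome`; returns integer codes."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("total injury cannot be negative")
    codes = np.full(totals.shape, OUTCOME_CODE[OutcomeClass.SEVERE_BRAIN_DISABILITY], dtype=np.int8)
    fs = totals < valuation.fs_upper
    codes[fs] = OUTCOME_CODE[OutcomeClass.FUNCTIONAL_SURVIVAL]
    codes[totals > valuation.death_lower] = OUTCOME_CODE[OutcomeClass.DEAD]
    codes[fs & np.asarray(quadriplegia, dtype=bool)] = OUTCOME_CODE[OutcomeClass.QUADRIPLEGIC]
    return codes


def decode_outcomes(codes: np.ndarray) -> np.ndarray:
    return _OUTCOME_VALUES[np.asarray(codes, dtype=int)]


def case_qaly(
    outcome_base: OutcomeClass, quadriplegia: bool, valuation: OutcomeValuation
) -> float:
    """QALYs of one case under the lesser-utility rule.

    Without quadriplegia: life expectancy x utility of the brain outcome.
    With quadriplegia: the state with the lesser utility (brain outcome vs
    quadriplegia) governs both the utility and the life expectancy.
    """
    if not quadriplegia:
        return valuation.class_qaly(outcome_base)
    governing = min(
        (outcome_base, OutcomeClass.QUADRIPLEGIC), key=lambda o: valuation.utility[o]
    )
    return valuation.class_qaly(governing)


def qaly_from_outcome(codes: np.ndarray, valuation: OutcomeValuation) -> np.ndarray:
    """Vectorized QALYs from reported outcome codes.

    The reported class already carries the quadriplegia information that
    matters for valuation: quadriplegia-with-FS is coded QUADRIPLEGIC, while
    quadriplegia with SBD or death is valued identically to SBD or death by
    the lesser-utility rule.
    """
    table = np.array([
        valuation.class_qaly(_CODE_TO_OUTCOME[i]) for i in range(len(OUTCOME_CODE))
    ])
    return table[np.asarray(codes, dtype=int)]


def cohort_mean_qaly_from_counts(
    counts: dict[OutcomeClass, float], valuation: OutcomeValuation
) -> float:
    """Mean QALYs implied by outcome counts (per-cohort or per-1,000)."""
    n = sum(counts.values())
    return sum(valuation.class_qaly(oc) * c for oc, c in counts.items()) / n


# --------------------------------------------------------------------------
# QALY loss decomposition
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LossDecomposition:
    """Net QALYs of a strategy and their split into the two loss channels.

    ``lost_to_quad`` is the QALY cost of quadriplegia (full model vs the same
    model with progression disabled); ``lost_to_csm_injury`` the cost of
    management-complication brain injury (progression-disabled model vs the
    benchmark).  By construction net + lost_to_quad + lost_to_csm_injury =
    benchmark exactly; ``additivity_residual`` records the deviation when the
    fields come from independently rounded published figures instead.
    """

    category: TBICategory
    strategy: StrategyName
    net_qaly: float
    lost_to_quad: float
    lost_to_csm_injury: float
    benchmark_qaly: float

    @property
    def total_lost(self) -> float:
        return self.lost_to_quad + self.lost_to_csm_injury

    @property
    def additivity_residual(self) -> float:
        return self.benchmark_qaly - (self.net_qaly + self.total_lost)

    def validate(self, atol: float = 0.005) -> "LossDecomposition":
        """Check the defining identities to within reporting rounding."""
        if abs(self.additivity_residual) > atol:
            raise ValueError(
                f"{self.strategy.value}/{self.category.value}: net + losses "
                f"!= benchmark (residual {self.additivity_residual:+.4f} > {atol})"
            )
        return self


def decompose_losses(
    category: TBICategory | str,
    strategy: StrategyName | str,
    config: ModelConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    p_csi: Optional[float] = None,
) -> LossDecomposition:
    """Decompose a strategy's QALY shortfall against the benchmark.

    Four paired simulations on common random numbers: the full model, the
    model with quadriplegia progression disabled, and the benchmark (both
    channels disabled).  lost_to_quad = QALY(quad off) - QALY(full);
    lost_to_csm_injury = QALY(benchmark) - QALY(quad off).
    """
    from . import engine  # local import to avoid cycle

    cat = TBICategory(category)
    strat = config.strategy(strategy)
    cp = config.category(cat)
    n = config.cohort_size if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    p = config.p_csi if p_csi is None else float(p_csi)
    draws = engine.draw_cohort(cp, config.valuation, n, seed)
    full = engine.run_strategy(draws, cp, strat, config.valuation, p)
    no_quad = engine.run_strategy(draws, cp, strat, config.valuation, p, disable_quad=True)
    bench = engine.run_strategy(
        draws, cp, strat, config.valuation, p, disable_quad=True, disable_csm=True
    )
    q_full = float(full.qaly.mean())
    q_noquad = float(no_quad.qaly.mean())
    q_bench = float(bench.qaly.mean())
    return LossDecomposition(
        category=cat,
        strategy=strat.name,
        net_qaly=q_full,
        lost_to_quad=q_noquad - q_full,
        lost_to_csm_injury=q_bench - q_noquad,
        benchmark_qaly=q_bench,
    )
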