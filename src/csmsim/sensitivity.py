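"""One-way and two-way sensitivity analyses over chance-node probabilities.

Sweeps vary one or two probabilities while holding everything else at its
baseline value, rank the strategies by mean QALY at each point, and (for the
two-way case) map the preference regions: which strategy is QALY-best at each
(x, y) probability coordinate.  All points and all strategies share one set
of common random numbers per category, so region boundaries are not blurred
by independent Monte Carlo noise.

Varied parameters and their semantics:

``p_csi``
    probability of cervical spine instability (affects every strategy's
    instability node; the benchmark and the 100%-protected MRI strategies are
    invariant to it by construction).
``collar_delirium``, ``collar_iicp``, ``collar_vap``
    marginal collar complication probabilities; only the late-removal arms
    (LCR, LCR/MRI) are exposed to collar sources, so early-removal arms are
    unaffected.
``mri_transport``, ``mri_iicp``, ``mri_vap``
    MRI complication probabilities, applied to the active MRI column of each
    MRI strategy (early for ECR/MRI, late for LCR/MRI).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .params import ModelConfig, StrategyName, TBICategory

SWEEPABLE = (
    "p_csi",
    "collar_delirium",
    "collar_iicp",
    "collar_vap",
    "mri_transport",
    "mri_iicp",
    "mri_vap",
)

#: Strategies compared in preference-region maps (the benchmark would
#: trivially dominate and is reported separately in one-way tables).
MANAGEMENT_STRATEGIES = (
    StrategyName.ECR,
    StrategyName.LCR,
    StrategyName.ECR_MRI,
    StrategyName.LCR_MRI,
)


@dataclasses.dataclass(frozen=True)
class SensitivityAxis:
    """One varied probability: parameter name, range and grid resolution."""

    parameter: str
    lo: float
    hi: float
    steps: int = 21

    def __post_init__(self):
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"unknown parameter {self.parameter!r}; choose from {SWEEPABLE}")
        if not 0.0 <= self.lo < self.hi <= 1.0:
            raise ValueError(f"need 0 <= lo < hi <= 1, got [{self.lo}, {self.hi}]")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.steps)


def _evaluate_point(
    draws: engine.CohortDraws,
    config: ModelConfig,
    category: TBICategory,
    strategies: Sequence[StrategyName],
    settings: dict[str, float],
) -> dict[StrategyName, float]:
    """Mean QALY of each strategy at one parameter setting, on shared draws."""
    cp = config.category(category)
    p_csi = settings.get("p_csi", config.p_csi)
    overrides = {k: v for k, v in settings.items() if k != "p_csi"}
    out = {}
    for name in strategies:
        run = engine.run_strategy(
            draws, cp, config.strategy(name), config.valuation, p_csi,
            prob_overrides=overrides,
        )
        out[name] = float(run.qaly.mean())
    return out


def one_way(
    category: TBICategory | str,
    axis: SensitivityAxis,
    config: ModelConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    strategies: Optional[Sequence[StrategyName]] = None,
) -> pd.DataFrame:
    """Sweep one parameter; returns a long table (value, strategy, mean_qaly, rank).

    Ranks are 1 = highest mean QALY, computed within the management
    strategies; the benchmark is included in the table with rank 0.
    """
    cat = TBICategory(category)
    n = config.cohort_size if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    strategies = tuple(strategies or MANAGEMENT_STRATEGIES)
    draws = engine.draw_cohort(config.category(cat), config.valuation, n, seed)
    rows = []
    for value in axis.values:
        qalys = _evaluate_point(
            draws, config, cat, (*strategies, StrategyName.BENCHMARK),
            {axis.parameter: float(value)},
        )
        managed = {s: qalys[s] for s in strategies if s is not StrategyName.BENCHMARK}
        order = sorted(managed, key=managed.get, reverse=True)
        rank = {s: i + 1 for i, s in enumerate(order)}
        rank[StrategyName.BENCHMARK] = 0
        for s, q in qalys.items():
            rows.append({
                "parameter": axis.parameter,
                "value": float(value),
                "strategy": s.value,
                "mean_qaly": q,
                "rank": rank[s],
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class SensitivityRegionMap:
    """Preference regions of a two-way sweep.

    ``best_strategy[i, j]`` is the QALY-best management strategy at
    ``(x_axis.values[j], y_axis.values[i])`` (row = y, column = x, the usual
    image convention); ``qaly_grid`` holds each strategy's mean-QALY surface;
    ``ties`` lists grid points where the top two strategies are within the
    tie tolerance (indifference boundaries run through these points).
    """

    category: TBICategory
    x_axis: SensitivityAxis
    y_axis: SensitivityAxis
    strategies: tuple[StrategyName, ...]
    best_strategy: np.ndarray
    qaly_grid: dict[StrategyName, np.ndarray]
    ties: tuple[tuple[float, float], ...]
    tie_tolerance: float
    n: int
    seed: int

    def best_at(self, x: float, y: float) -> StrategyName:
        """Best strategy at the grid point nearest to (x, y)."""
        j = int(np.argmin(np.abs(self.x_axis.values - x)))
        i = int(np.argmin(np.abs(self.y_axis.values - y)))
        return StrategyName(self.best_strategy[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: x, y, per-strategy mean QALYs, best, tie flag."""
        tie_set = {(round(x, 12), round(y, 12)) for x, y in self.ties}
        rows = []
        for i, y in enumerate(self.y_axis.values):
            for j, x in enumerate(self.x_axis.values):
                row = {self.x_axis.parameter: float(x), self.y_axis.parameter: float(y)}
                for s in self.strategies:
                    row[f"qaly_{s.value}"] = float(self.qaly_grid[s][i, j])
                row["best"] = str(self.best_strategy[i, j])
                row["tie"] = (round(float(x), 12), round(float(y), 12)) in tie_set
                rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Render the preference regions (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [s.value for s in self.strategies]
        index = {name: k for k, name in enumerate(names)}
        img = np.vectorize(index.get)(self.best_strategy)
        ax.imshow(
            img, origin="lower", aspect="auto",
            extent=(self.x_axis.lo, self.x_axis.hi, self.y_axis.lo, self.y_axis.hi),
            cmap="tab10", vmin=0, vmax=max(9, len(names) - 1), alpha=0.6,
        )
        ax.set_xlabel(self.x_axis.parameter)
        ax.set_ylabel(self.y_axis.parameter)
        ax.set_title(f"QALY-best strategy, {self.category.value} category")
        for name in names:
            mask = self.best_strategy == name
            if mask.any():
                ii, jj = np.nonzero(mask)
                ax.annotate(
                    name,
                    (self.x_axis.values[jj].mean(), self.y_axis.values[ii].mean()),
                    ha="center", va="center", fontsize=9, weight="bold",
                )
        return ax


def two_way(
    category: TBICategory | str,
    x_axis: SensitivityAxis,
    y_axis: SensitivityAxis,
    config: ModelConfig,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    tie_tolerance: float = 0.02,
) -> SensitivityRegionMap:
    """Map the QALY-best strategy over a two-parameter probability grid."""
    if x_axis.parameter == y_axis.parameter:
        raise ValueError("the two axes must vary distinct parameters")
    cat = TBICategory(category)
    n = config.cohort_size if n is None else int(n)
    seed = config.seed if seed is None else int(seed)
    draws = engine.draw_cohort(config.category(cat), config.valuation, n, seed)
    strategies = MANAGEMENT_STRATEGIES
    shape = (y_axis.steps, x_axis.steps)
    qaly_grid = {s: np.empty(shape) for s in strategies}
    best = np.empty(shape, dtype=object)
    ties = []
    for i, y in enumerate(y_axis.values):
        for j, x in enumerate(x_axis.values):
            qalys = _evaluate_point(
                draws, config, cat, strategies,
                {x_axis.parameter: float(x), y_axis.parameter: float(y)},
            )
            for s, q in qalys.items():
                qaly_grid[s][i, j] = q
            order = sorted(qalys, key=qalys.get, reverse=True)
            best[i, j] = order[0].value
            if qalys[order[0]] - qalys[order[1]] < tie_tolerance:
                ties.append((float(x), float(y)))
    return SensitivityRegionMap(
        category=cat,
        x_axis=x_axis,
        y_axis=y_axis,
        strategies=strategies,
        best_strategy=best,
        qaly_grid=qaly_grid,
        ties=tuple(ties),
        tie_tolerance=tie_tolerance,
        n=n,
        seed=seed,
    )
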