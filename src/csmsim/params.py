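"""Typed, validated model parameters for the cervical-spine-management model.

Every quantity the simulation consumes lives here: the three traumatic-brain-
injury (TBI) severity categories with their gamma injury distributions, the
per-strategy complication exposures, the outcome thresholds on the relative
brain-injury scale, and the QALY valuation (life expectancies and utilities).

Parameters can be loaded from a YAML/JSON config file whose key tree mirrors
the field names of :class:`ModelConfig`; absent keys take the package
defaults, unknown keys are rejected (they are almost always typos in
probability names).
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class TBICategory(str, enum.Enum):
    """Severity category of traumatic brain injury.

    ``unstable`` cases have intracranial hypertension, hypoxemia, hypotension
    or early ventilator-associated pneumonia; ``high_risk`` cases have GCS 3-5
    or age > 45 without those insults; ``stable`` cases have GCS 6-8, age
    15-45 and none of the insults.
    """

    UNSTABLE = "unstable"
    HIGH_RISK = "high_risk"
    STABLE = "stable"


class OutcomeClass(str, enum.Enum):
    """The four terminal health outcomes."""

    FUNCTIONAL_SURVIVAL = "functional_survival"
    QUADRIPLEGIC = "quadriplegic"
    SEVERE_BRAIN_DISABILITY = "severe_brain_disability"
    DEAD = "dead"


class StrategyName(str, enum.Enum):
    """Cervical spine management strategies plus the idealized benchmark."""

    ECR = "ECR"
    LCR = "LCR"
    ECR_MRI = "ECR_MRI"
    LCR_MRI = "LCR_MRI"
    BENCHMARK = "BENCHMARK"


class MriTiming(str, enum.Enum):
    NONE = "none"
    EARLY = "early"
    LATE = "late"


#: Collar complication sources (probabilities are *marginal*: the excess of
#: late over early collar removal, so early-removal arms carry none).
COLLAR_SOURCES = ("delirium", "iicp", "vap")
#: MRI complication sources.
MRI_SOURCES = ("transport", "iicp", "vap")

#: All six complication sources in their fixed stream order.
COMPLICATION_SOURCES = (
    "collar_delirium",
    "collar_iicp",
    "collar_vap",
    "mri_transport",
    "mri_iicp",
    "mri_vap",
)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


Probability = Field(ge=0.0, le=1.0)


class InjuryDistribution(_StrictModel):
    """Gamma distribution of an injury amount on the relative brain-injury scale.

    The mean is a fixed model input; the shape is either supplied explicitly
    or determined by calibration against the benchmark outcome counts
    (:mod:`csmsim.calibration`).  ``scale`` is always ``mean / shape``.
    """

    mean: float = Field(gt=0.0)
    shape: Optional[float] = Field(default=None, gt=0.0)

    @property
    def scale(self) -> float:
        if self.shape is None:
            raise ValueError(
                "injury distribution has no shape parameter; run calibration "
                "or set `shape` explicitly"
            )
        return self.mean / self.shape

    @property
    def is_calibrated(self) -> bool:
        return self.shape is not None


class CategoryParams(_StrictModel):
    """Per-category injury distributions and complication probabilities."""

    category: TBICategory
    primary_injury: InjuryDistribution
    secondary_injury: InjuryDistribution
    #: Marginal (late-minus-early) collar complication probabilities.
    collar_marginal_probs: dict[str, float]
    #: MRI complication probabilities when the scan is done early / late.
    mri_probs_early: dict[str, float]
    mri_probs_late: dict[str, float]

    @model_validator(mode="after")
    def _check_probs(self) -> "CategoryParams":
        for name, table, keys in (
            ("collar_marginal_probs", self.collar_marginal_probs, COLLAR_SOURCES),
            ("mri_probs_early", self.mri_probs_early, MRI_SOURCES),
            ("mri_probs_late", self.mri_probs_late, MRI_SOURCES),
        ):
            if set(table) != set(keys):
                raise ValueError(f"{name} must have exactly the keys {keys}, got {sorted(table)}")
            for k, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k}] = {p} is not a probability in [0, 1]")
        return self

    def complication_prob(self, source: str, mri_timing: MriTiming) -> float:
        """Probability of one of the six complication sources under an exposure.

        Collar sources use the marginal table; MRI sources use the column for
        the strategy's scan timing (0 when the strategy has no MRI).
        """
        kind, _, name = source.partition("_")
        if kind == "collar":
            return self.collar_marginal_probs[name]
        if mri_timing is MriTiming.NONE:
            return 0.0
        table = self.mri_probs_early if mri_timing is MriTiming.EARLY else self.mri_probs_late
        return table[name]


class StrategySpec(_StrictModel):
    """One management strategy: its complication exposure and collar efficacy.

    ``quad_protection`` is the probability that cervical spine instability is
    kept from progressing to quadriplegia under this strategy.
    """

    name: StrategyName
    uses_collar_marginals: bool
    mri_timing: MriTiming
    quad_protection: float = Probability

    def exposed_sources(self) -> tuple[str, ...]:
        """The complication sources this strategy can experience."""
        out: list[str] = []
        if self.uses_collar_marginals:
            out += [f"collar_{s}" for s in COLLAR_SOURCES]
        if self.mri_timing is not MriTiming.NONE:
            out += [f"mri_{s}" for s in MRI_SOURCES]
        return tuple(out)


class OutcomeValuation(_StrictModel):
    """Outcome thresholds and the QALY valuation of the four outcomes.

    A total brain injury below ``fs_upper`` is functional survival, above
    ``death_lower`` death, in between (inclusive on both ends) severe brain
    disability.  QALY = life expectancy x utility at the assumed age of 40;
    with quadriplegia the *lesser* of the two state utilities governs.
    """

    fs_upper: float = 0.56
    death_lower: float = 0.65
    life_expectancy_years: dict[OutcomeClass, float] = Field(
        default_factory=lambda: {
            OutcomeClass.FUNCTIONAL_SURVIVAL: 39.5,
            OutcomeClass.QUADRIPLEGIC: 20.0,
            OutcomeClass.SEVERE_BRAIN_DISABILITY: 20.0,
            OutcomeClass.DEAD: 0.0,
        }
    )
    utility: dict[OutcomeClass, float] = Field(
        default_factory=lambda: {
            OutcomeClass.FUNCTIONAL_SURVIVAL: 0.9,
            OutcomeClass.QUADRIPLEGIC: 0.2,
            OutcomeClass.SEVERE_BRAIN_DISABILITY: 0.1,
            OutcomeClass.DEAD: 0.0,
        }
    )
    assumed_age: float = 40.0
    #: Mean of the gamma distribution of injury added by any single complication.
    complication_injury_mean: float = Field(default=0.025, gt=0.0)
    #: Shape of that gamma (not identified by the printed outputs; see docs).
    complication_injury_shape: float = Field(default=4.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "OutcomeValuation":
        if not self.fs_upper < self.death_lower:
            raise ValueError("fs_upper must be below death_lower")
        for table, name in ((self.life_expectancy_years, "life_expectancy_years"), (self.utility, "utility")):
            if set(table) != set(OutcomeClass):
                raise ValueError(f"{name} must value all four outcomes")
        u = self.utility
        if not (
            u[OutcomeClass.FUNCTIONAL_SURVIVAL]
            > u[OutcomeClass.QUADRIPLEGIC]
            > u[OutcomeClass.SEVERE_BRAIN_DISABILITY]
            > u[OutcomeClass.DEAD]
        ):
            raise ValueError("utilities must be strictly ordered FS > quad > SBD > dead")
        for k, v in u.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility[{k.value}] out of [0, 1]")
        for k, v in self.life_expectancy_years.items():
            if v < 0:
                raise ValueError(f"life_expectancy_years[{k.value}] negative")
        return self

    def class_qaly(self, outcome: OutcomeClass) -> float:
        """QALYs of one outcome class (lesser-utility rule already encoded in
        the class itself: ``QUADRIPLEGIC`` means quadriplegia with an otherwise
        functional survivor)."""
        return self.life_expectancy_years[outcome] * self.utility[outcome]


class CalibrationSettings(_StrictModel):
    """How the unidentified gamma shape parameters are chosen.

    ``weighted``: both shapes free, weighted least squares on the benchmark
    (FS, dead) fractions with QALY-impact weights (default).
    ``cv_matched``: secondary shape equals primary shape (equal coefficient of
    variation), one free parameter.
    ``fixed_secondary``: secondary shape pinned at ``fixed_secondary_shape``.
    """

    policy: str = "weighted"
    fixed_secondary_shape: float = Field(default=4.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CalibrationSettings":
        if self.policy not in ("weighted", "cv_matched", "fixed_secondary"):
            raise ValueError(f"unknown calibration policy {self.policy!r}")
        return self


class ModelConfig(_StrictModel):
    """Complete parameterization of the decision model."""

    categories: dict[TBICategory, CategoryParams]
    strategies: dict[StrategyName, StrategySpec]
    valuation: OutcomeValuation = Field(default_factory=OutcomeValuation)
    #: Probability of cervical spine instability from isolated ligament damage.
    p_csi: float = Field(default=0.025, ge=0.0, le=1.0)
    cohort_size: int = Field(default=100_000, ge=1)
    seed: int = 0
    calibration: CalibrationSettings = Field(default_factory=CalibrationSettings)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if set(self.categories) != set(TBICategory):
            raise ValueError("config must define exactly the three TBI categories")
        if set(self.strategies) != set(StrategyName):
            raise ValueError("config must define all four strategies plus the benchmark")
        for cat, cp in self.categories.items():
            if cp.category is not cat:
                raise ValueError(f"category key {cat.value} does not match entry {cp.category.value}")
        for name, sp in self.strategies.items():
            if sp.name is not name:
                raise ValueError(f"strategy key {name.value} does not match entry {sp.name.value}")
        bench = self.strategies[StrategyName.BENCHMARK]
        if bench.uses_collar_marginals or bench.mri_timing is not MriTiming.NONE:
            raise ValueError("the benchmark carries no management exposure by definition")
        return self

    # -- convenience accessors -------------------------------------------------

    def category(self, cat: TBICategory | str) -> CategoryParams:
        return self.categories[TBICategory(cat)]

    def strategy(self, name: StrategyName | str) -> StrategySpec:
        return self.strategies[StrategyName(name)]

    def is_calibrated(self) -> bool:
        return all(
            c.primary_injury.is_calibrated and c.secondary_injury.is_calibrated
            for c in self.categories.values()
        )

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))


class ConfigError(ValueError):
    """A config file failed to parse or validate."""


# --------------------------------------------------------------------------
# Defaults
# --------------------------------------------------------------------------

# Baseline parameter tables, ordered (unstable, high_risk, stable).
_COLLAR_MARGINALS = {
    "delirium": (0.22, 0.22, 0.22),
    "iicp": (0.36, 0.00, 0.00),
    "vap": (0.14, 0.14, 0.14),
}
_MRI_EARLY = {
    "transport": (0.14, 0.14, 0.09),
    "iicp": (0.72, 0.00, 0.00),
    "vap": (0.18, 0.18, 0.18),
}
_MRI_LATE = {
    "transport": (0.14, 0.14, 0.09),
    "iicp": (0.00, 0.00, 0.00),
    "vap": (0.18, 0.18, 0.18),
}
_INJURY_MEANS = {  # (primary, secondary) gamma means per category
    TBICategory.UNSTABLE: (0.5000, 0.0750),
    TBICategory.HIGH_RISK: (0.7000, 0.0200),
    TBICategory.STABLE: (0.5000, 0.0200),
}
_QUAD_PROTECTION = {
    StrategyName.ECR: 0.0,
    StrategyName.LCR: 0.8,
    StrategyName.ECR_MRI: 1.0,
    StrategyName.LCR_MRI: 1.0,
    StrategyName.BENCHMARK: 1.0,
}


def default_config() -> ModelConfig:
    """The baseline parameterization (shapes left for calibration)."""
    order = (TBICategory.UNSTABLE, TBICategory.HIGH_RISK, TBICategory.STABLE)
    categories = {}
    for i, cat in enumerate(order):
        pm, sm = _INJURY_MEANS[cat]
        categories[cat] = CategoryParams(
            category=cat,
            primary_injury=InjuryDistribution(mean=pm),
            secondary_injury=InjuryDistribution(mean=sm),
            collar_marginal_probs={k: v[i] for k, v in _COLLAR_MARGINALS.items()},
            mri_probs_early={k: v[i] for k, v in _MRI_EARLY.items()},
            mri_probs_late={k: v[i] for k, v in _MRI_LATE.items()},
        )
    strategies = {
        StrategyName.ECR: StrategySpec(
            name=StrategyName.ECR, uses_collar_marginals=False,
            mri_timing=MriTiming.NONE, quad_protection=_QUAD_PROTECTION[StrategyName.ECR]),
        StrategyName.LCR: StrategySpec(
            name=StrategyName.LCR, uses_collar_marginals=True,
            mri_timing=MriTiming.NONE, quad_protection=_QUAD_PROTECTION[StrategyName.LCR]),
        StrategyName.ECR_MRI: StrategySpec(
            name=StrategyName.ECR_MRI, uses_collar_marginals=False,
            mri_timing=MriTiming.EARLY, quad_protection=_QUAD_PROTECTION[StrategyName.ECR_MRI]),
        StrategyName.LCR_MRI: StrategySpec(
            name=StrategyName.LCR_MRI, uses_collar_marginals=True,
            mri_timing=MriTiming.LATE, quad_protection=_QUAD_PROTECTION[StrategyName.LCR_MRI]),
        StrategyName.BENCHMARK: StrategySpec(
            name=StrategyName.BENCHMARK, uses_collar_marginals=False,
            mri_timing=MriTiming.NONE, quad_protection=_QUAD_PROTECTION[StrategyName.BENCHMARK]),
    }
    return ModelConfig(categories=categories, strategies=strategies)


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        here = f"{path}.{k}" if path else str(k)
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(out[k], v, here)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> ModelConfig:
    """Load a config file, filling absent fields with the package defaults.

    The file is YAML (JSON is a YAML subset).  Unknown keys raise
    :class:`ConfigError` naming the offending key; out-of-range probabilities
    raise with the field path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    merged = _deep_merge(default_config().to_dict(), raw)
    try:
        return ModelConfig.model_validate(merged)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"invalid config {path}: {exc}") from exc
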