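"""Synthetic micro survey records and macro regional panels with known truth.

The micro generator draws binary covariates X1..X12 independently at
configurable prevalences, draws the composite healthy-aging outcome from a
logistic model ``Y ~ Bernoulli(expit(b0 + b.X))``, splits that outcome into
the four criterion statuses, and then *constructs* item-level responses
(ADL grades, depression grades, activity counts, disability, chronic count)
that re-score exactly to the drawn statuses.  Each returned record carries
its ground-truth profile so downstream recovery is directly testable.

The macro generator emits a region x year panel of the raw ingredients of
the regional factors (schooling years, urbanization rate, households,
population, old-age dependency ratio) with per-region multiplicative trend
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .ha_criteria import (
    COVARIATE_NAMES,
    DEPRESSION_CUTOFF,
    MAX_CHRONIC,
    HAProfile,
    MicroRecord,
    N_ACTIVITIES,
    N_ADL_ITEMS,
    N_DEPRESSION_ITEMS,
)
from .fw_index import RegionalPanel

__all__ = [
    "MicroGenConfig",
    "MacroGenConfig",
    "SyntheticMicroRecord",
    "generate_micro",
    "generate_macro",
    "DEFAULT_PREVALENCES",
    "DEFAULT_TRUE_BETAS",
    "FINAL_STEP_ORS",
]

# Cohort margins of the reference survey (share coded 1 per covariate).
DEFAULT_PREVALENCES: dict[str, float] = {
    "X1": 348 / 795,   # male
    "X2": 307 / 795,   # younger (50-60)
    "X3": 177 / 795,   # urban
    "X4": 397 / 795,   # literate
    "X5": 602 / 795,   # married
    "X6": 528 / 795,   # expects long-term care from children
    "X7": 617 / 795,   # children literate
    "X8": 312 / 795,   # children co-resident
    "X9": 624 / 795,   # children married
    "X10": 467 / 795,  # children in good health
    "X11": 409 / 795,  # children own housing
    "X12": 400 / 795,  # provides grandchild care
}

# Final-model odds ratios used as default generating effects.
FINAL_STEP_ORS: dict[str, float] = {
    "X2": 1.554,
    "X3": 1.573,
    "X4": 0.663,
    "X6": 1.697,
    "X7": 0.497,
}

# intercept calibrated so the default cohort's composite prevalence ~ 17.2%
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "intercept": -1.533,
    **{x: 0.0 for x in COVARIATE_NAMES},
    **{x: math.log(orr) for x, orr in FINAL_STEP_ORS.items()},
}

#: P(criterion passes) for a respondent whose composite outcome is 0.
DEFAULT_NONHA_PASS = (0.65, 0.82, 0.58, 0.45)


@dataclass(frozen=True)
class MicroGenConfig:
    """Configuration of the micro record generator."""

    n_respondents: int
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    true_betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS)
    )
    item_noise: float = 0.0
    nonha_pass_probs: tuple[float, float, float, float] = DEFAULT_NONHA_PASS
    seed: int = 0

    def __post_init__(self):
        if self.n_respondents < 1:
            raise ConfigurationError("n_respondents must be >= 1")
        for name in COVARIATE_NAMES:
            p = self.covariate_prevalences.get(name)
            if p is None:
                raise ConfigurationError(f"missing prevalence for {name}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence for {name} must lie in [0,1], got {p}")
        if "intercept" not in self.true_betas:
            raise ConfigurationError("true_betas must include 'intercept'")
        if self.item_noise < 0:
            raise ConfigurationError("item_noise must be >= 0")
        if len(self.nonha_pass_probs) != 4 or not all(
            0.0 <= q <= 1.0 for q in self.nonha_pass_probs
        ):
            raise ConfigurationError("nonha_pass_probs must be four probabilities")
        if all(q >= 1.0 for q in self.nonha_pass_probs):
            raise ConfigurationError(
                "nonha_pass_probs all 1 cannot produce a failing criterion"
            )


@dataclass(frozen=True)
class SyntheticMicroRecord(MicroRecord):
    """A generated record that carries its ground-truth profile."""

    truth: HAProfile = None  # type: ignore[assignment]


def record_from_statuses(
    rid: str,
    *,
    y1: bool = True,
    y2: bool = True,
    y3: bool = True,
    y4: bool = True,
    x: Mapping[str, int] | None = None,
) -> SyntheticMicroRecord:
    """Deterministically build a record that scores to the given statuses.

    Useful for constructing exact-count cohorts in tests and reports.
    """
    covs = {name: 0 for name in COVARIATE_NAMES}
    if x:
        covs.update(x)
    return SyntheticMicroRecord(
        id=rid,
        adl_grades=(1,) * N_ADL_ITEMS if y2 else (1,) * (N_ADL_ITEMS - 1) + (3,),
        depression_grades=(1,) * N_DEPRESSION_ITEMS if y3 else (3,) * N_DEPRESSION_ITEMS,
        activity_counts=(1, 1) + (0,) * (N_ACTIVITIES - 2) if y4 else (0,) * N_ACTIVITIES,
        disabled=not y1,
        n_chronic=0,
        x=covs,
        truth=HAProfile(id=rid, y1_physical=y1, y2_adl=y2, y3_mental=y3, y4_social=y4),
    )


def _draw_statuses(rng: np.random.Generator, y: np.ndarray, pass_probs) -> np.ndarray:
    """Per-record criterion statuses consistent with the composite outcome."""
    n = y.shape[0]
    statuses = np.ones((n, 4), dtype=bool)
    idx = np.flatnonzero(~y)
    probs = np.asarray(pass_probs)
    # rejection sampling: a non-HA respondent must fail at least one criterion
    while idx.size:
        draw = rng.random((idx.size, 4)) < probs
        statuses[idx] = draw
        idx = idx[draw.all(axis=1)]
    return statuses


def generate_micro(config: MicroGenConfig) -> list[SyntheticMicroRecord]:
    """Generate micro records whose re-scored criteria equal the drawn truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    prev = np.array([config.covariate_prevalences[x] for x in COVARIATE_NAMES])
    X = (rng.random((n, len(COVARIATE_NAMES))) < prev).astype(np.int8)

    beta = np.array([config.true_betas.get(x, 0.0) for x in COVARIATE_NAMES])
    eta = float(config.true_betas["intercept"]) + X @ beta
    p = expit(eta)
    y = rng.random(n) < p
    statuses = _draw_statuses(rng, y, config.nonha_pass_probs)
    y1, y2, y3, y4 = statuses.T

    # respondent-level severity shift induces within-scale item correlation
    shift = (
        rng.standard_normal(n) * config.item_noise if config.item_noise > 0 else np.zeros(n)
    )
    p_high = np.clip(0.35 + shift, 0.0, 1.0)[:, None]

    # Y2 (ADL): pass -> all grades in {1,2}; fail -> at least one grade >= 3
    adl = 1 + (rng.random((n, N_ADL_ITEMS)) < p_high).astype(np.int16)
    fail2 = np.flatnonzero(~y2)
    cols = rng.integers(0, N_ADL_ITEMS, size=fail2.size)
    adl[fail2, cols] = rng.integers(3, 5, size=fail2.size)

    # Y3 (depression): pass -> grades in {1,2} (sum <= 20 by construction);
    # fail -> grades in {2,3} with at least one 3 (sum >= 21)
    dep = 1 + (rng.random((n, N_DEPRESSION_ITEMS)) < p_high).astype(np.int16)
    fail3 = np.flatnonzero(~y3)
    dep[fail3] = 2 + (rng.random((fail3.size, N_DEPRESSION_ITEMS)) < p_high[fail3]).astype(
        np.int16
    )
    all_two = fail3[dep[fail3].sum(axis=1) <= DEPRESSION_CUTOFF]
    dep[all_two, rng.integers(0, N_DEPRESSION_ITEMS, size=all_two.size)] = 3

    # Y4 (social): pass -> >= 2 distinct activities; fail -> <= 1
    acts = np.zeros((n, N_ACTIVITIES), dtype=np.int16)
    n_active = np.where(
        y4,
        2 + rng.binomial(N_ACTIVITIES - 2, 0.25, size=n),
        rng.integers(0, 2, size=n),
    )
    order = np.argsort(rng.random((n, N_ACTIVITIES)), axis=1)
    chosen = order < n_active[:, None]
    acts[chosen] = 1 + rng.poisson(2.0, size=int(chosen.sum()))

    # Y1 (physical): pass -> not disabled, <= 2 chronic; fail -> disabled or >= 3
    disabled = np.zeros(n, dtype=bool)
    n_chronic = rng.integers(0, MAX_CHRONIC + 1, size=n)
    fail1 = np.flatnonzero(~y1)
    mode_disabled = rng.random(fail1.size) < 0.5
    disabled[fail1[mode_disabled]] = True
    many = fail1[~mode_disabled]
    n_chronic[many] = rng.integers(MAX_CHRONIC + 1, 9, size=many.size)

    width = len(str(n))
    records = []
    for i in range(n):
        rid = f"r{i:0{width}d}"
        truth = HAProfile(
            id=rid,
            y1_physical=bool(y1[i]),
            y2_adl=bool(y2[i]),
            y3_mental=bool(y3[i]),
            y4_social=bool(y4[i]),
        )
        records.append(
            SyntheticMicroRecord(
                id=rid,
                adl_grades=tuple(adl[i]),
                depression_grades=tuple(dep[i]),
                activity_counts=tuple(acts[i]),
                disabled=bool(disabled[i]),
                n_chronic=int(n_chronic[i]),
                x={name: int(X[i, j]) for j, name in enumerate(COVARIATE_NAMES)},
                truth=truth,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Macro panel generator
# ---------------------------------------------------------------------------

#: national-mean levels of the raw factor ingredients
DEFAULT_FACTOR_MEANS = {
    "schooling_years": 8.0,
    "urbanization_rate": 0.50,
    "dependency_ratio": 0.14,
    "persons_per_household": 3.1,
}


@dataclass(frozen=True)
class MacroGenConfig:
    """Configuration of the regional panel generator.

    ``trend_profiles`` maps a region name to a per-ingredient multiplicative
    growth factor applied once per period (year step).  Unlisted regions
    drift with noise only.  ``region_scale`` maps a region to a static
    multiplicative offset from the national mean.
    """

    n_regions: int
    years: Sequence[int]
    factor_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_MEANS)
    )
    trend_profiles: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    region_scale: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion: float = 0.05
    base_population: float = 5e7
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        years = list(self.years)
        if not years:
            raise ConfigurationError("years must be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigurationError("years must be strictly increasing")
        for k, v in self.factor_means.items():
            if v <= 0:
                raise ConfigurationError(f"factor mean {k} must be > 0, got {v}")
        for k in DEFAULT_FACTOR_MEANS:
            if k not in self.factor_means:
                raise ConfigurationError(f"missing factor mean: {k}")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")

    def region_names(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]


_INGREDIENTS = ("schooling_years", "urbanization_rate", "dependency_ratio", "persons_per_household")


def generate_macro(config: MacroGenConfig) -> RegionalPanel:
    """Generate a regional panel; national aggregates derive from the rows."""
    rng = np.random.default_rng(config.seed)
    regions = config.region_names()
    rows = []
    for r, region in enumerate(regions):
        scale = config.region_scale.get(region, {})
        trend = config.trend_profiles.get(region, {})
        base = {
            k: config.factor_means[k]
            * float(scale.get(k, 1.0))
            * float(np.exp(rng.normal(0.0, config.dispersion)))
            for k in _INGREDIENTS
        }
        population = config.base_population * float(
            np.exp(rng.normal(0.0, config.dispersion))
        )
        for t, year in enumerate(config.years):
            vals = {k: base[k] * float(trend.get(k, 1.0)) ** t for k in _INGREDIENTS}
            rows.append(
                {
                    "region": region,
                    "year": int(year),
                    "mean_schooling_years": vals["schooling_years"],
                    "urbanization_rate": vals["urbanization_rate"],
                    "population": population,
                    "households": population / vals["persons_per_household"],
                    "old_age_dependency_ratio": vals["dependency_ratio"],
                }
            )
    return RegionalPanel(pd.DataFrame(rows))
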