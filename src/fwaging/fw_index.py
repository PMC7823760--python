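"""The F-W composite regional index.

Micro-model odds ratios become macro weights (``w = |ln OR|``), regional
factors are ratios of a region's ingredient to the national value, and the
composite score is ``sum(F_i * w_i)``, optionally normalized so a region
sitting exactly at the national average scores 100.

Factor map:

* F1 aging level      — reciprocal old-age dependency ratio vs national
* F2 education level  — mean schooling years vs national
* F3 urbanization     — urbanization rate vs national
* F4 family care      — persons per household vs national (default mode),
  or raw household count vs national (``household_mode='households'``)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, FactorLookupError, UndefinedStatisticError

__all__ = [
    "FWWeights",
    "RegionalPanel",
    "RegionalIndex",
    "derive_weights",
    "compute_factors",
    "fw_score",
    "score_panel",
    "classify_trend",
    "aggregate_zones",
    "plot_indices",
    "load_zone_map",
    "DEFAULT_ZONES_FILE",
]

PANEL_COLUMNS = [
    "region",
    "year",
    "mean_schooling_years",
    "urbanization_rate",
    "households",
    "population",
    "old_age_dependency_ratio",
]

DEFAULT_ZONES_FILE = Path(__file__).parent / "data" / "zones.yaml"

#: share of the education weight contributed by the respondent's own
#: education (X4) versus the grown children's education (X7)
EDUCATION_MIX = (1.0 / 3.0, 2.0 / 3.0)


@dataclass(frozen=True)
class FWWeights:
    """Macro factor weights derived from the retained micro model."""

    w1_aging: float
    w2_urbanization: float
    w3_education: float
    w4_family_care: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative real, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "w1_aging": self.w1_aging,
            "w2_urbanization": self.w2_urbanization,
            "w3_education": self.w3_education,
            "w4_family_care": self.w4_family_care,
        }

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w1_aging, self.w2_urbanization, self.w3_education, self.w4_family_care)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "FWWeights":
        return cls(**json.loads(Path(path).read_text()))


def derive_weights(
    final_fit,
    *,
    precision: int | None = None,
    signed: bool = False,
) -> FWWeights:
    """Map the retained micro fit to macro weights.

    Each weight is ``|ln OR|`` of the corresponding term (signed logs with
    ``signed=True``); the education weight blends the respondent's own and
    the grown children's education as ``|b_X4|/3 + |b_X7|*2/3``.  With
    ``precision`` the per-term logs are rounded first, mirroring a report
    that prints weights at fixed precision.

    Raises
    ------
    FactorLookupError
        If the fit lacks any of X2, X3, X4, X6, X7.
    """
    needed = ("X2", "X3", "X4", "X6", "X7")
    missing = [t for t in needed if t not in final_fit.terms]
    if missing:
        raise FactorLookupError(f"final fit lacks terms: {missing}")
    logs = {}
    for t in needed:
        b = math.log(final_fit.or_[final_fit.terms.index(t)])
        if not signed:
            b = abs(b)
        if precision is not None:
            b = round(b, precision)
        logs[t] = b
    a4, a7 = EDUCATION_MIX
    return FWWeights(
        w1_aging=logs["X2"],
        w2_urbanization=logs["X3"],
        w3_education=a4 * logs["X4"] + a7 * logs["X7"],
        w4_family_care=logs["X6"],
    )


class RegionalPanel:
    """Region x year panel of raw factor ingredients.

    National aggregates are population-weighted means (household counts are
    summed) derived from the member rows, unless a ``national`` frame
    indexed by year with the same value columns is supplied.
    """

    def __init__(self, frame: pd.DataFrame, national: pd.DataFrame | None = None):
        missing = set(PANEL_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"panel lacks columns: {sorted(missing)}")
        if frame.empty:
            raise EmptyInputError("panel has no rows")
        vals = frame[PANEL_COLUMNS[2:]]
        if (vals.to_numpy(dtype=float) <= 0).any():
            raise ValueError("all panel ingredient values must be > 0")
        self.frame = frame.reset_index(drop=True)
        self._national = national

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.frame["year"].unique())

    def row(self, region: str, year: int) -> pd.Series:
        sel = self.frame[(self.frame["region"] == region) & (self.frame["year"] == int(year))]
        if sel.empty:
            raise FactorLookupError(f"no panel row for region={region!r}, year={year}")
        return sel.iloc[0]

    def national(self, year: int) -> pd.Series:
        """National ingredient values for one year."""
        if self._national is not None:
            try:
                return self._national.loc[int(year)]
            except KeyError as exc:
                raise FactorLookupError(f"no national row for year {year}") from exc
        sel = self.frame[self.frame["year"] == int(year)]
        if sel.empty:
            raise FactorLookupError(f"no panel rows for year {year}")
        pop = sel["population"].to_numpy(dtype=float)
        w = pop / pop.sum()
        return pd.Series(
            {
                "mean_schooling_years": float(sel["mean_schooling_years"] @ w),
                "urbanization_rate": float(sel["urbanization_rate"] @ w),
                "households": float(sel["households"].sum()),
                "population": float(pop.sum()),
                "old_age_dependency_ratio": float(sel["old_age_dependency_ratio"] @ w),
            }
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, national_csv=None) -> "RegionalPanel":
        national = None
        if national_csv is not None:
            national = pd.read_csv(national_csv).set_index("year")
        return cls(pd.read_csv(path), national=national)


@dataclass(frozen=True)
class RegionalIndex:
    """Factor values and composite score for one region-year."""

    region: str
    year: int
    f1_aging: float
    f2_urbanization: float
    f3_education: float
    f4_family_care: float
    score_raw: float
    score_100: float

    def factors(self) -> tuple[float, float, float, float]:
        return (self.f1_aging, self.f2_urbanization, self.f3_education, self.f4_family_care)


def compute_factors(
    panel: RegionalPanel,
    region: str,
    year: int,
    *,
    household_mode: str = "persons_per_household",
) -> tuple[float, float, float, float]:
    """Regional factor ratios (F1 aging, F2 urbanization, F3 education,
    F4 family care) relative to the national value.

    Raises
    ------
    UndefinedStatisticError
        On a zero denominator.
    """
    if household_mode not in ("persons_per_household", "households"):
        raise ConfigurationError(f"unknown household_mode: {household_mode!r}")
    row = panel.row(region, year)
    nat = panel.national(year)
    for series, label in ((row, region), (nat, "national")):
        if any(series[c] == 0 for c in PANEL_COLUMNS[2:] if c in series.index):
            raise UndefinedStatisticError(f"zero ingredient for {label} in {year}")

    f1 = (1.0 / row["old_age_dependency_ratio"]) / (1.0 / nat["old_age_dependency_ratio"])
    f2 = row["urbanization_rate"] / nat["urbanization_rate"]
    f3 = row["mean_schooling_years"] / nat["mean_schooling_years"]
    if household_mode == "persons_per_household":
        f4 = (row["population"] / row["households"]) / (nat["population"] / nat["households"])
    else:
        f4 = row["households"] / nat["households"]
    return (float(f1), float(f2), float(f3), float(f4))


def fw_score(
    factors: Sequence[float],
    weights: FWWeights,
    *,
    normalize: bool = True,
    region: str = "",
    year: int = 0,
) -> RegionalIndex:
    """Composite score ``sum(F_i w_i)``; ``score_100 = 100*raw/sum(w)``.

    Raises
    ------
    UndefinedStatisticError
        If all weights are zero.
    """
    f1, f2, f3, f4 = (float(f) for f in factors)
    if min(f1, f2, f3, f4) <= 0:
        raise ValueError("factors must be positive")
    total = weights.total
    if total == 0:
        raise UndefinedStatisticError("sum of weights is zero")
    raw = float(np.dot([f1, f2, f3, f4], weights.as_tuple()))
    score_100 = 100.0 * raw / total if normalize else raw
    return RegionalIndex(
        region=region,
        year=int(year),
        f1_aging=f1,
        f2_urbanization=f2,
        f3_education=f3,
        f4_family_care=f4,
        score_raw=raw,
        score_100=score_100,
    )


def score_panel(
    panel: RegionalPanel,
    weights: FWWeights,
    *,
    household_mode: str = "persons_per_household",
    normalize: bool = True,
) -> list[RegionalIndex]:
    """Score every region-year in the panel."""
    out = []
    for region in panel.regions:
        for year in panel.years:
            factors = compute_factors(panel, region, year, household_mode=household_mode)
            out.append(
                fw_score(factors, weights, normalize=normalize, region=region, year=year)
            )
    return out


def classify_trend(scores: Mapping[int, float] | Sequence[float]) -> int:
    """Trend type over three ordered time points.

    1 = up then down, 2 = down then down, 3 = down then up, 4 = up then up.
    A flat segment counts as "down".
    """
    if isinstance(scores, Mapping):
        years = sorted(scores)
        vals = [scores[y] for y in years]
    else:
        vals = list(scores)
    if len(vals) != 3:
        raise FactorLookupError(f"classify_trend needs exactly three points, got {len(vals)}")
    up1 = vals[1] > vals[0]
    up2 = vals[2] > vals[1]
    if up1 and not up2:
        return 1
    if not up1 and not up2:
        return 2
    if not up1 and up2:
        return 3
    return 4


def trend_table(indices: Iterable[RegionalIndex]) -> pd.DataFrame:
    """Per-region trend type from each region's three-year score series."""
    frame = indices_to_frame(indices)
    rows = []
    for region, grp in frame.groupby("region", sort=True):
        series = dict(zip(grp["year"].astype(int), grp["score_100"]))
        rows.append({"region": region, "trend_type": classify_trend(series)})
    return pd.DataFrame(rows)


def aggregate_zones(
    indices: Iterable[RegionalIndex],
    zone_map: Mapping[str, str],
) -> pd.DataFrame:
    """Unweighted mean score per zone per year, plus the across-year mean.

    Returns a frame with one row per zone: one column per year and a
    ``period_mean`` column (mean of the yearly zone means).

    Raises
    ------
    ConfigurationError
        If any scored region is missing from ``zone_map``.
    """
    frame = indices_to_frame(indices)
    if frame.empty:
        raise EmptyInputError("no indices to aggregate")
    unmapped = sorted(set(frame["region"]) - set(zone_map))
    if unmapped:
        raise ConfigurationError(f"regions missing from zone map: {unmapped}")
    frame = frame.assign(zone=frame["region"].map(zone_map))
    wide = (
        frame.groupby(["zone", "year"], sort=True)["score_100"]
        .mean()
        .unstack("year")
    )
    wide["period_mean"] = wide.mean(axis=1)
    return wide.reset_index()


def indices_to_frame(indices: Iterable[RegionalIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": ix.region,
                "year": ix.year,
                "f1_aging": ix.f1_aging,
                "f2_urbanization": ix.f2_urbanization,
                "f3_education": ix.f3_education,
                "f4_family_care": ix.f4_family_care,
                "score_raw": ix.score_raw,
                "score_100": ix.score_100,
            }
            for ix in indices
        ],
        columns=[
            "region",
            "year",
            "f1_aging",
            "f2_urbanization",
            "f3_education",
            "f4_family_care",
            "score_raw",
            "score_100",
        ],
    )


def load_zone_map(path=None) -> dict[str, str]:
    """Region -> zone mapping from a YAML file (default: packaged mapping)."""
    import yaml

    raw = yaml.safe_load(Path(path or DEFAULT_ZONES_FILE).read_text())
    zones = raw["zones"] if isinstance(raw, dict) and "zones" in raw else raw
    out = {}
    for zone, members in zones.items():
        for region in members:
            out[str(region)] = str(zone)
    return out


def plot_indices(indices: Sequence[RegionalIndex], out_dir, *, fmt: str = "png") -> list[Path]:
    """Per-year bar charts and a ranked average chart; returns written paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = indices_to_frame(indices)
    if frame.empty:
        warnings.warn("plot_indices called with no indices; nothing written")
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * frame["region"].nunique() + 2), 4))
    for year, grp in frame.groupby("year"):
        grp = grp.sort_values("region")
        ax.plot(grp["region"], grp["score_100"], marker="o", label=str(year))
    ax.axhline(100.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("composite score (baseline 100)")
    ax.legend(title="year")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    path = out_dir / f"scores_by_year.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    avg = (
        frame.groupby("region")["score_100"]
        .mean()
        .sort_values(ascending=False)
    )
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(avg) + 2), 4))
    ax.bar(avg.index, avg.to_numpy())
    ax.axhline(100.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("average composite score")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    path = out_dir / f"ranked_average.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)
    return written
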