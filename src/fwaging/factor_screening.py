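"""Factor screening: descriptive tables, chi-square tests, block logistic fits.

Candidate factors are screened one at a time against the composite outcome
with Pearson's chi-square (no continuity correction), then jointly in two
multivariable logistic blocks: the respondent's own characteristics
("first family", X1-X6) and the grown children's characteristics ("second
family", X7-X12).  Per-criterion regressions run the six headline factors
against each of the four criteria separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (
    EmptyInputError,
    FactorLookupError,
    RankDeficiencyError,
    SeparationError,
    UndefinedStatisticError,
)
from .ha_criteria import COVARIATE_NAMES, HAProfile, MicroRecord

__all__ = [
    "ContingencyTable2x2",
    "LogisticFit",
    "crosstab",
    "chi_square",
    "fit_logistic",
    "block_regressions",
    "criterion_regressions",
    "descriptive_table",
    "FIRST_FAMILY",
    "SECOND_FAMILY",
    "CRITERION_TERMS",
]

FIRST_FAMILY = ("X1", "X2", "X3", "X4", "X5", "X6")
SECOND_FAMILY = ("X7", "X8", "X9", "X10", "X11", "X12")
CRITERION_TERMS = ("X2", "X3", "X4", "X6", "X7", "X10")

Z_95 = 1.96  # Wald 95% CI multiplier


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows = factor level (1 then 0), columns = non-HA / HA."""

    a: int  # level 1, non-HA
    b: int  # level 1, HA
    c: int  # level 0, non-HA
    d: int  # level 0, HA

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row0, non-HA, HA) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def has_zero_margin(self) -> bool:
        return min(self.margins) == 0


def crosstab(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    factor: str,
    *,
    outcome: str = "y_ha",
) -> ContingencyTable2x2:
    """Cross-tabulate one binary factor against an outcome criterion.

    Records and profiles are aligned by id; a mismatch is an error.
    """
    if not records or not profiles:
        raise EmptyInputError("crosstab requires records and profiles")
    if factor not in COVARIATE_NAMES:
        raise FactorLookupError(f"unknown factor: {factor!r}")
    if outcome not in HAProfile.CRITERIA:
        raise FactorLookupError(f"unknown outcome: {outcome!r}")
    by_id = {p.id: p for p in profiles}
    a = b = c = d = 0
    for r in records:
        p = by_id.get(r.id)
        if p is None:
            raise FactorLookupError(f"no profile for record id {r.id!r}")
        level = r.x[factor]
        ha = bool(getattr(p, outcome))
        if level == 1:
            b += ha
            a += not ha
        else:
            d += ha
            c += not ha
    t = ContingencyTable2x2(a, b, c, d)
    if t.has_zero_margin:
        warnings.warn(f"crosstab for {factor}: zero margin, chi-square undefined")
    return t


def chi_square(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df=1.

    ``chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``.

    Raises
    ------
    UndefinedStatisticError
        If any margin is zero.
    """
    if t.has_zero_margin:
        raise UndefinedStatisticError("chi-square undefined: zero margin")
    r1, r0, c0, c1 = t.margins
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    stat = num / (r1 * r0 * c0 * c1)
    p = float(stats.chi2.sf(stat, df=1))
    return (float(stat), p)


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: per-term estimates plus the intercept."""

    terms: tuple[str, ...]
    beta: tuple[float, ...]
    se: tuple[float, ...]
    or_: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    p: tuple[float, ...]
    intercept: float
    intercept_se: float
    converged: bool
    n_obs: int
    outcome: str = "y_ha"

    def term(self, name: str) -> dict[str, float]:
        """All statistics for one term."""
        try:
            i = self.terms.index(name)
        except ValueError as exc:
            raise FactorLookupError(f"term {name!r} not in fit") from exc
        return {
            "beta": self.beta[i],
            "se": self.se[i],
            "or": self.or_[i],
            "ci_low": self.ci95[i][0],
            "ci_high": self.ci95[i][1],
            "p": self.p[i],
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "or": self.or_,
                "ci_low": [lo for lo, _ in self.ci95],
                "ci_high": [hi for _, hi in self.ci95],
                "p": self.p,
            }
        )

    def to_dict(self) -> dict:
        d = self.summary_frame().to_dict(orient="list")
        d.update(
            intercept=self.intercept,
            intercept_se=self.intercept_se,
            converged=self.converged,
            n_obs=self.n_obs,
            outcome=self.outcome,
        )
        return d


def _design(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    terms: Sequence[str],
    outcome: str,
) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise EmptyInputError("no records")
    if len(records) != len(profiles):
        raise ValueError("records and profiles differ in length")
    by_id = {p.id: p for p in profiles}
    X = np.empty((len(records), len(terms)), dtype=float)
    y = np.empty(len(records), dtype=float)
    for i, r in enumerate(records):
        p = by_id.get(r.id)
        if p is None:
            raise FactorLookupError(f"no profile for record id {r.id!r}")
        for j, t in enumerate(terms):
            X[i, j] = r.x[t]
        y[i] = float(getattr(p, outcome))
    return X, y


_SEPARATION_BETA = 30.0  # |beta| beyond this is a numerical-separation signal


def fit_logistic_arrays(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str],
    *,
    outcome: str = "y_ha",
) -> LogisticFit:
    """Maximum-likelihood logistic fit on a prebuilt design matrix."""
    y = np.asarray(y, dtype=float)
    n_classes = np.unique(y).size
    if n_classes < 2:
        raise UndefinedStatisticError("outcome has a single class; fit undefined")
    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {Xc.shape[1]} columns (terms {list(terms)})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian during fit: {exc}") from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    runaway = {
        name: float(params[j + 1])
        for j, name in enumerate(terms)
        if abs(params[j + 1]) > _SEPARATION_BETA
    }
    if runaway:
        raise SeparationError(
            f"quasi-separation: runaway coefficients {runaway}", diagnostics=runaway
        )
    beta = tuple(float(b) for b in params[1:])
    se = tuple(float(s) for s in bse[1:])
    pvals = tuple(float(p) for p in np.asarray(res.pvalues)[1:])
    return LogisticFit(
        terms=tuple(terms),
        beta=beta,
        se=se,
        or_=tuple(math.exp(b) for b in beta),
        ci95=tuple(
            (math.exp(b - Z_95 * s), math.exp(b + Z_95 * s)) for b, s in zip(beta, se)
        ),
        p=pvals,
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_obs=int(y.shape[0]),
        outcome=outcome,
    )


def fit_logistic(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    terms: Sequence[str],
    *,
    outcome: str = "y_ha",
) -> LogisticFit:
    """Logistic regression of an outcome criterion on named binary factors.

    Raises
    ------
    SeparationError
        On perfect or quasi separation (with diagnostics).
    RankDeficiencyError
        If the design matrix (with intercept) is rank deficient.
    """
    unknown = [t for t in terms if t not in COVARIATE_NAMES]
    if unknown:
        raise FactorLookupError(f"unknown terms: {unknown}")
    X, y = _design(records, profiles, terms, outcome)
    return fit_logistic_arrays(X, y, terms, outcome=outcome)


def block_regressions(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
) -> tuple[LogisticFit, LogisticFit]:
    """Multivariable fits of the first family (X1-X6) and second (X7-X12)."""
    first = fit_logistic(records, profiles, FIRST_FAMILY)
    second = fit_logistic(records, profiles, SECOND_FAMILY)
    return first, second


def criterion_regressions(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    terms: Sequence[str] = CRITERION_TERMS,
) -> dict[str, LogisticFit]:
    """One fit per criterion Y1..Y4 with the named terms."""
    out = {}
    for crit in ("y1_physical", "y2_adl", "y3_mental", "y4_social"):
        out[crit] = fit_logistic(records, profiles, terms, outcome=crit)
    return out


def descriptive_table(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    factors: Sequence[str] = COVARIATE_NAMES,
) -> pd.DataFrame:
    """Per-factor counts by outcome plus the chi-square screen."""
    rows = []
    for factor in factors:
        t = crosstab(records, profiles, factor)
        if t.has_zero_margin:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = chi_square(t)
        rows.append(
            {
                "factor": factor,
                "n_level1": t.a + t.b,
                "n_level0": t.c + t.d,
                "non_ha_level1": t.a,
                "ha_level1": t.b,
                "non_ha_level0": t.c,
                "ha_level0": t.d,
                "chi_square": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
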