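"""Backward stepwise elimination over the candidate factors.

Starting from the full model, the term with the largest Wald p-value above
the stay threshold is dropped (one per step, ties broken toward the term
latest in candidate order), the model is refit, and the procedure stops
once every remaining term is below the threshold.  Removed terms never
re-enter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import FactorLookupError, FWAgingError, StepwiseError
from .factor_screening import LogisticFit, fit_logistic
from .ha_criteria import COVARIATE_NAMES, HAProfile, MicroRecord

__all__ = ["Step", "StepwiseTrace", "backward_stepwise", "linear_predictor"]


@dataclass(frozen=True)
class Step:
    """One elimination step: the fit of the current term set, and the term
    removed from it (``None`` on the final step)."""

    terms: tuple[str, ...]
    fit: LogisticFit
    removed: str | None
    removal_p: float | None


@dataclass(frozen=True)
class StepwiseTrace:
    steps: tuple[Step, ...]

    @property
    def final(self) -> LogisticFit:
        return self.steps[-1].fit

    @property
    def removal_order(self) -> tuple[str, ...]:
        return tuple(s.removed for s in self.steps if s.removed is not None)

    def to_frame(self) -> pd.DataFrame:
        """Wide trace: one column per step, ``OR (SE)`` strings per term."""
        all_terms = list(self.steps[0].terms)
        data = {}
        for k, step in enumerate(self.steps, start=1):
            col = {}
            for t in all_terms:
                if t in step.terms:
                    d = step.fit.term(t)
                    col[t] = f"{d['or']:.3f} ({d['se']:.3f})"
                else:
                    col[t] = ""
            col["_cons"] = f"{step.fit.intercept:.3f} ({step.fit.intercept_se:.3f})"
            data[f"step{k}"] = col
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "terms": list(s.terms),
                    "removed": s.removed,
                    "removal_p": s.removal_p,
                    "fit": s.fit.to_dict(),
                }
                for s in self.steps
            ],
            "final_terms": list(self.final.terms),
        }


def backward_stepwise(
    records: Sequence[MicroRecord],
    profiles: Sequence[HAProfile],
    candidates: Sequence[str] = COVARIATE_NAMES,
    alpha_stay: float = 0.05,
    *,
    outcome: str = "y_ha",
) -> StepwiseTrace:
    """Backward elimination at the given stay threshold.

    Raises
    ------
    StepwiseError
        If a fit fails mid-way; carries ``partial_trace``.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if not 0.0 <= alpha_stay <= 1.0:
        raise ValueError("alpha_stay must lie in [0, 1]")
    current = list(candidates)
    steps: list[Step] = []
    while True:
        try:
            fit = fit_logistic(records, profiles, current, outcome=outcome)
        except FWAgingError as exc:
            raise StepwiseError(
                f"fit failed with terms {current}: {exc}",
                partial_trace=StepwiseTrace(tuple(steps)) if steps else None,
            ) from exc
        if not current:  # everything eliminated: intercept-only terminal step
            steps.append(Step((), fit, None, None))
            return StepwiseTrace(tuple(steps))
        worst, worst_p = None, -1.0
        for t in current:  # ties: later candidate wins via >=
            p = fit.p[fit.terms.index(t)]
            if p >= worst_p:
                worst, worst_p = t, p
        if worst_p > alpha_stay:
            steps.append(Step(tuple(current), fit, worst, worst_p))
            current.remove(worst)
        else:
            steps.append(Step(tuple(current), fit, None, None))
            return StepwiseTrace(tuple(steps))


def linear_predictor(fit: LogisticFit, x: Mapping[str, float]) -> float:
    """Sum of ``beta_i * x_i`` over the fit's terms (intercept excluded).

    Raises
    ------
    FactorLookupError
        If ``x`` lacks a value for any retained term.
    """
    total = 0.0
    for t, b in zip(fit.terms, fit.beta):
        if t not in x:
            raise FactorLookupError(f"covariate map lacks term {t!r}")
        total += b * float(x[t])
    return total
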