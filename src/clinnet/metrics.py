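"""Study-specific measures.

Diagnostic accuracy is min-max normalized absolute error against the
16% anchor: 1 at the anchor, 0 at the farthest possible estimate (100,
i.e. 84 points away). Option rates, the undertreatment/guideline gap and
the between-arm inequity follow the trial-then-grand averaging order by
default (each trial contributes equally regardless of cell size); pooled
averaging is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clinical import DEFAULT_RULE, CorrectnessRule, is_correct
from .errors import MissingDataError, UndefinedStatisticError, ValidationError
from .simulate import ANCHOR, ARMS, BLACK_FEMALE, MAX_ERROR, OPTIONS, WHITE_MALE


def normalized_accuracy(
    estimate: float | np.ndarray,
    anchor: float = ANCHOR,
    max_error: float = MAX_ERROR,
) -> float | np.ndarray:
    """1 - |estimate - anchor| / max_error, on the 0-1 accuracy scale."""
    est = np.asarray(estimate, dtype=float)
    if np.any(est < 0) or np.any(est > 100):
        raise ValidationError("estimates must lie in [0,100]")
    value = 1.0 - np.abs(est - anchor) / max_error
    return float(value) if np.isscalar(estimate) else value


def _select(
    records: pd.DataFrame,
    round_no: int | None = None,
    condition: str | None = None,
    arm: str | None = None,
) -> pd.DataFrame:
    out = records
    if round_no is not None:
        out = out[out["round"] == round_no]
    if condition is not None:
        out = out[out["condition"] == condition]
    if arm is not None:
        out = out[out["arm"] == arm]
    return out


def option_rates(
    records: pd.DataFrame,
    round_no: int,
    condition: str | None = None,
    arm: str | None = None,
    aggregate: str = "trial",
) -> np.ndarray:
    """Fraction of records recommending each of A,B,C,D.

    ``aggregate="trial"`` averages within each trial first, then across
    trials, so trials with different cell sizes weigh equally;
    ``aggregate="pooled"`` is the raw proportion over all selected records.
    """
    sel = _select(records, round_no, condition, arm)
    if sel.empty:
        raise MissingDataError("selection matched no records")
    if aggregate == "pooled":
        counts = sel["recommendation"].value_counts()
        rates = np.array([counts.get(o, 0) for o in OPTIONS], dtype=float)
        return rates / rates.sum()
    if aggregate != "trial":
        raise ValidationError(f"unknown aggregate mode {aggregate!r}")
    per_trial = (
        sel.groupby("trial_id")["recommendation"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(OPTIONS), fill_value=0.0)
    )
    return per_trial.mean(axis=0).to_numpy()


@dataclass(frozen=True)
class InequityStat:
    """Per-arm P(A)-P(C) gaps and their between-arm difference, all in
    percentage points."""

    gap_black_female: float
    gap_white_male: float

    @property
    def inequity(self) -> float:
        return self.gap_black_female - self.gap_white_male


def option_gap(
    records: pd.DataFrame,
    round_no: int,
    arm: str,
    condition: str | None = None,
    aggregate: str = "trial",
) -> float:
    """P(unsafe undertreatment) - P(guideline care) for one arm, in pp."""
    rates = option_rates(records, round_no, condition=condition, arm=arm, aggregate=aggregate)
    return 100.0 * (rates[OPTIONS.index("A")] - rates[OPTIONS.index("C")])


def inequity(
    records: pd.DataFrame,
    round_no: int,
    condition: str | None = None,
    aggregate: str = "trial",
) -> InequityStat:
    """Between-arm treatment inequity at one round."""
    for required in ARMS:
        if _select(records, round_no, condition, required).empty:
            raise MissingDataError(f"arm {required!r} absent from selection")
    return InequityStat(
        gap_black_female=option_gap(records, round_no, BLACK_FEMALE, condition, aggregate),
        gap_white_male=option_gap(records, round_no, WHITE_MALE, condition, aggregate),
    )


def undertreatment_odds(
    records: pd.DataFrame,
    round_no: int,
    arm: str | None = None,
    condition: str | None = None,
    haldane: bool = False,
) -> float:
    """Odds of recommending A rather than C: count(A)/count(C).

    A zero C-count raises :class:`UndefinedStatisticError` unless
    ``haldane`` applies the +0.5 Haldane-Anscombe correction to both
    counts (intended for regression contexts, not headline reporting).
    """
    sel = _select(records, round_no, condition, arm)
    if sel.empty:
        raise MissingDataError("selection matched no records")
    n_a = int((sel["recommendation"] == "A").sum())
    n_c = int((sel["recommendation"] == "C").sum())
    if haldane:
        return (n_a + 0.5) / (n_c + 0.5)
    if n_c == 0:
        raise UndefinedStatisticError("zero guideline-option count: odds undefined")
    return n_a / n_c


def revision_coefficient(
    initial_estimates: np.ndarray,
    final_estimates: np.ndarray,
    cluster_labels: np.ndarray | None = None,
    anchor: float = ANCHOR,
) -> tuple[float, float]:
    """Correlation between initial absolute error and revision magnitude.

    r is the Pearson correlation of x = |initial - anchor| with
    y = |final - initial|. The standard error comes from an OLS fit of y on
    x — cluster-robust by ``cluster_labels`` (typically trial ids) when
    given, classical otherwise — with the slope's SE rescaled to the
    correlation scale by sd(x)/sd(y) (since r = slope * sd(x)/sd(y)).
    """
    x = np.abs(np.asarray(initial_estimates, dtype=float) - anchor)
    y = np.abs(np.asarray(final_estimates, dtype=float) - np.asarray(initial_estimates, dtype=float))
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired estimates")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("zero variance: revision coefficient undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    model = sm.OLS(y, sm.add_constant(x))
    if cluster_labels is not None:
        labels = np.asarray(cluster_labels)
        if labels.size != x.size:
            raise ValidationError("cluster_labels must align with estimates")
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": labels})
    else:
        fit = model.fit()
    se = float(np.asarray(fit.bse)[1] * sx / sy)
    return r, se


def improvement(
    records: pd.DataFrame,
    round_a: int,
    round_b: int,
    rule: CorrectnessRule = DEFAULT_RULE,
) -> tuple[pd.Series, float]:
    """Per-clinician improvement flags plus the correct-rate change in pp.

    A clinician improves when their ``round_a`` recommendation is not
    accepted by ``rule`` but their ``round_b`` one is. Clinicians missing
    either round are excluded (with a warning, since that indicates
    attrition).
    """
    pivot = records.pivot_table(
        index="clinician_id", columns="round", values="recommendation", aggfunc="first"
    )
    missing_cols = [r for r in (round_a, round_b) if r not in pivot.columns]
    if missing_cols:
        raise MissingDataError(f"rounds {missing_cols} absent from records")
    both = pivot[[round_a, round_b]].dropna()
    dropped = len(pivot) - len(both)
    if dropped:
        warnings.warn(
            f"excluded {dropped} clinician(s) missing round {round_a} or {round_b}",
            stacklevel=2,
        )
    if both.empty:
        raise MissingDataError("no clinician has both rounds")
    correct_a = both[round_a].map(lambda o: is_correct(o, rule))
    correct_b = both[round_b].map(lambda o: is_correct(o, rule))
    flags = (~correct_a) & correct_b
    delta_pp = 100.0 * (correct_b.mean() - correct_a.mean())
    return flags, float(delta_pp)
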