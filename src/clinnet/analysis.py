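"""Trial-level statistical framework.

All inference runs on trial-level observations: one metric vector per
(trial, condition, arm) cell. Control cells, which enroll fewer clinicians
than network cells, are first bootstrapped into groups matching the network
cell size so the units are comparable. Contrasts use Wilcoxon rank-sum and
signed-rank tests implemented with exact enumeration on small samples and
tie-corrected normal approximations otherwise; individual-level odds-ratio
contracts use logistic models with trial-clustered sandwich errors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .clinical import DEFAULT_RULE, CorrectnessRule, is_correct
from .errors import MissingDataError, ValidationError
from .metrics import normalized_accuracy
from .simulate import ARMS, BLACK_FEMALE, CONDITIONS, CONTROL, NETWORK, OPTIONS, WHITE_MALE

_EXACT_RANKSUM_LIMIT = 200_000  # max enumerated splits before falling back


@dataclass(frozen=True)
class BootstrapGroup:
    """A with-replacement resample of one control cell's clinicians."""

    group_id: int
    trial_id: int
    condition: str
    arm: str
    members: tuple[str, ...]


def bootstrap_control_groups(
    control_records: pd.DataFrame,
    group_size: int = 40,
    n_groups: int = 1,
    seed: int = 0,
) -> list[BootstrapGroup]:
    """Resample each control (trial, arm) cell into groups of ``group_size``.

    Sampling is with replacement, within trial (preserving trial
    clustering), and deterministic given ``seed``.
    """
    records = control_records[control_records["condition"] == CONTROL]
    if records.empty:
        raise MissingDataError("no control records to bootstrap")
    rng = np.random.default_rng(seed)
    groups: list[BootstrapGroup] = []
    gid = 0
    cells = records.groupby(["trial_id", "arm"], sort=True)
    for (trial_id, arm), cell in cells:
        pool = sorted(cell["clinician_id"].unique())
        for _ in range(n_groups):
            members = tuple(rng.choice(pool, size=group_size, replace=True))
            groups.append(
                BootstrapGroup(
                    group_id=gid,
                    trial_id=int(trial_id),
                    condition=CONTROL,
                    arm=str(arm),
                    members=members,
                )
            )
            gid += 1
    return groups


def _wide_responses(
    records: pd.DataFrame,
    initial_round: int,
    final_round: int,
    attrition: str,
) -> pd.DataFrame:
    """One row per clinician with initial/final estimate and recommendation."""
    est = records.pivot_table(
        index="clinician_id", columns="round", values="estimate", aggfunc="first"
    )
    rec = records.pivot_table(
        index="clinician_id", columns="round", values="recommendation", aggfunc="first"
    )
    meta = records.groupby("clinician_id")[["trial_id", "condition", "arm"]].first()
    if initial_round not in est.columns:
        raise MissingDataError(f"round {initial_round} absent from records")
    wide = meta.copy()
    wide["est_initial"] = est[initial_round]
    wide["rec_initial"] = rec[initial_round]
    rounds_present = [c for c in est.columns if c <= final_round]
    if attrition == "locf":
        last = est[rounds_present].ffill(axis=1)[rounds_present[-1]]
        last_rec = rec[rounds_present].ffill(axis=1)[rounds_present[-1]]
        wide["est_final"] = last
        wide["rec_final"] = last_rec
    elif attrition == "complete_case":
        if final_round in est.columns:
            wide["est_final"] = est[final_round]
            wide["rec_final"] = rec[final_round]
        else:
            wide["est_final"] = np.nan
            wide["rec_final"] = None
        wide = wide.dropna(subset=["est_final", "est_initial"])
    else:
        raise ValidationError(f"unknown attrition mode {attrition!r}")
    return wide.dropna(subset=["est_initial"])


def _cell_metrics(wide: pd.DataFrame, rule: CorrectnessRule) -> dict[str, float]:
    out: dict[str, float] = {
        "n": float(len(wide)),
        "accuracy_initial": float(np.mean(normalized_accuracy(wide["est_initial"].to_numpy()))),
        "accuracy_final": float(np.mean(normalized_accuracy(wide["est_final"].to_numpy()))),
    }
    for stage in ("initial", "final"):
        recs = wide[f"rec_{stage}"]
        for opt in OPTIONS:
            out[f"rate_{opt}_{stage}"] = float((recs == opt).mean())
        out[f"correct_{stage}"] = float(recs.map(lambda o: is_correct(o, rule)).mean())
        out[f"gap_{stage}"] = 100.0 * (out[f"rate_A_{stage}"] - out[f"rate_C_{stage}"])
    out["improvement_pp"] = 100.0 * (out["correct_final"] - out["correct_initial"])
    return out


def build_trial_observations(
    records: pd.DataFrame,
    groups: list[BootstrapGroup] | None = None,
    rule: CorrectnessRule = DEFAULT_RULE,
    attrition: str = "complete_case",
    initial_round: int = 1,
    final_round: int = 3,
) -> pd.DataFrame:
    """Aggregate records into one observation per (trial, condition, arm).

    When ``groups`` is given, each control observation is computed over a
    bootstrap group's members (with multiplicity); with more than one group
    per cell, each group contributes its own observation row.
    """
    wide = _wide_responses(records, initial_round, final_round, attrition)
    rows: list[dict] = []
    by_group: dict[tuple[int, str], list[BootstrapGroup]] = {}
    for g in groups or []:
        by_group.setdefault((g.trial_id, g.arm), []).append(g)
    for (trial_id, condition, arm), cell in wide.groupby(
        ["trial_id", "condition", "arm"], sort=True
    ):
        base = {"trial_id": int(trial_id), "condition": condition, "arm": arm}
        if condition == CONTROL and (int(trial_id), arm) in by_group:
            for g in by_group[(int(trial_id), arm)]:
                members = [m for m in g.members if m in cell.index]
                if not members:
                    raise MissingDataError(
                        f"bootstrap group {g.group_id} has no members with complete rounds"
                    )
                rows.append(
                    base | {"group_id": g.group_id} | _cell_metrics(cell.loc[members], rule)
                )
        else:
            rows.append(base | {"group_id": -1} | _cell_metrics(cell, rule))
    if not rows:
        raise MissingDataError("no observations could be built")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def rank_sum_test(obs_a, obs_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test on two independent samples.

    Returns (U statistic of the first sample, two-sided p). Exact
    enumeration of rank splits (tie-aware) when either side has fewer than
    8 values and the split count is tractable; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(obs_a, dtype=float)
    b = np.asarray(obs_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("each sample needs >= 1 observation")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; rank-sum p forced to 1", stacklevel=2)
        return u1, 1.0
    n = n1 + n2
    exact = min(n1, n2) < 8 and comb(n, n1) <= _EXACT_RANKSUM_LIMIT
    if exact:
        offset = n1 * (n1 + 1) / 2
        count_le = count_ge = total = 0
        for idx in itertools.combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if u <= u1 + 1e-9:
                count_le += 1
            if u >= u1 - 1e-9:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return u1, p
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        warnings.warn("degenerate rank variance; p forced to 1", stacklevel=2)
        return u1, 1.0
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    return u1, float(2.0 * sps.norm.sf(abs(z)))


def signed_rank_test(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Pass differences directly, or two paired samples. Zero differences are
    dropped (standard convention). Exact null via the distribution of the
    positive-rank sum for n <= 25; tie-corrected normal approximation with
    continuity correction otherwise. Returns (W+, two-sided p).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.size < 1:
        raise ValidationError("need >= 1 paired difference")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p forced to 1", stacklevel=2)
        return 0.0, 1.0
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        # distribution of 2*W+ over all 2^n sign assignments (doubling makes
        # midranks integral)
        doubled = np.round(2 * ranks).astype(int)
        total = int(doubled.sum())
        dist = np.zeros(total + 1, dtype=float)
        dist[0] = 1.0
        for r2 in doubled:
            shifted = np.zeros_like(dist)
            shifted[r2:] = dist[: dist.size - r2]
            dist = dist + shifted
        w2 = int(round(2 * w_pos))
        n_assign = dist.sum()
        p_le = dist[: w2 + 1].sum() / n_assign
        p_ge = dist[w2:].sum() / n_assign
        return w_pos, min(1.0, 2.0 * min(p_le, p_ge))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        warnings.warn("degenerate rank variance; p forced to 1", stacklevel=2)
        return w_pos, 1.0
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(var)
    return w_pos, float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Clustered logistic contracts
# ---------------------------------------------------------------------------


def clustered_choice_model(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cluster: str = "trial_id",
    penalized: bool = False,
) -> pd.DataFrame:
    """Logistic regression with cluster-robust (sandwich) standard errors.

    Returns one row per term with coef, SE, OR = exp(coef), the 95% CI on
    the OR scale, p, and a ``separation`` flag. Under (quasi-)separation
    the MLE diverges; with ``penalized=True`` a small ridge penalty is used
    instead and no CI is reported for the penalized fit.
    """
    y = data[outcome].astype(float).to_numpy()
    X = sm.add_constant(data[list(covariates)].astype(float), has_constant="add")
    groups = data[cluster]
    model = sm.Logit(y, X)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=200, cov_type="cluster", cov_kwds={"groups": groups})
        params = np.asarray(fit.params)
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 15):
            separated = True
    except Exception:
        separated = True
        fit = None
    if separated and penalized:
        reg = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
        rows = [
            {
                "term": t,
                "coef": float(c),
                "se": np.nan,
                "odds_ratio": float(np.exp(c)),
                "or_ci_low": np.nan,
                "or_ci_high": np.nan,
                "p_value": np.nan,
                "separation": True,
            }
            for t, c in zip(X.columns, np.asarray(reg.params))
        ]
        return pd.DataFrame(rows)
    if fit is None:
        raise ValidationError(
            "logistic fit failed (likely separation); retry with penalized=True"
        )
    ci = np.asarray(fit.conf_int())
    rows = [
        {
            "term": t,
            "coef": float(fit.params.iloc[i]),
            "se": float(fit.bse.iloc[i]),
            "odds_ratio": float(np.exp(fit.params.iloc[i])),
            "or_ci_low": float(np.exp(ci[i, 0])),
            "or_ci_high": float(np.exp(ci[i, 1])),
            "p_value": float(fit.pvalues.iloc[i]),
            "separation": separated,
        }
        for i, t in enumerate(X.columns)
    ]
    return pd.DataFrame(rows)


def arm_choice_model(
    records: pd.DataFrame,
    round_no: int = 1,
    outcome_option: str = "C",
    restrict_options: list[str] | None = None,
    condition: str | None = None,
    penalized: bool = False,
) -> pd.DataFrame:
    """OR contract for arm differences in recommending one option.

    Builds clinician-level data at ``round_no`` (optionally restricted to a
    subset of options, e.g. ["A", "C"]), codes the white-male arm as 1, and
    fits the trial-clustered logistic model.
    """
    sel = records[records["round"] == round_no]
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    if restrict_options is not None:
        sel = sel[sel["recommendation"].isin(restrict_options)]
    if sel.empty:
        raise MissingDataError("selection matched no records")
    frame = pd.DataFrame(
        {
            "outcome": (sel["recommendation"] == outcome_option).astype(int),
            "white_male": (sel["arm"] == WHITE_MALE).astype(int),
            "trial_id": sel["trial_id"],
        }
    )
    return clustered_choice_model(
        frame, "outcome", ["white_male"], cluster="trial_id", penalized=penalized
    )


# ---------------------------------------------------------------------------
# Study-level battery
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    observations: pd.DataFrame
    tests: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _obs_values(obs: pd.DataFrame, column: str, condition=None, arm=None) -> np.ndarray:
    sel = obs
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    if arm is not None:
        sel = sel[sel["arm"] == arm]
    return sel[column].to_numpy(dtype=float)


def run_analysis(
    records: pd.DataFrame,
    rule: CorrectnessRule = DEFAULT_RULE,
    attrition: str = "complete_case",
    group_size: int = 40,
    n_groups: int = 1,
    bootstrap_seed: int = 0,
) -> AnalysisResult:
    """Full trial-level battery: observations, contrasts and summaries."""
    control = records[records["condition"] == CONTROL]
    groups = (
        bootstrap_control_groups(control, group_size, n_groups, bootstrap_seed)
        if not control.empty
        else None
    )
    obs = build_trial_observations(records, groups=groups, rule=rule, attrition=attrition)

    tests: list[dict] = []

    def add_rank_sum(name, column, cond_a, arm_a, cond_b, arm_b):
        va = _obs_values(obs, column, cond_a, arm_a)
        vb = _obs_values(obs, column, cond_b, arm_b)
        stat, p = rank_sum_test(va, vb)
        tests.append(
            {
                "contrast": name,
                "test": "rank_sum",
                "statistic": stat,
                "p_value": p,
                "n_obs": va.size + vb.size,
            }
        )

    def add_signed_rank(name, col_final, col_initial, condition, arm):
        sel = obs
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        if arm is not None:
            sel = sel[sel["arm"] == arm]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = signed_rank_test(
                sel[col_final].to_numpy(dtype=float), sel[col_initial].to_numpy(dtype=float)
            )
        tests.append(
            {
                "contrast": name,
                "test": "signed_rank",
                "statistic": stat,
                "p_value": p,
                "n_obs": len(sel),
            }
        )

    # between-arm contrasts on all observations (both conditions)
    add_rank_sum("initial_accuracy_by_arm", "accuracy_initial", None, BLACK_FEMALE, None, WHITE_MALE)
    add_rank_sum("initial_guideline_rate_by_arm", "rate_C_initial", None, BLACK_FEMALE, None, WHITE_MALE)
    add_rank_sum("initial_gap_by_arm", "gap_initial", None, BLACK_FEMALE, None, WHITE_MALE)
    # within-cell initial-to-final changes
    for condition in CONDITIONS:
        for arm in ARMS:
            tag = f"{condition}_{arm}"
            add_signed_rank(f"accuracy_change_{tag}", "accuracy_final", "accuracy_initial", condition, arm)
            add_signed_rank(f"guideline_rate_change_{tag}", "rate_C_final", "rate_C_initial", condition, arm)
            add_signed_rank(f"gap_change_{tag}", "gap_final", "gap_initial", condition, arm)
    # final between-arm disparity within each condition
    for condition in CONDITIONS:
        add_rank_sum(
            f"final_guideline_rate_by_arm_{condition}",
            "rate_C_final",
            condition,
            BLACK_FEMALE,
            condition,
            WHITE_MALE,
        )
        add_rank_sum(
            f"final_gap_by_arm_{condition}",
            "gap_final",
            condition,
            BLACK_FEMALE,
            condition,
            WHITE_MALE,
        )

    summary = {
        "n_observations": int(len(obs)),
        "n_trials": int(obs["trial_id"].nunique()),
        "accepted_options": sorted(o.value for o in rule.accepted_options),
        "attrition": attrition,
    }
    for condition in CONDITIONS:
        for arm in ARMS:
            sub = obs[(obs["condition"] == condition) & (obs["arm"] == arm)]
            prefix = f"{condition}.{arm}"
            for col in ("accuracy_initial", "accuracy_final", "rate_C_initial", "rate_C_final",
                        "gap_initial", "gap_final", "improvement_pp"):
                summary[f"{prefix}.{col}"] = float(sub[col].mean())
    summary["inequity_initial_pp"] = float(
        _obs_values(obs, "gap_initial", None, BLACK_FEMALE).mean()
        - _obs_values(obs, "gap_initial", None, WHITE_MALE).mean()
    )
    for condition in CONDITIONS:
        summary[f"inequity_final_pp_{condition}"] = float(
            _obs_values(obs, "gap_final", condition, BLACK_FEMALE).mean()
            - _obs_values(obs, "gap_final", condition, WHITE_MALE).mean()
        )
    return AnalysisResult(observations=obs, tests=pd.DataFrame(tests), summary=summary)


def sensitivity_reanalysis(
    records: pd.DataFrame,
    rule: CorrectnessRule,
    **kwargs,
) -> AnalysisResult:
    """Re-run the full battery under an alternate correctness rule."""
    return run_analysis(records, rule=rule, **kwargs)
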