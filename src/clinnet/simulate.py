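"""Agent-based generator of three-round study data.

Simulates the statistical structure of the experiment: per trial, four
cells (network/control x two patient-actor arms). Round 1 is independent:
estimates are truncated-normal on [0,100] and recommendations are drawn
from arm-specific categorical distributions. In network cells, rounds 2-3
revise each estimate toward the mean of the agent's network neighbors with
an adoption weight that grows with the agent's own initial error — accurate
agents move less, which is what gives them outsized influence on the
consensus. Revised recommendations are redrawn from a softmax choice model
whose guideline-option utility increases with diagnostic accuracy, so
better estimates pull recommendations toward guideline care. Control cells
revise independently: small estimate noise plus an occasional one-step
drift toward higher-acuity options.

Individual revision behavior is a modeling choice (only aggregate dynamics
are constrained); all parameters are exposed in :class:`GeneratorConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .topology import Topology, make_egalitarian_network

NETWORK = "network"
CONTROL = "control"
CONDITIONS = (NETWORK, CONTROL)

BLACK_FEMALE = "black_female"
WHITE_MALE = "white_male"
ARMS = (BLACK_FEMALE, WHITE_MALE)

OPTIONS = ("A", "B", "C", "D")

#: Anchor of the accuracy scale: the correct 30-day risk estimate (percent).
ANCHOR = 16.0
#: Largest achievable absolute error on the [0,100] estimate scale.
MAX_ERROR = 84.0

ROUNDS = (1, 2, 3)

COLUMNS = [
    "trial_id",
    "condition",
    "arm",
    "clinician_id",
    "round",
    "estimate",
    "recommendation",
    "network_position",
    "completed",
]


@dataclass(frozen=True)
class ArmConfig:
    """Behavioral parameters for one patient-actor arm."""

    estimate_mean: float
    estimate_sd: float
    initial_choice_probs: tuple[float, float, float, float]
    choice_intercepts: tuple[float, float, float, float] | None = None

    def validate(self) -> None:
        probs = np.asarray(self.initial_choice_probs, dtype=float)
        if probs.shape != (4,):
            raise ValidationError("initial_choice_probs must have 4 entries (A,B,C,D)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValidationError("choice probabilities must lie in [0,1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"choice probabilities sum to {probs.sum()}, not 1")
        if self.estimate_sd < 0:
            raise ValidationError("estimate_sd must be >= 0")
        if not (0.0 <= self.estimate_mean <= 100.0):
            raise ValidationError("estimate_mean must lie in [0,100]")


@dataclass(frozen=True)
class RevisionRule:
    """Error-dependent adoption weight w = clip(alpha + beta*|e-16|/84, 0, 1)."""

    alpha: float = 0.05
    beta: float = 0.9
    noise_sd: float = 2.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributions, effect parameters and seeds of the generator."""

    arms: Mapping[str, ArmConfig]
    n_trials: int = 7
    n_network_per_arm: int = 40
    n_control_per_arm: int = 20
    network_degree: int = 4
    choice_slope: float = 8.0
    revision: RevisionRule = field(default_factory=RevisionRule)
    control_drift: float = 0.03
    completion_prob: float = 1.0
    master_seed: int = 0

    def validate(self) -> None:
        if set(self.arms) != set(ARMS):
            raise ValidationError(f"arms must be exactly {ARMS}, got {sorted(self.arms)}")
        for arm_cfg in self.arms.values():
            arm_cfg.validate()
        self.revision.validate()
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.n_network_per_arm < self.network_degree + 1:
            raise ValidationError("n_network_per_arm too small for network_degree")
        if self.n_control_per_arm < 1:
            raise ValidationError("n_control_per_arm must be >= 1")
        if not (0.0 <= self.control_drift <= 1.0):
            raise ValidationError("control_drift must lie in [0,1]")
        if not (0.0 <= self.completion_prob <= 1.0):
            raise ValidationError("completion_prob must lie in [0,1]")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def cell_rng(master_seed: int, trial_id: int, condition: str, arm: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one (trial, condition, arm)."""
    key = (int(master_seed), int(trial_id), CONDITIONS.index(condition), ARMS.index(arm))
    return np.random.default_rng(np.random.SeedSequence(key))


def _draw_estimates(arm_cfg: ArmConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    if arm_cfg.estimate_sd == 0:
        return np.full(size, float(arm_cfg.estimate_mean))
    a = (0.0 - arm_cfg.estimate_mean) / arm_cfg.estimate_sd
    b = (100.0 - arm_cfg.estimate_mean) / arm_cfg.estimate_sd
    return stats.truncnorm.rvs(
        a, b, loc=arm_cfg.estimate_mean, scale=arm_cfg.estimate_sd, size=size, random_state=rng
    )


def _draw_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw over OPTIONS; probs is (n, 4)."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(OPTIONS)[np.clip(idx, 0, 3)]


def choice_probabilities(
    estimates: np.ndarray,
    intercepts: Sequence[float],
    slope: float,
) -> np.ndarray:
    """Softmax choice model: utility(C) gains ``slope`` * normalized accuracy.

    Accuracy is 1 - |estimate - 16| / 84, so estimates near the anchor push
    probability mass toward the guideline option.
    """
    estimates = np.asarray(estimates, dtype=float)
    acc = 1.0 - np.abs(estimates - ANCHOR) / MAX_ERROR
    util = np.tile(np.asarray(intercepts, dtype=float), (estimates.size, 1))
    util[:, OPTIONS.index("C")] += slope * acc
    util -= util.max(axis=1, keepdims=True)
    expu = np.exp(util)
    return expu / expu.sum(axis=1, keepdims=True)


def calibrate_intercepts(
    target_probs: Sequence[float],
    estimates: np.ndarray,
    slope: float,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[float, float, float, float]:
    """Solve softmax intercepts so the model's marginal option rates over
    ``estimates`` match ``target_probs``.

    Uses a multiplicative (log-space) fixed-point update; converges for any
    strictly positive target vector. Zero targets get a -inf-like floor.
    """
    target = np.asarray(target_probs, dtype=float)
    if abs(target.sum() - 1.0) > 1e-9:
        raise ValidationError("target probabilities must sum to 1")
    floor = 1e-12
    c = np.log(np.maximum(target, floor))
    for _ in range(max_iter):
        marg = choice_probabilities(estimates, c, slope).mean(axis=0)
        if np.max(np.abs(marg - target)) < tol:
            break
        c = c + np.log(np.maximum(target, floor)) - np.log(marg)
        c -= c.max()
    return tuple(float(v) for v in c)


def _records(
    trial_id: int,
    condition: str,
    arm: str,
    clinician_ids: Sequence[str],
    round_no: int,
    estimates: np.ndarray,
    recommendations: np.ndarray,
    positions: Sequence[int] | None,
    completed: np.ndarray,
) -> pd.DataFrame:
    n = len(clinician_ids)
    return pd.DataFrame(
        {
            "trial_id": np.full(n, trial_id, dtype=int),
            "condition": condition,
            "arm": arm,
            "clinician_id": list(clinician_ids),
            "round": np.full(n, round_no, dtype=int),
            "estimate": np.asarray(estimates, dtype=float),
            "recommendation": np.asarray(recommendations, dtype=object),
            "network_position": (
                pd.array(positions, dtype="Int64")
                if positions is not None
                else pd.array([pd.NA] * n, dtype="Int64")
            ),
            "completed": np.asarray(completed, dtype=int),
        }
    )


def draw_initial_responses(
    cfg: GeneratorConfig,
    trial_id: int,
    condition: str,
    arm: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Round-1 records for one (trial, condition, arm) cell."""
    cfg.validate()
    arm_cfg = cfg.arms[arm]
    n = cfg.n_network_per_arm if condition == NETWORK else cfg.n_control_per_arm
    estimates = _draw_estimates(arm_cfg, n, rng)
    probs = np.tile(np.asarray(arm_cfg.initial_choice_probs, dtype=float), (n, 1))
    recommendations = _draw_categorical(probs, rng)
    tag = "N" if condition == NETWORK else "K"
    atag = "BF" if arm == BLACK_FEMALE else "WM"
    ids = [f"T{trial_id:02d}-{tag}-{atag}-{i:03d}" for i in range(n)]
    positions = list(range(n)) if condition == NETWORK else None
    return _records(
        trial_id, condition, arm, ids, 1, estimates, recommendations, positions, np.ones(n)
    )


def _arm_intercepts(cfg: GeneratorConfig, arm: str) -> tuple[float, ...]:
    arm_cfg = cfg.arms[arm]
    if arm_cfg.choice_intercepts is not None:
        return tuple(arm_cfg.choice_intercepts)
    # calibrate against the arm's own initial estimate distribution so the
    # choice model is marginally consistent with round 1
    grid = _estimate_grid(arm_cfg)
    return calibrate_intercepts(arm_cfg.initial_choice_probs, grid, cfg.choice_slope)


def _estimate_grid(arm_cfg: ArmConfig) -> np.ndarray:
    if arm_cfg.estimate_sd == 0:
        return np.array([arm_cfg.estimate_mean])
    a = (0.0 - arm_cfg.estimate_mean) / arm_cfg.estimate_sd
    b = (100.0 - arm_cfg.estimate_mean) / arm_cfg.estimate_sd
    q = np.linspace(0.0005, 0.9995, 400)
    return stats.truncnorm.ppf(q, a, b, loc=arm_cfg.estimate_mean, scale=arm_cfg.estimate_sd)


def revise_network(
    cfg: GeneratorConfig,
    topology: Topology,
    prior_records: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One network revision round applied to ``prior_records``.

    Each agent adopts the mean of its neighbors' prior estimates with
    weight w = clip(alpha + beta*|own - 16|/84, 0, 1), plus Gaussian noise,
    clipped to [0,100]; the recommendation is redrawn from the softmax
    choice model at the revised estimate.
    """
    prior = prior_records.sort_values("network_position")
    if prior["network_position"].isna().any():
        raise ValidationError("network revision requires network positions")
    positions = prior["network_position"].to_numpy(dtype=int)
    if len(positions) != topology.n or set(positions) != set(range(topology.n)):
        raise ValidationError("prior round does not cover every network position")
    own = prior["estimate"].to_numpy(dtype=float)
    adj = topology.adjacency_matrix()
    nbr_mean = adj @ own / adj.sum(axis=1)
    rule = cfg.revision
    w = np.clip(rule.alpha + rule.beta * np.abs(own - ANCHOR) / MAX_ERROR, 0.0, 1.0)
    noise = rng.normal(0.0, rule.noise_sd, size=own.size) if rule.noise_sd > 0 else 0.0
    new = np.clip((1.0 - w) * own + w * nbr_mean + noise, 0.0, 100.0)
    arm = prior["arm"].iloc[0]
    intercepts = _arm_intercepts(cfg, arm)
    probs = choice_probabilities(new, intercepts, cfg.choice_slope)
    recommendations = _draw_categorical(probs, rng)
    round_no = int(prior["round"].iloc[0]) + 1
    return _records(
        int(prior["trial_id"].iloc[0]),
        NETWORK,
        arm,
        prior["clinician_id"].tolist(),
        round_no,
        new,
        recommendations,
        positions.tolist(),
        prior["completed"].to_numpy(),
    )


_STEP_UP = {"A": "B", "B": "C", "C": "D", "D": "D"}


def revise_control(
    cfg: GeneratorConfig,
    prior_records: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One independent-reflection round: noisy estimates, occasional
    one-step drift toward higher-acuity recommendations."""
    prior = prior_records
    own = prior["estimate"].to_numpy(dtype=float)
    rule = cfg.revision
    noise = rng.normal(0.0, rule.noise_sd, size=own.size) if rule.noise_sd > 0 else 0.0
    new = np.clip(own + noise, 0.0, 100.0)
    recommendations = prior["recommendation"].to_numpy(dtype=object).copy()
    drift = rng.random(own.size) < cfg.control_drift
    recommendations[drift] = [_STEP_UP[r] for r in recommendations[drift]]
    round_no = int(prior["round"].iloc[0]) + 1
    return _records(
        int(prior["trial_id"].iloc[0]),
        CONTROL,
        prior["arm"].iloc[0],
        prior["clinician_id"].tolist(),
        round_no,
        new,
        recommendations,
        None,
        prior["completed"].to_numpy(),
    )


def study_topology(cfg: GeneratorConfig) -> Topology:
    """The one network topology shared by all trials of a study."""
    return make_egalitarian_network(cfg.n_network_per_arm, cfg.network_degree, cfg.master_seed)


def simulate_study(cfg: GeneratorConfig, topology: Topology | None = None) -> pd.DataFrame:
    """Full study table: n_trials x 4 cells x 3 rounds.

    Attrition drops each clinician's rounds 2-3 with probability
    1 - completion_prob (round 1 is always present — responding in round 1
    is what enrolls a clinician). Attrited agents still hold their last
    response for neighbors' averaging, but emit no further rows, and their
    ``completed`` flag is 0 on every row.
    """
    cfg.validate()
    if topology is None:
        topology = study_topology(cfg)
    frames: list[pd.DataFrame] = []
    for trial_id in range(1, cfg.n_trials + 1):
        for condition in CONDITIONS:
            for arm in ARMS:
                rng = cell_rng(cfg.master_seed, trial_id, condition, arm)
                first = draw_initial_responses(cfg, trial_id, condition, arm, rng)
                n = len(first)
                completed = (
                    rng.random(n) < cfg.completion_prob
                    if cfg.completion_prob < 1.0
                    else np.ones(n, dtype=bool)
                )
                first["completed"] = completed.astype(int)
                frames.append(first)
                latent = first
                for _ in (2, 3):
                    if condition == NETWORK:
                        latent_next = revise_network(cfg, topology, latent, rng)
                    else:
                        latent_next = revise_control(cfg, latent, rng)
                    # attrited agents keep their last response (LOCF) in the
                    # latent state but contribute no new rows
                    keep = ~completed
                    latent_next.loc[keep, "estimate"] = latent.loc[keep, "estimate"].to_numpy()
                    latent_next.loc[keep, "recommendation"] = latent.loc[
                        keep, "recommendation"
                    ].to_numpy()
                    frames.append(latent_next[completed].reset_index(drop=True))
                    latent = latent_next
    table = pd.concat(frames, ignore_index=True)
    return table[COLUMNS]
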