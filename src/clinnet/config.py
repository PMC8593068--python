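"""Study configuration: JSON schema, validation and the reference setup.

The reference generator mirrors the study design (7 trials; 40 clinicians
per network arm, 20 per control arm; degree-4 network) and anchors the
arm-specific initial recommendation distributions to the published pooled
initial rates (Black female arm: 29.9% unsafe undertreatment, 14.1%
guideline care; white male arm: 23.4% and 21.4%). The B/D split and the
estimate distributions are calibration choices, not published quantities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .clinical import RiskBand
from .errors import ValidationError
from .simulate import ARMS, ArmConfig, GeneratorConfig, RevisionRule


@dataclass(frozen=True)
class AnalysisConfig:
    """Flags controlling the analysis half of the pipeline."""

    aggregation: str = "trial"
    correctness_rule: tuple[str, ...] = ("C",)
    attrition: str = "complete_case"
    group_size: int = 40
    n_groups: int = 1
    bootstrap_seed: int = 0

    def validate(self) -> None:
        if self.aggregation not in ("trial", "pooled"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        if self.attrition not in ("complete_case", "locf"):
            raise ValidationError(f"unknown attrition mode {self.attrition!r}")
        if not self.correctness_rule:
            raise ValidationError("correctness_rule must be non-empty")
        for code in self.correctness_rule:
            if code not in ("A", "B", "C", "D"):
                raise ValidationError(f"unknown option code {code!r}")
        if self.group_size < 1 or self.n_groups < 1:
            raise ValidationError("group_size and n_groups must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    """Everything one end-to-end run needs, loadable from a single JSON file."""

    generator: GeneratorConfig
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    risk_bands: tuple[RiskBand, ...] = ()
    output_dir: str | None = None

    @property
    def master_seed(self) -> int:
        return self.generator.master_seed

    def with_seed(self, seed: int) -> "StudyConfig":
        return dataclasses.replace(self, generator=self.generator.replace(master_seed=seed))


def _check_keys(obj: Mapping[str, Any], allowed: set[str], required: set[str], ctx: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ValidationError(f"{ctx}: unknown key(s) {sorted(unknown)}")
    missing = required - set(obj)
    if missing:
        raise ValidationError(f"{ctx}: missing required key(s) {sorted(missing)}")


def _arm_from_dict(name: str, obj: Mapping[str, Any]) -> ArmConfig:
    _check_keys(
        obj,
        {"estimate_mean", "estimate_sd", "initial_choice_probs", "choice_intercepts"},
        {"estimate_mean", "estimate_sd", "initial_choice_probs"},
        f"arms.{name}",
    )
    intercepts = obj.get("choice_intercepts")
    return ArmConfig(
        estimate_mean=float(obj["estimate_mean"]),
        estimate_sd=float(obj["estimate_sd"]),
        initial_choice_probs=tuple(float(p) for p in obj["initial_choice_probs"]),
        choice_intercepts=tuple(float(c) for c in intercepts) if intercepts is not None else None,
    )


def generator_from_dict(obj: Mapping[str, Any]) -> GeneratorConfig:
    _check_keys(
        obj,
        {
            "arms",
            "n_trials",
            "n_network_per_arm",
            "n_control_per_arm",
            "network_degree",
            "choice_slope",
            "revision",
            "control_drift",
            "completion_prob",
            "master_seed",
        },
        {"arms"},
        "generator",
    )
    rev = obj.get("revision", {})
    _check_keys(rev, {"alpha", "beta", "noise_sd"}, set(), "generator.revision")
    cfg = GeneratorConfig(
        arms={name: _arm_from_dict(name, arm) for name, arm in obj["arms"].items()},
        n_trials=int(obj.get("n_trials", 7)),
        n_network_per_arm=int(obj.get("n_network_per_arm", 40)),
        n_control_per_arm=int(obj.get("n_control_per_arm", 20)),
        network_degree=int(obj.get("network_degree", 4)),
        choice_slope=float(obj.get("choice_slope", 8.0)),
        revision=RevisionRule(
            alpha=float(rev.get("alpha", RevisionRule.alpha)),
            beta=float(rev.get("beta", RevisionRule.beta)),
            noise_sd=float(rev.get("noise_sd", RevisionRule.noise_sd)),
        ),
        control_drift=float(obj.get("control_drift", 0.03)),
        completion_prob=float(obj.get("completion_prob", 1.0)),
        master_seed=int(obj.get("master_seed", 0)),
    )
    cfg.validate()
    return cfg


def study_config_from_dict(obj: Mapping[str, Any]) -> StudyConfig:
    _check_keys(
        obj,
        {"generator", "analysis", "risk_bands", "output_dir", "master_seed"},
        {"generator"},
        "config",
    )
    generator = generator_from_dict(obj["generator"])
    if "master_seed" in obj:
        generator = generator.replace(master_seed=int(obj["master_seed"]))
    ana = obj.get("analysis", {})
    _check_keys(
        ana,
        {"aggregation", "correctness_rule", "attrition", "bootstrap"},
        set(),
        "analysis",
    )
    boot = ana.get("bootstrap", {})
    _check_keys(boot, {"group_size", "n_groups", "seed"}, set(), "analysis.bootstrap")
    analysis = AnalysisConfig(
        aggregation=ana.get("aggregation", "trial"),
        correctness_rule=tuple(ana.get("correctness_rule", ["C"])),
        attrition=ana.get("attrition", "complete_case"),
        group_size=int(boot.get("group_size", 40)),
        n_groups=int(boot.get("n_groups", 1)),
        bootstrap_seed=int(boot.get("seed", 0)),
    )
    analysis.validate()
    bands = tuple(
        RiskBand(lo=int(b["lo"]), hi=int(b["hi"]), risk_percent=float(b["risk_percent"]))
        for b in obj.get("risk_bands", [])
    )
    return StudyConfig(
        generator=generator,
        analysis=analysis,
        risk_bands=bands,
        output_dir=obj.get("output_dir"),
    )


def study_config_to_dict(cfg: StudyConfig) -> dict:
    gen = cfg.generator
    return {
        "generator": {
            "arms": {
                name: {
                    "estimate_mean": arm.estimate_mean,
                    "estimate_sd": arm.estimate_sd,
                    "initial_choice_probs": list(arm.initial_choice_probs),
                    "choice_intercepts": (
                        list(arm.choice_intercepts) if arm.choice_intercepts else None
                    ),
                }
                for name, arm in gen.arms.items()
            },
            "n_trials": gen.n_trials,
            "n_network_per_arm": gen.n_network_per_arm,
            "n_control_per_arm": gen.n_control_per_arm,
            "network_degree": gen.network_degree,
            "choice_slope": gen.choice_slope,
            "revision": {
                "alpha": gen.revision.alpha,
                "beta": gen.revision.beta,
                "noise_sd": gen.revision.noise_sd,
            },
            "control_drift": gen.control_drift,
            "completion_prob": gen.completion_prob,
            "master_seed": gen.master_seed,
        },
        "analysis": {
            "aggregation": cfg.analysis.aggregation,
            "correctness_rule": list(cfg.analysis.correctness_rule),
            "attrition": cfg.analysis.attrition,
            "bootstrap": {
                "group_size": cfg.analysis.group_size,
                "n_groups": cfg.analysis.n_groups,
                "seed": cfg.analysis.bootstrap_seed,
            },
        },
        "risk_bands": [
            {"lo": b.lo, "hi": b.hi, "risk_percent": b.risk_percent} for b in cfg.risk_bands
        ],
        "output_dir": cfg.output_dir,
    }


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    return study_config_from_dict(obj)


def save_study_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(study_config_to_dict(cfg), indent=2) + "\n")


#: Published pooled initial rates used to anchor the reference arms; the
#: B/D splits are free choices consistent with the remaining mass.
_REFERENCE_ARM_PARAMS = {
    "black_female": {"A": 0.299, "B": 0.370, "C": 0.141, "D": 0.190},
    "white_male": {"A": 0.234, "B": 0.330, "C": 0.214, "D": 0.222},
}


def reference_generator(master_seed: int = 0) -> GeneratorConfig:
    """The reference synthetic-study configuration (7 trials, 840 clinicians)."""
    arms = {
        name: ArmConfig(
            estimate_mean=25.0,
            estimate_sd=20.0,
            initial_choice_probs=(p["A"], p["B"], p["C"], p["D"]),
        )
        for name, p in _REFERENCE_ARM_PARAMS.items()
    }
    assert set(arms) == set(ARMS)
    return GeneratorConfig(arms=arms, master_seed=master_seed)


def reference_study_config(master_seed: int = 0) -> StudyConfig:
    return StudyConfig(generator=reference_generator(master_seed))
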