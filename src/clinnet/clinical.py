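"""Clinical case encoding: risk scoring, treatment options and correctness.

The simulated case is an intermediate-risk chest-pain presentation. Five
0-2 sub-scores (history, ECG, age, risk factors, troponin) sum to a risk
score; the troponin component may be absent, in which case it contributes
nothing. Scores of 4-6 correspond to a 16% 30-day adverse-event risk, which
is the anchor every diagnostic estimate in the study is judged against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import ValidationError

#: The 30-day adverse cardiac event risk (percent) for the intermediate band.
INTERMEDIATE_RISK_PERCENT = 16.0

#: Score band (inclusive) that is pinned to :data:`INTERMEDIATE_RISK_PERCENT`.
INTERMEDIATE_BAND = (4, 6)


class OptionCategory(str, Enum):
    UNSAFE_UNDERTREATMENT = "unsafe_undertreatment"
    UNDERTREATMENT = "undertreatment"
    GUIDELINE = "guideline"
    OVERTREATMENT = "overtreatment"


class TreatmentOption(str, Enum):
    """The four mutually exclusive treatment recommendations."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def category(self) -> OptionCategory:
        return _CATEGORIES[self]

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def coerce(cls, value: "TreatmentOption | str") -> "TreatmentOption":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(f"unknown treatment option: {value!r}") from None


_CATEGORIES: Mapping[TreatmentOption, OptionCategory] = {
    TreatmentOption.A: OptionCategory.UNSAFE_UNDERTREATMENT,
    TreatmentOption.B: OptionCategory.UNDERTREATMENT,
    TreatmentOption.C: OptionCategory.GUIDELINE,
    TreatmentOption.D: OptionCategory.OVERTREATMENT,
}

_LABELS: Mapping[TreatmentOption, str] = {
    TreatmentOption.A: "daily 81 mg aspirin, return to clinic in one week",
    TreatmentOption.B: "daily 81 mg aspirin, stress test within 2-3 days",
    TreatmentOption.C: "full-dose aspirin, emergency department referral",
    TreatmentOption.D: "full-dose aspirin, urgent cardiac catheterization",
}


@dataclass(frozen=True)
class HeartComponents:
    """The five 0-2 sub-scores of the chest-pain risk score.

    ``troponin`` may be ``None`` (not measured); an absent component
    contributes zero points.
    """

    history: int
    ecg: int
    age: int
    risk_factors: int
    troponin: int | None = None

    def __post_init__(self) -> None:
        for name in ("history", "ecg", "age", "risk_factors"):
            _check_component(name, getattr(self, name))
        if self.troponin is not None:
            _check_component("troponin", self.troponin)


def _check_component(name: str, value: int) -> None:
    if not isinstance(value, int) or isinstance(value, bool) or value not in (0, 1, 2):
        raise ValidationError(f"component {name!r} must be an integer in {{0,1,2}}, got {value!r}")


def heart_score(components: HeartComponents) -> int:
    """Sum the present sub-scores; an absent troponin contributes 0."""
    total = components.history + components.ecg + components.age + components.risk_factors
    if components.troponin is not None:
        total += components.troponin
    return total


@dataclass(frozen=True)
class RiskBand:
    """Inclusive score range mapped to a 30-day risk percentage."""

    lo: int
    hi: int
    risk_percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 10):
            raise ValidationError(f"band [{self.lo},{self.hi}] out of score range [0,10]")
        if not (0.0 <= self.risk_percent <= 100.0):
            raise ValidationError(f"risk percent {self.risk_percent} outside [0,100]")


def risk_for_score(score: int, bands: Iterable[RiskBand] | None = None) -> float:
    """30-day adverse-event risk (percent) for a risk score.

    Scores 4-6 always map to 16.0; this band is canonical and cannot be
    overridden. Other bands come from ``bands`` (for instance loaded from a
    study config); scores not covered by any configured band return NaN
    rather than an invented number.
    """
    if not isinstance(score, int) or isinstance(score, bool):
        raise ValidationError(f"score must be an integer, got {score!r}")
    if not (0 <= score <= 10):
        raise ValidationError(f"score {score} outside [0,10]")
    lo, hi = INTERMEDIATE_BAND
    if bands is not None:
        for band in bands:
            overlaps = band.lo <= hi and band.hi >= lo
            if overlaps and band.risk_percent != INTERMEDIATE_RISK_PERCENT:
                raise ValidationError(
                    f"band [{band.lo},{band.hi}]={band.risk_percent} conflicts with the "
                    f"canonical {lo}-{hi} band ({INTERMEDIATE_RISK_PERCENT}%)"
                )
    if lo <= score <= hi:
        return INTERMEDIATE_RISK_PERCENT
    if bands is not None:
        for band in bands:
            if band.lo <= score <= band.hi:
                return band.risk_percent
    return math.nan


@dataclass(frozen=True)
class CorrectnessRule:
    """Which options count as correct, for compensation and sensitivity runs."""

    accepted_options: frozenset[TreatmentOption]

    def __post_init__(self) -> None:
        if not self.accepted_options:
            raise ValidationError("accepted_options must be non-empty")
        object.__setattr__(
            self,
            "accepted_options",
            frozenset(TreatmentOption.coerce(o) for o in self.accepted_options),
        )

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CorrectnessRule":
        return cls(frozenset(TreatmentOption.coerce(c) for c in codes))


#: Default: only the guideline-recommended option is correct.
DEFAULT_RULE = CorrectnessRule.from_codes(["C"])

#: Sensitivity variant: the milder undertreatment is also accepted.
SENSITIVITY_RULE = CorrectnessRule.from_codes(["B", "C"])


def is_correct(option: TreatmentOption | str, rule: CorrectnessRule = DEFAULT_RULE) -> bool:
    """True iff ``option`` is accepted by ``rule``."""
    return TreatmentOption.coerce(option) in rule.accepted_options
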