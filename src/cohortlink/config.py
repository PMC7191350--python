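"""Configuration objects for simulation, linkage, and pipeline runs.

All probabilities are validated to lie in [0, 1]; every configuration
error names the offending field so a bad YAML file fails loudly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of range or malformed."""


class InputError(ValueError):
    """Raised when input data violates a precondition (e.g. duplicate IDs)."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CorruptionRates:
    """Per-field identifier corruption probabilities.

    Applied independently per roster record, in fixed order:
    SSN missingness, then a one-character name typo, then name
    truncation (keeping a prefix of >= 3 letters), then a single
    date-of-birth component error.
    """

    ssn_missing: float = 0.15
    name_typo: float = 0.05
    name_truncation: float = 0.05
    dob_component_error: float = 0.02

    def __post_init__(self) -> None:
        for name in ("ssn_missing", "name_typo", "name_truncation", "dob_component_error"):
            _check_prob(f"corruption_rates.{name}", getattr(self, name))

    @classmethod
    def zero(cls) -> "CorruptionRates":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class OutcomeProbs:
    """Care-continuum outcome probabilities for one group.

    care_in_year         P(>=1 CD4/VL lab in the outcome year | >=1 lab ever)
    ever_suppressed      P(>=1 VL <= 200 copies/mL in the suppression window | >=1 lab)
    suppressed_last_lab  P(last outcome-year VL <= 200 | has an outcome-year VL)
    """

    care_in_year: float
    ever_suppressed: float
    suppressed_last_lab: float

    def __post_init__(self) -> None:
        for name in ("care_in_year", "ever_suppressed", "suppressed_last_lab"):
            _check_prob(f"outcome_model.{name}", getattr(self, name))


#: Group-specific defaults: cohort enrollees are more engaged in care than
#: the surveillance-only population, mirroring the engagement gap the
#: pipeline is built to measure.
DEFAULT_OUTCOME_MODEL: dict[str, OutcomeProbs] = {
    "cohort": OutcomeProbs(care_in_year=0.835, ever_suppressed=0.837, suppressed_last_lab=0.614),
    "non_cohort": OutcomeProbs(care_in_year=0.717, ever_suppressed=0.781, suppressed_last_lab=0.505),
}

#: Demographic category distributions (labels match the reporting schema).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "gender_identity": {"Male": 0.717, "Female": 0.266, "Transgender": 0.017},
    "race_ethnicity": {"White": 0.160, "Black": 0.746, "Hispanic": 0.068, "Other": 0.026},
    "transmission_risk": {
        "MSM": 0.443,
        "IDU": 0.106,
        "MSM/IDU": 0.032,
        "Heterosexual contact": 0.277,
        "Perinatal": 0.011,
        "Other": 0.001,
        "Not identified": 0.130,
    },
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic registry/roster generator.

    study_window is the enrollment window (consent dates, diagnosis-event
    window); clinical labs extend one calendar year past its end (the
    outcome year). Identical configs, including seed, reproduce
    byte-identical output tables.
    """

    n_persons: int = 13_000
    enroll_fraction: float = 0.4
    corruption_rates: CorruptionRates = field(default_factory=CorruptionRates)
    outcome_model: dict[str, OutcomeProbs] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MODEL)
    )
    labs_per_person_mean: float = 8.0
    study_window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2016, 12, 31))
    seed: int = 0
    # Secondary realism knobs (fractions of registry persons).
    non_resident_fraction: float = 0.05
    deceased_fraction: float = 0.03
    stale_lab_fraction: float = 0.04      # last lab predates the window
    withdrawal_fraction: float = 0.02     # consented then withdrew
    diagnosis_rates: dict[str, float] = field(
        default_factory=lambda: {
            "sti": 0.18,
            "hbv_chronic_confirmed": 0.015,
            "hcv_chronic_confirmed": 0.048,
            "oi_aids_defining": 0.15,
        }
    )
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )

    def __post_init__(self) -> None:
        if not isinstance(self.n_persons, int) or self.n_persons < 1:
            raise ConfigurationError(f"n_persons must be a positive integer, got {self.n_persons!r}")
        _check_prob("enroll_fraction", self.enroll_fraction)
        if self.labs_per_person_mean <= 0:
            raise ConfigurationError(
                f"labs_per_person_mean must be positive, got {self.labs_per_person_mean!r}"
            )
        start, end = self.study_window
        if not start < end:
            raise ConfigurationError(f"study_window start {start} must precede end {end}")
        for name in (
            "non_resident_fraction",
            "deceased_fraction",
            "stale_lab_fraction",
            "withdrawal_fraction",
        ):
            _check_prob(name, getattr(self, name))
        for grp in ("cohort", "non_cohort"):
            if grp not in self.outcome_model:
                raise ConfigurationError(f"outcome_model missing group {grp!r}")
        for kind, rate in self.diagnosis_rates.items():
            _check_prob(f"diagnosis_rates.{kind}", rate)
        for var, dist in self.demographics.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(f"demographics.{var} probabilities sum to {total}, not 1")

    @property
    def outcome_year(self) -> int:
        return self.study_window[1].year + 1

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "SimConfig":
        raw = dict(raw)
        if "corruption_rates" in raw and isinstance(raw["corruption_rates"], dict):
            raw["corruption_rates"] = CorruptionRates(**raw["corruption_rates"])
        if "outcome_model" in raw and isinstance(raw["outcome_model"], dict):
            raw["outcome_model"] = {
                grp: OutcomeProbs(**probs) if isinstance(probs, dict) else probs
                for grp, probs in raw["outcome_model"].items()
            }
        if "study_window" in raw:
            raw["study_window"] = tuple(
                d if isinstance(d, dt.date) else dt.date.fromisoformat(d)
                for d in raw["study_window"]
            )
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        out["study_window"] = [d.isoformat() for d in self.study_window]
        return out


@dataclass(frozen=True)
class ScoreWeights:
    """Field agreement weights of the validation score (rescaled to 0-100).

    The default weighting puts the most trust in SSN agreement, then
    names, then individual date-of-birth components.
    """

    ssn: float = 40.0
    first_name: float = 15.0
    last_name: float = 15.0
    dob_day: float = 10.0
    dob_month: float = 10.0
    dob_year: float = 10.0

    def __post_init__(self) -> None:
        total = self.ssn + self.first_name + self.last_name + self.dob_day + self.dob_month + self.dob_year
        if total <= 0:
            raise ConfigurationError(f"score weights must sum to a positive total, got {total}")
        for name in ("ssn", "first_name", "last_name", "dob_day", "dob_month", "dob_year"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"score weight {name} must be non-negative")


@dataclass(frozen=True)
class StudyWindow:
    """Analysis windows: eligibility labs, outcome year, suppression span.

    All intervals are closed. The eligibility window bounds the "last
    reported lab"; suppression is assessed through the end of the outcome
    year.
    """

    lab_window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2016, 12, 31))
    outcome_year: int = 2017
    suppression_window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2017, 12, 31))

    def __post_init__(self) -> None:
        if not self.lab_window[0] < self.lab_window[1]:
            raise ConfigurationError("lab_window start must precede end")
        if self.lab_window[1] > dt.date(self.outcome_year, 12, 31):
            raise ConfigurationError("lab_window must precede the end of the outcome year")

    @property
    def outcome_start(self) -> dt.date:
        return dt.date(self.outcome_year, 1, 1)

    @property
    def outcome_end(self) -> dt.date:
        return dt.date(self.outcome_year, 12, 31)

    @classmethod
    def from_sim_config(cls, sim: SimConfig) -> "StudyWindow":
        start, end = sim.study_window
        return cls(
            lab_window=(start, end),
            outcome_year=sim.outcome_year,
            suppression_window=(start, dt.date(sim.outcome_year, 12, 31)),
        )
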