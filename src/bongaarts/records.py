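"""Domain types and analysis configuration.

All dates are integer month indices (the semantics of DHS century-month
codes, CMC): month 1 is January 1900 in real DHS exports, but the model
only ever uses differences of month indices, so any consistent origin
works. Keeping dates integral removes every calendar edge case from the
exposure arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

MARITAL_STATUSES = ("never_married", "married", "formerly_married")

#: Contraceptive method vocabulary. ``none`` means no current use.
METHODS = (
    "none",
    "pill",
    "iud",
    "injection",
    "diaphragm",
    "condom",
    "sterilization",
    "implant",
    "foam_jelly",
    "lam",
    "rhythm",
    "withdrawal",
    "folk",
    "other_traditional",
)

#: The methods conventionally classed as modern in DHS reporting.
MODERN_METHODS = frozenset(
    {"pill", "iud", "injection", "diaphragm", "condom", "sterilization", "implant", "foam_jelly"}
)

MIN_AGE = 15
MAX_AGE = 49


class SchemaError(ValueError):
    """A structural problem with an input file (missing column, bad header)."""


class ConfigError(ValueError):
    """An invalid or unknown configuration key/value."""


class RecordError(ValueError):
    """A woman record violating a hard invariant."""


@dataclass(frozen=True)
class WomanRecord:
    """One surveyed woman of reproductive age.

    Parameters
    ----------
    woman_id:
        Opaque identifier, unique within a table.
    weight:
        Nonnegative sampling weight; 1.0 for unweighted/synthetic data.
        (Real DHS exports carry ``v005``; divide by 1,000,000 on ingest.)
    dob_cm, interview_cm:
        Month indices of the woman's birth and of the interview.
    marital_status:
        ``never_married`` / ``married`` / ``formerly_married``. "Married"
        pools formal marriages and consensual unions into one category.
    current_method:
        Current contraceptive method, ``none`` if not using.
    insusceptible_now:
        True when currently postpartum amenorrheic or postpartum
        abstaining (not at risk of conception following a birth).
    births_cm:
        Month indices of live births, may be empty.
    insus_months:
        Optional reported completed duration (months) of postpartum
        insusceptibility after the most recent birth; used only by the
        ``reported_duration`` estimator.
    stratifiers:
        Categorical background variables (residence, region, education,
        religion, wealth_quintile, ...). Extensible.
    """

    woman_id: str
    dob_cm: int
    interview_cm: int
    marital_status: str
    weight: float = 1.0
    current_method: str = "none"
    insusceptible_now: bool = False
    births_cm: tuple[int, ...] = ()
    insus_months: float | None = None
    stratifiers: Mapping[str, str] = field(default_factory=dict)

    @property
    def age_years(self) -> int:
        """Completed years of age at interview."""
        return (self.interview_cm - self.dob_cm) // 12

    def validate(self) -> list[str]:
        """Check invariants; raise :class:`RecordError` on hard violations.

        Returns a list of soft-warning strings (never raises for those).
        """
        if self.weight < 0:
            raise RecordError(f"{self.woman_id}: negative weight {self.weight}")
        if self.interview_cm <= self.dob_cm:
            raise RecordError(f"{self.woman_id}: interview_cm not after dob_cm")
        if not MIN_AGE <= self.age_years <= MAX_AGE:
            raise RecordError(f"{self.woman_id}: age out of range ({self.age_years})")
        if self.marital_status not in MARITAL_STATUSES:
            raise RecordError(f"{self.woman_id}: unknown marital_status {self.marital_status!r}")
        if self.current_method not in METHODS:
            raise RecordError(f"{self.woman_id}: unknown current_method {self.current_method!r}")
        for b in self.births_cm:
            if not (self.dob_cm < b <= self.interview_cm):
                raise RecordError(f"{self.woman_id}: birth month {b} outside (dob, interview]")
        warnings: list[str] = []
        if self.insusceptible_now and not self.births_cm:
            warnings.append(f"{self.woman_id}: insusceptible_now without any recorded birth")
        return warnings


@dataclass(frozen=True)
class EffectivenessTable:
    """Use-effectiveness e_m in [0, 1] per contraceptive method (excluding ``none``)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for method, e in self.values.items():
            if method == "none" or method not in METHODS:
                raise ConfigError(f"effectiveness: invalid method {method!r}")
            if not 0.0 <= e <= 1.0:
                raise ConfigError(f"effectiveness[{method}] = {e} outside [0, 1]")

    def lookup(self, method: str) -> float:
        if method == "none":
            raise KeyError("no effectiveness for 'none'")
        return self.values[method]


def default_effectiveness() -> EffectivenessTable:
    """Bongaarts' standard use-effectiveness schedule.

    Sterilization is a perfect method (1.0); IUD 0.95; other hormonal
    methods 0.90; barrier methods and LAM 0.70; traditional methods 0.50.
    Fully overridable through the ``effectiveness`` config block.
    """
    return EffectivenessTable(
        {
            "sterilization": 1.00,
            "iud": 0.95,
            "pill": 0.90,
            "injection": 0.90,
            "implant": 0.90,
            "condom": 0.70,
            "diaphragm": 0.70,
            "foam_jelly": 0.70,
            "lam": 0.70,
            "rhythm": 0.50,
            "withdrawal": 0.50,
            "folk": 0.50,
            "other_traditional": 0.50,
        }
    )


#: Default re-binning of education for decomposition output.
DEFAULT_EDUCATION_BINS = {
    "none": "none",
    "primary": "primary",
    "secondary": "secondary+",
    "higher": "secondary+",
}

_CM_METHODS = ("formula", "ratio")
_I_ESTIMATORS = ("prevalence_incidence", "reported_duration")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the aggregate fertility model fit.

    Defaults are the model's canonical constants: total fecundity
    TF = 15.3 births, sterility correction 1.08 in the contraception
    index, total abortion rate TA = 0 (so Ca = 1), and a 36-month
    births reference window.
    """

    window_months: int = 36
    tf: float = 15.3
    sterility_correction: float = 1.08
    ta: float = 0.0
    effectiveness: EffectivenessTable = field(default_factory=default_effectiveness)
    cm_method: str = "formula"
    i_estimator: str = "prevalence_incidence"
    min_stratum_n: int = 100
    education_bins: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_EDUCATION_BINS))

    def __post_init__(self) -> None:
        if self.window_months < 12:
            raise ConfigError(f"window_months must be >= 12, got {self.window_months}")
        if self.tf <= 0:
            raise ConfigError(f"tf must be positive, got {self.tf}")
        if not 0 < self.sterility_correction <= 1.2:
            raise ConfigError(f"sterility_correction must be in (0, 1.2], got {self.sterility_correction}")
        if self.ta < 0:
            raise ConfigError(f"ta must be nonnegative, got {self.ta}")
        if self.cm_method not in _CM_METHODS:
            raise ConfigError(f"cm_method must be one of {_CM_METHODS}, got {self.cm_method!r}")
        if self.i_estimator not in _I_ESTIMATORS:
            raise ConfigError(f"i_estimator must be one of {_I_ESTIMATORS}, got {self.i_estimator!r}")
        if self.min_stratum_n < 1:
            raise ConfigError(f"min_stratum_n must be positive, got {self.min_stratum_n}")

    def to_dict(self) -> dict:
        return {
            "window_months": self.window_months,
            "tf": self.tf,
            "sterility_correction": self.sterility_correction,
            "ta": self.ta,
            "effectiveness": dict(self.effectiveness.values),
            "cm_method": self.cm_method,
            "i_estimator": self.i_estimator,
            "min_stratum_n": self.min_stratum_n,
            "education_bins": dict(self.education_bins),
        }


_CONFIG_KEYS = (
    "window_months",
    "tf",
    "sterility_correction",
    "ta",
    "effectiveness",
    "cm_method",
    "i_estimator",
    "min_stratum_n",
    "education_bins",
    "column_map",
)


def load_config(path: str | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML/JSON key-value file.

    Every key is optional; absent keys take the model defaults. The
    ``effectiveness`` block overrides individual methods on top of the
    default schedule. An unknown key raises :class:`ConfigError` naming
    the valid keys. ``column_map`` is accepted here but consumed by the
    CSV reader, not by the model.
    """
    if path is None:
        return AnalysisConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    unknown = sorted(set(raw) - set(_CONFIG_KEYS))
    if unknown:
        raise ConfigError(f"unknown config keys {unknown}; valid keys are {sorted(_CONFIG_KEYS)}")
    kwargs: dict = {k: v for k, v in raw.items() if k not in ("effectiveness", "column_map")}
    if "effectiveness" in raw:
        merged = dict(default_effectiveness().values)
        merged.update({str(k): float(v) for k, v in raw["effectiveness"].items()})
        kwargs["effectiveness"] = EffectivenessTable(merged)
    return AnalysisConfig(**kwargs)


def load_column_map(path: str | None) -> dict[str, str] | None:
    """Extract the optional ``column_map`` block (canonical -> actual name)."""
    if path is None:
        return None
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cmap = raw.get("column_map")
    return {str(k): str(v) for k, v in cmap.items()} if cmap else None
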