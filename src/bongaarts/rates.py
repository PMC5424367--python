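"""Age-specific fertility schedules from birth histories.

Rates use person-month exposure over a reference window ending at the
interview: month m of the window contributes 1/12 person-years (times
the sampling weight) to the age group of the woman's completed age in
that month. Births 1..window months before interview are attributed to
the mother's completed-age group at the birth month. Age groups are the
seven standard 5-year bins 15–19 ... 45–49, closed on the left.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import MAX_AGE, MIN_AGE, WomanRecord

logger = logging.getLogger("bongaarts")

AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
N_GROUPS = len(AGE_GROUPS)


def age_group_index(age_years: int) -> int:
    """0-based bin of a completed age, or -1 outside [15, 49]."""
    if age_years < MIN_AGE or age_years > MAX_AGE:
        return -1
    return (age_years - MIN_AGE) // 5


@dataclass
class AgeSchedule:
    """A value per 5-year age group 15–19 ... 45–49."""

    values: Mapping[str, float]
    kind: str  # asfr | asmfr | proportion_married | exposure | births
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if tuple(self.values) != AGE_GROUPS:
            self.values = {g: float(self.values.get(g, 0.0)) for g in AGE_GROUPS}

    def as_array(self) -> np.ndarray:
        return np.array([self.values[g] for g in AGE_GROUPS], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float], kind: str, flags: list[str] | None = None) -> "AgeSchedule":
        return cls(dict(zip(AGE_GROUPS, map(float, arr))), kind, flags or [])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": AGE_GROUPS,
                "value": [self.values[g] for g in AGE_GROUPS],
                "flag": ["; ".join(f for f in self.flags if g in f) for g in AGE_GROUPS],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RateSet:
    """ASFR/ASMFR schedules with their totals and the marriage schedule."""

    asfr: AgeSchedule
    asmfr: AgeSchedule
    prop_married: AgeSchedule
    tfr: float
    tmfr: float


def _arrays(records: Sequence[WomanRecord]):
    dob = np.array([r.dob_cm for r in records], dtype=np.int64)
    interview = np.array([r.interview_cm for r in records], dtype=np.int64)
    weight = np.array([r.weight for r in records], dtype=float)
    return dob, interview, weight


def exposure_by_age(records: Sequence[WomanRecord], window_months: int) -> AgeSchedule:
    """Weighted person-years of exposure per age group over the window.

    Each month m in [interview − window, interview − 1] contributes
    weight/12 person-years to the group of the woman's completed age in
    month m; months at ages below 15 or above 49 are dropped.
    """
    totals = np.zeros(N_GROUPS)
    if not records:
        logger.warning("exposure_by_age: empty input, all-zero schedule")
        return AgeSchedule.from_array(totals, "exposure", ["empty input"])
    dob, interview, weight = _arrays(records)
    offsets = np.arange(1, window_months + 1, dtype=np.int64)
    age_months = interview[:, None] - offsets[None, :] - dob[:, None]  # (n, window)
    ages = age_months // 12
    groups = (ages - MIN_AGE) // 5
    valid = (ages >= MIN_AGE) & (ages <= MAX_AGE)
    # integer month counts per (woman, group), then one weighted multiply:
    # keeps the weighted sum numerically tight for the oracle comparison
    for g in range(N_GROUPS):
        months = ((groups == g) & valid).sum(axis=1)
        totals[g] = float(np.dot(weight, months) / 12.0)
    return AgeSchedule.from_array(totals, "exposure")


def births_by_age(
    records: Sequence[WomanRecord], window_months: int, married_only: bool = False
) -> AgeSchedule:
    """Weighted birth counts per age group of the mother at the birth month.

    Counts births with 1 <= interview − birth <= window. With
    ``married_only`` only births to currently married women count — a
    current-status approximation, since the schema carries no marriage
    histories.
    """
    totals = np.zeros(N_GROUPS)
    for rec in records:
        if married_only and rec.marital_status != "married":
            continue
        for b in rec.births_cm:
            lag = rec.interview_cm - b
            if not 1 <= lag <= window_months:
                continue
            g = age_group_index((b - rec.dob_cm) // 12)
            if g >= 0:
                totals[g] += rec.weight
    return AgeSchedule.from_array(totals, "births")


def rate_schedule(births: AgeSchedule, exposure: AgeSchedule, kind: str = "asfr") -> AgeSchedule:
    """Per-group births/exposure; zero-exposure groups give rate 0 with a flag."""
    b, e = births.as_array(), exposure.as_array()
    flags = []
    rates = np.zeros(N_GROUPS)
    for i, g in enumerate(AGE_GROUPS):
        if e[i] > 0:
            rates[i] = b[i] / e[i]
        elif b[i] > 0 or e[i] == 0:
            flags.append(f"zero exposure in {g}")
            logger.warning("rate_schedule: zero exposure in %s, rate set to 0", g)
    return AgeSchedule.from_array(rates, kind, flags)


def total_rate(schedule: AgeSchedule) -> float:
    """5 x the sum of the seven 5-year-group rates (TFR/TMFR construction)."""
    return 5.0 * float(schedule.as_array().sum())


def proportion_married_by_age(records: Sequence[WomanRecord]) -> AgeSchedule:
    """Weighted proportion currently married per age group at interview."""
    married = np.zeros(N_GROUPS)
    total = np.zeros(N_GROUPS)
    for rec in records:
        g = age_group_index(rec.age_years)
        if g < 0:
            continue
        total[g] += rec.weight
        if rec.marital_status == "married":
            married[g] += rec.weight
    flags = []
    props = np.zeros(N_GROUPS)
    for i, g in enumerate(AGE_GROUPS):
        if total[i] > 0:
            props[i] = married[i] / total[i]
        else:
            flags.append(f"empty age group {g}")
            logger.warning("proportion_married_by_age: empty group %s", g)
    return AgeSchedule.from_array(props, "proportion_married", flags)


def compute_rates(records: Sequence[WomanRecord], window_months: int) -> RateSet:
    """Full rate set: ASFR over all women, ASMFR over currently married women."""
    married = [r for r in records if r.marital_status == "married"]
    exp_all = exposure_by_age(records, window_months)
    exp_married = exposure_by_age(married, window_months)
    asfr = rate_schedule(births_by_age(records, window_months), exp_all, "asfr")
    asmfr = rate_schedule(births_by_age(married, window_months, married_only=True), exp_married, "asmfr")
    return RateSet(
        asfr=asfr,
        asmfr=asmfr,
        prop_married=proportion_married_by_age(records),
        tfr=total_rate(asfr),
        tmfr=total_rate(asmfr),
    )
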