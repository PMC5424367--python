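"""The four proximate-determinant indices and the aggregate model.

The aggregate model predicts the total fertility rate as

    TFR = Cm * Cc * Ci * Ca * TF

where each index lies in [0, 1] (1 = no fertility inhibition) and TF is
total fecundity, the theoretical maximum of 15.3 births per woman:

* Cm, marriage:        sum_a m(a) g(a) / sum_a g(a)   (or TFR/TMFR)
* Cc, contraception:   1 - 1.08 u e
* Ci, postpartum:      20 / (18.5 + i)
* Ca, abortion:        TFR / (TFR + b TA),  b = 0.4 (1 + u)

with m(a) the age-specific proportion currently married, g(a) the
age-specific marital fertility rate, u the contraceptive prevalence
among married women (any method), e the mean use-effectiveness among
users, i the mean postpartum-insusceptibility duration in months and
TA the total abortion rate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rates import AgeSchedule, RateSet, compute_rates
from .records import AnalysisConfig, EffectivenessTable, WomanRecord

logger = logging.getLogger("bongaarts")


class UndefinedIndexError(ValueError):
    """An index cannot be estimated from the data at hand (e.g. empty stratum)."""


class DomainError(ValueError):
    """Inputs outside the formula's domain (e.g. Cc would be negative)."""


@dataclass
class IndexSet:
    """Fitted quantities of the aggregate model for one population.

    ``tfr_predicted`` always equals ``cm * cc * ci * ca * tf`` exactly;
    out-of-range indices (e.g. Ci > 1 when i < 1.5 months) are reported
    with a warning, never clamped.
    """

    u: float
    e: float
    i: float
    ta: float
    cm: float
    cc: float
    ci: float
    ca: float
    tf: float
    tfr_observed: float
    tfr_predicted: float
    n_unweighted: int
    n_weighted: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "u": self.u,
            "e": self.e,
            "i": self.i,
            "ta": self.ta,
            "cm": self.cm,
            "cc": self.cc,
            "ci": self.ci,
            "ca": self.ca,
            "tf": self.tf,
            "tfr_observed": self.tfr_observed,
            "tfr_predicted": self.tfr_predicted,
            "n_unweighted": self.n_unweighted,
            "n_weighted": self.n_weighted,
            "warnings": "; ".join(self.warnings),
        }


def index_marriage(
    prop_married: AgeSchedule,
    asmfr: AgeSchedule,
    method: str = "formula",
    rates: RateSet | None = None,
) -> float:
    """Index of marriage Cm.

    ``formula``: sum m(a) g(a) / sum g(a) — marital fertility weights the
    marriage schedule so married women in the central childbearing ages
    count most. ``ratio``: TFR / TMFR, equivalent when all fertility is
    marital. Values outside [0, 1] are returned with a warning.
    """
    if method == "ratio":
        if rates is None or rates.tmfr <= 0:
            raise UndefinedIndexError("Cm (ratio): total marital fertility rate is zero")
        cm = rates.tfr / rates.tmfr
    else:
        m, g = prop_married.as_array(), asmfr.as_array()
        denom = float(g.sum())
        if denom <= 0:
            raise UndefinedIndexError("Cm (formula): sum of marital fertility g(a) is zero")
        cm = float(np.dot(m, g) / denom)
    if not 0.0 <= cm <= 1.0:
        logger.warning("Cm = %.6f outside [0, 1]", cm)
    return cm


def contraceptive_summary(
    records: Sequence[WomanRecord], effectiveness: EffectivenessTable
) -> tuple[float, float]:
    """Prevalence u and mean use-effectiveness e among married women.

    u counts ALL current methods, traditional included, each method
    weighted by its own use-effectiveness in e. When u = 0, e := 0 by
    convention.
    """
    w_married = 0.0
    w_using = 0.0
    w_eff = 0.0
    for rec in records:
        if rec.marital_status != "married":
            continue
        w_married += rec.weight
        if rec.current_method != "none":
            w_using += rec.weight
            w_eff += rec.weight * effectiveness.lookup(rec.current_method)
    if w_married <= 0:
        raise UndefinedIndexError("contraceptive summary: no married women in stratum")
    u = w_using / w_married
    e = w_eff / w_using if w_using > 0 else 0.0
    return u, e


def index_contraception(u: float, e: float, sterility_correction: float = 1.08) -> float:
    """Index of contraception Cc = 1 − 1.08 u e (1 when no contraception is used)."""
    if not 0.0 <= u <= 1.0 or not 0.0 <= e <= 1.0:
        raise DomainError(f"u and e must be in [0, 1]: u={u}, e={e}")
    cc = 1.0 - sterility_correction * u * e
    if cc < 0:
        raise DomainError(
            f"Cc = {cc:.4f} < 0: prevalence u={u} and effectiveness e={e} "
            f"inconsistent with correction {sterility_correction}"
        )
    return cc


def mean_insusceptibility(
    records: Sequence[WomanRecord],
    window_months: int,
    estimator: str = "prevalence_incidence",
) -> float:
    """Mean postpartum-insusceptibility duration i (months).

    ``prevalence_incidence`` is a current-status estimator: the weighted
    count of women currently insusceptible divided by the mean monthly
    (weighted) number of births over the reference window. In a
    stationary population prevalence = incidence x mean duration, so the
    ratio recovers the mean duration without duration reporting.

    ``reported_duration`` averages the optional ``insus_months`` column.
    """
    if estimator == "reported_duration":
        w_sum = sum(r.weight for r in records if r.insus_months is not None)
        if w_sum <= 0:
            raise UndefinedIndexError("i (reported_duration): no reported durations")
        return sum(r.weight * r.insus_months for r in records if r.insus_months is not None) / w_sum
    births_w = 0.0
    insus_w = 0.0
    for rec in records:
        if rec.insusceptible_now:
            insus_w += rec.weight
        for b in rec.births_cm:
            if 1 <= rec.interview_cm - b <= window_months:
                births_w += rec.weight
    if births_w <= 0:
        raise UndefinedIndexError("i (prevalence_incidence): no births in reference window")
    return insus_w / (births_w / window_months)


def index_postpartum(i: float) -> float:
    """Index of postpartum infecundability Ci = 20 / (18.5 + i).

    20 months is the average birth interval absent breastfeeding and
    postpartum abstinence (1.5 months minimum anovulation + 7.5 waiting
    time to conception + 2 intrauterine mortality + 9 gestation); with
    them the interval is 18.5 + i. Values above 1 (i < 1.5) are returned
    with a warning, not clamped.
    """
    if i < 0:
        raise DomainError(f"mean insusceptibility duration must be >= 0, got {i}")
    ci = 20.0 / (18.5 + i)
    if ci > 1.0:
        logger.warning("Ci = %.6f > 1 (i = %.2f < 1.5 months)", ci, i)
    return ci


def index_abortion(tfr: float, ta: float, u: float) -> float:
    """Index of abortion Ca = TFR / (TFR + b TA) with b = 0.4 (1 + u).

    b is the average number of births averted per induced abortion;
    Ca = 1 when the total abortion rate TA is 0.
    """
    if tfr < 0 or ta < 0 or not 0.0 <= u <= 1.0:
        raise DomainError(f"invalid inputs: tfr={tfr}, ta={ta}, u={u}")
    if ta == 0:
        if tfr == 0:
            logger.warning("Ca: TFR = TA = 0, vacuously 1.0")
        return 1.0
    if tfr == 0:
        return 0.0
    return tfr / (tfr + 0.4 * (1.0 + u) * ta)


def predicted_tfr(cm: float, cc: float, ci: float, ca: float, tf: float = 15.3) -> float:
    """Model-predicted TFR = Cm * Cc * Ci * Ca * TF."""
    if min(cm, cc, ci, ca, tf) < 0:
        raise DomainError("all arguments must be nonnegative")
    return cm * cc * ci * ca * tf


def fit_index_set(records: Sequence[WomanRecord], config: AnalysisConfig | None = None) -> IndexSet:
    """Estimate the full index set for one population of women.

    Pipeline: rate schedules -> Cm -> (u, e) -> Cc -> i -> Ci -> Ca
    (with the configured total abortion rate) -> predicted TFR.
    """
    if config is None:
        config = AnalysisConfig()
    if not records:
        raise UndefinedIndexError("empty record table")
    warnings: list[str] = []
    rates = compute_rates(records, config.window_months)
    cm = index_marriage(rates.prop_married, rates.asmfr, config.cm_method, rates)
    if not 0.0 <= cm <= 1.0:
        warnings.append(f"Cm = {cm:.6f} outside [0, 1]")
    u, e = contraceptive_summary(records, config.effectiveness)
    cc = index_contraception(u, e, config.sterility_correction)
    i = mean_insusceptibility(records, config.window_months, config.i_estimator)
    ci = index_postpartum(i)
    if ci > 1.0:
        warnings.append(f"Ci = {ci:.6f} > 1 (i = {i:.2f} < 1.5 months)")
    ca = index_abortion(rates.tfr, config.ta, u)
    return IndexSet(
        u=u,
        e=e,
        i=i,
        ta=config.ta,
        cm=cm,
        cc=cc,
        ci=ci,
        ca=ca,
        tf=config.tf,
        tfr_observed=rates.tfr,
        tfr_predicted=predicted_tfr(cm, cc, ci, ca, config.tf),
        n_unweighted=len(records),
        n_weighted=float(sum(r.weight for r in records)),
        warnings=warnings,
    )
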