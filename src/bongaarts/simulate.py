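"""Seeded monthly microsimulation of a synthetic survey cohort.

Generates women's records whose true proximate-determinant parameters
(contraceptive prevalence u, mean use-effectiveness e, mean postpartum
insusceptibility i, marriage schedule m(a)) are known by construction,
so every pipeline stage can be tested without restricted survey
microdata.

Each woman's reproductive history runs month by month from exact age 15
to her interview through the states exposed -> pregnant (9 months) ->
postpartum insusceptible (random duration, geometric with mean
``insusceptibility_mean``) -> exposed. While exposed, the monthly
conception probability is ``fecundability`` for married non-users,
``fecundability * (1 - e_method)`` for users, and
``fecundability * nonmarital_exposure_factor`` for women not currently
married (0 by default: no premarital or post-union exposure). Marriage
and contraceptive use are current-status draws applied to the whole
history — the same approximation the estimators themselves make.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .indices import IndexSet, index_contraception, index_postpartum, predicted_tfr
from .rates import AGE_GROUPS, AgeSchedule, compute_rates
from .records import METHODS, EffectivenessTable, WomanRecord, default_effectiveness

GESTATION_MONTHS = 9
_INTERVIEW_CM = 1404  # arbitrary fixed interview month index

#: Age-group shares of women 15-49, roughly a high-fertility East African
#: age pyramid (youngest groups largest).
DEFAULT_AGE_DISTRIBUTION = (0.232, 0.193, 0.178, 0.128, 0.116, 0.084, 0.069)

#: Proportion currently married by age group, rising steeply out of the
#: teens and plateauing around four in five women.
DEFAULT_MARRIAGE_SCHEDULE = (0.20, 0.62, 0.78, 0.82, 0.82, 0.80, 0.76)

#: Share of currently non-married women who are formerly (vs never) married.
_FORMERLY_SHARE = (0.03, 0.20, 0.40, 0.55, 0.65, 0.75, 0.85)

#: Method mix among users: injectable-dominated, with a traditional tail.
DEFAULT_METHOD_MIX = {
    "injection": 0.40,
    "pill": 0.12,
    "condom": 0.10,
    "implant": 0.08,
    "sterilization": 0.06,
    "lam": 0.05,
    "iud": 0.02,
    "rhythm": 0.09,
    "withdrawal": 0.05,
    "other_traditional": 0.03,
}


class ParamError(ValueError):
    """Invalid simulation parameters (raised before any sampling)."""


@dataclass
class StratifierSpec:
    """One categorical background variable: category probabilities plus
    optional per-category overrides of u_true / fecundability /
    insusceptibility_mean (how socioeconomic differentials are planted)."""

    categories: Mapping[str, float]
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def default_stratifiers() -> dict[str, StratifierSpec]:
    return {
        "residence": StratifierSpec({"urban": 0.20, "rural": 0.80}),
        "region": StratifierSpec(
            {"kampala": 0.10, "central": 0.21, "eastern": 0.24, "northern": 0.18, "western": 0.27}
        ),
        "education": StratifierSpec({"none": 0.13, "primary": 0.59, "secondary": 0.23, "higher": 0.05}),
        "religion": StratifierSpec(
            {"catholic": 0.41, "protestant": 0.43, "muslim": 0.13, "other": 0.03}
        ),
        "wealth_quintile": StratifierSpec(
            {"poorest": 0.18, "poorer": 0.18, "middle": 0.19, "richer": 0.20, "richest": 0.25}
        ),
    }


@dataclass
class SimulationParams:
    """Generative parameters of a synthetic cohort and their implied truths."""

    n_women: int = 1000
    seed: int = 0
    age_distribution: Sequence[float] = DEFAULT_AGE_DISTRIBUTION
    marriage_schedule: Sequence[float] = DEFAULT_MARRIAGE_SCHEDULE
    u_true: float = 0.30
    method_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_METHOD_MIX))
    fecundability: float = 0.2
    insusceptibility_mean: float = 11.5
    gestation_months: int = GESTATION_MONTHS
    nonmarital_exposure_factor: float = 0.0
    effectiveness: EffectivenessTable = field(default_factory=default_effectiveness)
    stratifiers: Mapping[str, StratifierSpec] = field(default_factory=default_stratifiers)
    interview_cm: int = _INTERVIEW_CM

    def validate(self) -> None:
        if self.n_women < 1:
            raise ParamError("n_women must be positive")
        for name, probs in (
            ("age_distribution", self.age_distribution),
            ("marriage_schedule", self.marriage_schedule),
        ):
            if len(probs) != len(AGE_GROUPS):
                raise ParamError(f"{name} needs {len(AGE_GROUPS)} entries")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ParamError(f"{name} values must be in [0, 1]")
        if abs(sum(self.age_distribution) - 1.0) > 1e-9:
            raise ParamError("age_distribution must sum to 1")
        if not 0.0 <= self.u_true <= 1.0:
            raise ParamError("u_true must be in [0, 1]")
        mix_total = sum(self.method_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ParamError("method_mix must sum to 1")
        for m in self.method_mix:
            if m not in METHODS or m == "none":
                raise ParamError(f"method_mix: invalid method {m!r}")
        if not 0.0 <= self.fecundability <= 1.0:
            raise ParamError("fecundability must be in [0, 1]")
        if self.insusceptibility_mean < 0:
            raise ParamError("insusceptibility_mean must be >= 0")
        if not 0.0 <= self.nonmarital_exposure_factor <= 1.0:
            raise ParamError("nonmarital_exposure_factor must be in [0, 1]")
        if self.gestation_months < 1:
            raise ParamError("gestation_months must be >= 1")
        for name, spec in self.stratifiers.items():
            if abs(sum(spec.categories.values()) - 1.0) > 1e-9:
                raise ParamError(f"stratifier {name}: category probabilities must sum to 1")
            for cat in spec.overrides:
                if cat not in spec.categories:
                    raise ParamError(f"stratifier {name}: override for unknown category {cat!r}")

    def mean_effectiveness(self) -> float:
        """True mean use-effectiveness implied by the method mix."""
        return sum(p * self.effectiveness.lookup(m) for m, p in self.method_mix.items())


def _draw_durations(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Postpartum insusceptibility durations: geometric on {1, 2, ...} with
    the given mean (p = 1/mean); 0 everywhere when mean < 1."""
    if mean < 1.0:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(1.0 / mean, size=size).astype(np.int64)


def simulate_cohort(params: SimulationParams) -> list[WomanRecord]:
    """Generate a cohort of :class:`WomanRecord`; deterministic under (seed, params)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_women

    group = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(params.age_distribution, dtype=float))
    # exact age in months, uniform within the 5-year group
    age_months = 15 * 12 + group * 60 + rng.integers(0, 60, size=n)
    dob = params.interview_cm - age_months

    sched = np.asarray(params.marriage_schedule, dtype=float)
    married = rng.random(n) < sched[group]
    formerly = (~married) & (rng.random(n) < np.asarray(_FORMERLY_SHARE)[group])
    status = np.where(married, "married", np.where(formerly, "formerly_married", "never_married"))

    # stratifiers and per-woman generative parameters (overrides planted here)
    strat_values: dict[str, np.ndarray] = {}
    u_w = np.full(n, params.u_true)
    fec_w = np.full(n, params.fecundability)
    insus_mean_w = np.full(n, params.insusceptibility_mean)
    for name, spec in params.stratifiers.items():
        cats = list(spec.categories)
        probs = np.array([spec.categories[c] for c in cats], dtype=float)
        drawn = rng.choice(len(cats), size=n, p=probs)
        strat_values[name] = np.array(cats, dtype=object)[drawn]
        for cat, over in spec.overrides.items():
            mask = strat_values[name] == cat
            if "u_true" in over:
                u_w[mask] = over["u_true"]
            if "fecundability" in over:
                fec_w[mask] = over["fecundability"]
            if "insusceptibility_mean" in over:
                insus_mean_w[mask] = over["insusceptibility_mean"]

    using = married & (rng.random(n) < u_w)
    mix_methods = list(params.method_mix)
    mix_probs = np.array([params.method_mix[m] for m in mix_methods], dtype=float)
    method = np.full(n, "none", dtype=object)
    if using.any():
        picks = rng.choice(len(mix_methods), size=int(using.sum()), p=mix_probs)
        method[using] = np.array(mix_methods, dtype=object)[picks]
    eff = np.array(
        [params.effectiveness.lookup(m) if m != "none" else 0.0 for m in method], dtype=float
    )

    # monthly conception probability per woman, constant over her history
    p_conceive = np.where(
        married, fec_w * (1.0 - eff), fec_w * params.nonmarital_exposure_factor
    )

    # month-by-month history from exact age 15 (month index 180) to interview
    preg_left = np.zeros(n, dtype=np.int64)
    insus_left = np.zeros(n, dtype=np.int64)
    births: list[list[int]] = [[] for _ in range(n)]
    max_t = int(age_months.max())
    for t in range(15 * 12, max_t):
        active = t < age_months
        pregnant = active & (preg_left > 0)
        preg_left[pregnant] -= 1
        delivering = pregnant & (preg_left == 0)
        if delivering.any():
            idx = np.flatnonzero(delivering)
            for j in idx:
                births[j].append(int(dob[j] + t))
            durs = np.zeros(len(idx), dtype=np.int64)
            for k, j in enumerate(idx):
                durs[k] = _draw_durations(rng, float(insus_mean_w[j]), 1)[0]
            insus_left[idx] = durs
        insusceptible = active & ~pregnant & (insus_left > 0)
        insus_left[insusceptible] -= 1
        exposed = active & ~pregnant & ~insusceptible
        conceive = exposed & (rng.random(n) < p_conceive)
        preg_left[conceive] = params.gestation_months

    insusceptible_now = insus_left > 0

    records = []
    for j in range(n):
        records.append(
            WomanRecord(
                woman_id=f"W{j:06d}",
                weight=1.0,
                dob_cm=int(dob[j]),
                interview_cm=params.interview_cm,
                marital_status=str(status[j]),
                current_method=str(method[j]),
                insusceptible_now=bool(insusceptible_now[j]),
                births_cm=tuple(births[j]),
                stratifiers={name: str(strat_values[name][j]) for name in strat_values},
            )
        )
    return records


def true_index_set(params: SimulationParams, reference_n: int = 8000) -> IndexSet:
    """Expected index values implied by the generative parameters.

    Cc and Ci follow in closed form from u_true, the method mix and the
    mean insusceptibility; Ca is 1 (no abortion in the generator). Cm is
    1 when the marriage schedule is all-ones; otherwise it is computed
    from the target m(a) and the realised marital fertility g(a) of a
    large reference run (marital fertility has no closed form here).
    """
    params.validate()
    e_bar = params.mean_effectiveness()
    cc = index_contraception(params.u_true, e_bar)
    ci = index_postpartum(params.insusceptibility_mean)
    if all(abs(p - 1.0) < 1e-12 for p in params.marriage_schedule):
        cm = 1.0
    else:
        ref = SimulationParams(
            **{
                **params.__dict__,
                "n_women": reference_n,
                "seed": (params.seed * 2654435761 + 1) % (2**31),
            }
        )
        rates = compute_rates(simulate_cohort(ref), 36)
        g = rates.asmfr.as_array()
        m = np.asarray(params.marriage_schedule, dtype=float)
        cm = float(np.dot(m, g) / g.sum()) if g.sum() > 0 else 1.0
    ca = 1.0
    tf = 15.3
    return IndexSet(
        u=params.u_true,
        e=e_bar,
        i=params.insusceptibility_mean,
        ta=0.0,
        cm=cm,
        cc=cc,
        ci=ci,
        ca=ca,
        tf=tf,
        tfr_observed=float("nan"),
        tfr_predicted=predicted_tfr(cm, cc, ci, ca, tf),
        n_unweighted=params.n_women,
        n_weighted=float(params.n_women),
    )
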