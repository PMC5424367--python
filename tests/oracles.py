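"""Independent brute-force oracles: per-woman per-month pure-Python loops.

Deliberately naive and structurally unrelated to the vectorised
implementation so the two can check each other.
"""
from __future__ import annotations

from bongaarts.rates import AGE_GROUPS


def _group_of(age: int) -> str | None:
    if 15 <= age <= 49:
        return AGE_GROUPS[(age - 15) // 5]
    return None


def brute_exposure(records, window_months: int) -> dict[str, float]:
    totals = {g: 0.0 for g in AGE_GROUPS}
    for rec in records:
        for k in range(1, window_months + 1):
            month = rec.interview_cm - k
            g = _group_of((month - rec.dob_cm) // 12)
            if g is not None:
                totals[g] += rec.weight / 12.0
    return totals


def brute_births(records, window_months: int, married_only: bool = False) -> dict[str, float]:
    totals = {g: 0.0 for g in AGE_GROUPS}
    for rec in records:
        if married_only and rec.marital_status != "married":
            continue
        for b in rec.births_cm:
            if 1 <= rec.interview_cm - b <= window_months:
                g = _group_of((b - rec.dob_cm) // 12)
                if g is not None:
                    totals[g] += rec.weight
    return totals


def brute_tfr(records, window_months: int) -> float:
    births = brute_births(records, window_months)
    exposure = brute_exposure(records, window_months)
    return 5.0 * sum(
        births[g] / exposure[g] for g in AGE_GROUPS if exposure[g] > 0
    )
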