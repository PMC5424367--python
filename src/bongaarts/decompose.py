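"""Stratified decomposition of the aggregate model and weighted tabulation.

Fits the full index set within each category of one or more background
variables (residence, region, education, religion, wealth quintile, ...)
plus a TOTAL row, and renders the long-format results as CSV or as a
fixed-width text table with indices to 6 decimals and TFR to 1 decimal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .indices import IndexSet, UndefinedIndexError, fit_index_set
from .records import AnalysisConfig, WomanRecord

logger = logging.getLogger("bongaarts")

MISSING_CATEGORY = "(missing)"


@dataclass
class StratumResult:
    """Fitted index set for one (variable, category) cell."""

    variable: str
    category: str
    index_set: IndexSet | None
    flags: list[str] = field(default_factory=list)


def _category_of(rec: WomanRecord, variable: str, config: AnalysisConfig) -> str:
    raw = rec.stratifiers.get(variable, "")
    if raw is None or str(raw).strip() == "":
        return MISSING_CATEGORY
    raw = str(raw)
    if variable == "education":
        return config.education_bins.get(raw, raw)
    return raw


def decompose(
    records: Sequence[WomanRecord],
    by_variables: Sequence[str],
    config: AnalysisConfig | None = None,
) -> list[StratumResult]:
    """Fit the index set within each category of each variable, plus TOTAL.

    Education is re-binned per ``config.education_bins`` (default
    none / primary / secondary+). Missing stratifier values form an
    explicit ``(missing)`` category. Strata with fewer than
    ``config.min_stratum_n`` women are flagged; a stratum whose fit
    fails (e.g. no married women) is reported with the failure in its
    flags rather than aborting the others.
    """
    if config is None:
        config = AnalysisConfig()
    available = sorted({name for rec in records for name in rec.stratifiers})
    results: list[StratumResult] = []
    for variable in by_variables:
        if not any(variable in rec.stratifiers for rec in records):
            raise KeyError(f"unknown stratifier {variable!r}; available: {available}")
        cats: dict[str, list[WomanRecord]] = {}
        for rec in records:
            cats.setdefault(_category_of(rec, variable, config), []).append(rec)
        for category in sorted(cats):
            subset = cats[category]
            flags = []
            if len(subset) < config.min_stratum_n:
                flags.append(f"small stratum (n={len(subset)} < {config.min_stratum_n})")
                logger.warning("%s=%s: %s", variable, category, flags[-1])
            try:
                iset = fit_index_set(subset, config)
                flags.extend(iset.warnings)
            except UndefinedIndexError as exc:
                logger.warning("%s=%s: %s", variable, category, exc)
                iset = None
                flags.append(str(exc))
            results.append(StratumResult(variable, category, iset, flags))
    total = fit_index_set(list(records), config)
    results.append(StratumResult("TOTAL", "TOTAL", total, list(total.warnings)))
    return results


def tabulate_weighted(records: Sequence[WomanRecord], variable: str) -> pd.DataFrame:
    """Weighted frequency distribution of one stratifier.

    Columns: category, n_unweighted, weighted_n, percent (summing to 100
    within rounding).
    """
    if not any(variable in rec.stratifiers for rec in records):
        available = sorted({name for rec in records for name in rec.stratifiers})
        raise KeyError(f"unknown stratifier {variable!r}; available: {available}")
    rows: dict[str, dict] = {}
    for rec in records:
        cat = rec.stratifiers.get(variable) or MISSING_CATEGORY
        entry = rows.setdefault(str(cat), {"n_unweighted": 0, "weighted_n": 0.0})
        entry["n_unweighted"] += 1
        entry["weighted_n"] += rec.weight
    df = pd.DataFrame(
        [{"category": c, **v} for c, v in sorted(rows.items())],
    )
    total_w = df["weighted_n"].sum()
    df["percent"] = 100.0 * df["weighted_n"] / total_w if total_w > 0 else 0.0
    return df


def results_to_frame(results: Sequence[StratumResult]) -> pd.DataFrame:
    """Long-format table: one row per stratum with every fitted quantity."""
    rows = []
    for res in results:
        base = {"variable": res.variable, "category": res.category}
        if res.index_set is not None:
            base.update(res.index_set.to_dict())
        base["flags"] = "; ".join(res.flags)
        rows.append(base)
    columns = [
        "variable", "category", "u", "e", "i", "ta", "cm", "cc", "ci", "ca",
        "tf", "tfr_observed", "tfr_predicted", "n_unweighted", "n_weighted",
        "warnings", "flags",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def _round_half_up(x: float, places: int) -> str:
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def render_table(results: Sequence[StratumResult]) -> str:
    """Fixed-width text table: indices to 6 decimals, TFR to 1 decimal."""
    header = ("Variable", "Category", "Cm", "Cc", "Ci", "Ca", "TFR")
    body: list[tuple[str, ...]] = []
    for res in results:
        if res.index_set is None:
            body.append((res.variable, res.category, "-", "-", "-", "-", "-"))
            continue
        s = res.index_set
        body.append(
            (
                res.variable,
                res.category,
                _round_half_up(s.cm, 6),
                _round_half_up(s.cc, 6),
                _round_half_up(s.ci, 6),
                _round_half_up(s.ca, 1),
                _round_half_up(s.tfr_predicted, 1),
            )
        )
    widths = [max(len(h), *(len(r[i]) for r in body)) if body else len(h) for i, h in enumerate(header)]
    def fmt(row: tuple[str, ...]) -> str:
        return "  ".join(c.ljust(w) if i < 2 else c.rjust(w) for i, (c, w) in enumerate(zip(row, widths)))
    lines = [fmt(header), fmt(tuple("-" * w for w in widths))]
    lines.extend(fmt(r) for r in body)
    return "\n".join(lines) + "\n"
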