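"""CSV schema, reader and writer for women's record tables.

The canonical file is UTF-8 CSV with a header row and one row per woman:

======================  =======================================================
column                  contents
======================  =======================================================
woman_id                opaque identifier
weight                  nonnegative sampling weight (1.0 if unweighted)
dob_cm                  month index of woman's birth
interview_cm            month index of interview
marital_status          never_married / married / formerly_married
current_method          contraceptive method, ``none`` if not using
insusceptible_now       0/1 — currently postpartum amenorrheic or abstaining
births_cm               ``;``-delimited month indices of live births (may be
                        empty); alternatively wide columns b1_cm, b2_cm, ...
insus_months            optional reported insusceptibility duration (months)
<anything else>         treated as a categorical stratifier column
======================  =======================================================

A ``column_map`` (canonical name -> actual header) lets real survey
exports be read without renaming; e.g. DHS women's recodes after
``weight = v005 / 1,000,000`` has been applied upstream.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import RecordError, SchemaError, WomanRecord

logger = logging.getLogger("bongaarts")

CORE_COLUMNS = (
    "woman_id",
    "weight",
    "dob_cm",
    "interview_cm",
    "marital_status",
    "current_method",
    "insusceptible_now",
)
_WIDE_BIRTH_RE = re.compile(r"^b(\d+)_cm$")
_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f", ""}


@dataclass
class LoadReport:
    """Outcome of reading a women's CSV: counts plus per-row diagnostics."""

    rows_read: int = 0
    rows_rejected: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (row label, reason)
    warnings: list[str] = field(default_factory=list)

    def log(self) -> None:
        logger.info(
            "load report: %d rows read, %d rejected, %d warnings",
            self.rows_read,
            self.rows_rejected,
            len(self.warnings),
        )
        for label, reason in self.rejections:
            logger.info("rejected row %s: %s", label, reason)
        for w in self.warnings:
            logger.warning("%s", w)


def _parse_bool(raw: str, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValueError(f"unparseable boolean in {column}: {raw!r}")


def _parse_births(row: pd.Series, wide_cols: Sequence[str]) -> tuple[int, ...]:
    if "births_cm" in row.index and not _is_blank(row["births_cm"]):
        parts = [p for p in str(row["births_cm"]).split(";") if p.strip() != ""]
        return tuple(int(float(p)) for p in parts)
    births = []
    for c in wide_cols:
        if not _is_blank(row.get(c)):
            births.append(int(float(row[c])))
    return tuple(births)


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "" or str(v) == "nan"


def read_women_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[WomanRecord], LoadReport]:
    """Read and validate a women's record table.

    Rows violating a hard invariant (age outside 15–49, births outside
    the (dob, interview] range, unknown categories, unparseable month
    indices) are rejected and counted in the returned
    :class:`LoadReport`; soft problems become warnings. The report is
    also emitted to the ``bongaarts`` logger at INFO level.

    Raises :class:`SchemaError` when a mandatory column is missing.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        reverse = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=reverse)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    wide_cols = sorted(
        (c for c in df.columns if _WIDE_BIRTH_RE.match(c)),
        key=lambda c: int(_WIDE_BIRTH_RE.match(c).group(1)),
    )
    known = set(CORE_COLUMNS) | {"births_cm", "insus_months"} | set(wide_cols)
    strat_cols = [c for c in df.columns if c not in known]

    report = LoadReport(rows_read=len(df))
    records: list[WomanRecord] = []
    for idx, row in df.iterrows():
        label = str(row.get("woman_id") or f"row {idx + 2}")
        try:
            rec = WomanRecord(
                woman_id=str(row["woman_id"]),
                weight=float(row["weight"]),
                dob_cm=int(float(row["dob_cm"])),
                interview_cm=int(float(row["interview_cm"])),
                marital_status=str(row["marital_status"]).strip(),
                current_method=str(row["current_method"]).strip(),
                insusceptible_now=_parse_bool(row["insusceptible_now"], "insusceptible_now"),
                births_cm=_parse_births(row, wide_cols),
                insus_months=None
                if _is_blank(row.get("insus_months"))
                else float(row["insus_months"]),
                stratifiers={c: str(row[c]) for c in strat_cols},
            )
            report.warnings.extend(rec.validate())
        except (RecordError, ValueError) as exc:
            reason = str(exc)
            if "age out of range" in reason:
                reason = "age out of range"
            report.rows_rejected += 1
            report.rejections.append((label, reason))
            continue
        records.append(rec)
    report.log()
    return records, report


def write_women_csv(records: Iterable[WomanRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect (births as a ``;`` list)."""
    records = list(records)
    strat_cols: list[str] = []
    for rec in records:
        for name in rec.stratifiers:
            if name not in strat_cols:
                strat_cols.append(name)
    rows = []
    for rec in records:
        row = {
            "woman_id": rec.woman_id,
            "weight": repr(rec.weight) if rec.weight != int(rec.weight) else str(rec.weight),
            "dob_cm": rec.dob_cm,
            "interview_cm": rec.interview_cm,
            "marital_status": rec.marital_status,
            "current_method": rec.current_method,
            "insusceptible_now": int(rec.insusceptible_now),
            "births_cm": ";".join(str(b) for b in rec.births_cm),
            "insus_months": "" if rec.insus_months is None else rec.insus_months,
        }
        for c in strat_cols:
            row[c] = rec.stratifiers.get(c, "")
        rows.append(row)
    columns = list(CORE_COLUMNS) + ["births_cm", "insus_months"] + strat_cols
    # reorder: weight after woman_id per CORE_COLUMNS ordering already
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
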