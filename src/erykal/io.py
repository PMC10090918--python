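"""Tabular input and report output.

CSV dialect: comma-separated, UTF-8, header required, dot decimal separator.
Required columns: k_hem, k_pl, ht; optional: patient_id, time, cl, hb,
mass_kg, dilution (empty cells mean missing).  Units are fixed at mmol/L and
percent — mEq/L equals mmol/L for monovalent ions, so no conversion layer
exists.

Rows failing validation are quarantined with a reason, never dropped
silently; every applied default (e.g. assumed chloride) is logged at INFO.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DomainError
from .cohort import CorrelationResult, FilterReport, SummaryStats
from .table import RAW_COLUMNS, CohortTable

log = logging.getLogger("erykal")

SCHEMA_VERSION = 1
REQUIRED_COLUMNS = ("k_hem", "k_pl", "ht")


@dataclass
class ReadResult:
    """Accepted rows as a cohort table plus per-row quarantine reasons.

    ``len(table) + len(quarantined)`` always equals the input row count.
    """

    table: CohortTable
    quarantined: pd.DataFrame  # original row values + "reason" column


def _row_problem(row: pd.Series) -> Optional[str]:
    for col in REQUIRED_COLUMNS:
        if pd.isna(row[col]):
            return f"missing or unparseable {col}"
    if not (0.0 < row["ht"] < 100.0):
        return "hematocrit out of range (must be percent in (0, 100))"
    if row["k_hem"] < 0 or row["k_pl"] < 0:
        return "negative concentration"
    if not pd.isna(row["cl"]) and row["cl"] < 0:
        return "negative chloride"
    if not pd.isna(row["dilution"]) and row["dilution"] <= 0:
        return "nonpositive dilution"
    if not pd.isna(row["mass_kg"]) and row["mass_kg"] <= 0:
        return "nonpositive body mass"
    return None


def read_samples(path) -> ReadResult:
    """Read a samples CSV into a validated :class:`CohortTable`.

    Raises on a missing required column; individual bad rows (unparseable
    numbers, out-of-range hematocrit, negative concentrations) are moved to
    the quarantine frame with a stated reason.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise DomainError(
            f"{path.name}: missing required column(s) {missing}; header was {list(raw.columns)}"
        )
    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"].replace("", np.nan) if "patient_id" in raw else np.nan
    numeric_cols = [c for c in RAW_COLUMNS if c != "patient_id"]
    for col in numeric_cols:
        if col in raw.columns:
            df[col] = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        else:
            df[col] = np.nan

    reasons = df.apply(_row_problem, axis=1)
    # distinguish "cell present but unparseable" from "cell empty" for required cols
    for col in REQUIRED_COLUMNS:
        if col in raw.columns:
            garbled = (raw[col] != "") & df[col].isna()
            reasons[garbled & reasons.isna()] = f"unparseable {col}"
    bad = reasons.notna()
    quarantined = raw[bad].copy()
    quarantined["reason"] = reasons[bad]
    if bad.any():
        log.warning("%s: quarantined %d of %d rows", path.name, int(bad.sum()), len(raw))
    table = CohortTable(df[~bad].reset_index(drop=True))
    return ReadResult(table=table, quarantined=quarantined.reset_index(drop=True))


def write_report(
    path,
    panels: Optional[CohortTable] = None,
    filter_report: Optional[FilterReport] = None,
    stats: Optional[dict[str, SummaryStats]] = None,
    correlations: Sequence[CorrelationResult] = (),
) -> dict:
    """Serialize a full analysis report to JSON with a versioned schema.

    Key order is stable; NaN panel cells become nulls.  Returns the report
    dict (also written to ``path`` unless path is None).
    """
    report: dict = {"schema_version": SCHEMA_VERSION}
    report["filter"] = filter_report.to_dict() if filter_report else None
    report["stats"] = {k: s.to_dict() for k, s in (stats or {}).items()}
    report["correlations"] = [c.to_dict() for c in correlations]
    if panels is not None:
        cols = [c for c in panels.data.columns if c not in ("is_spike", "k_er_true")]
        records = panels.data[cols].replace({np.nan: None}).to_dict(orient="records")
        report["panels"] = records
    else:
        report["panels"] = None
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, allow_nan=False), encoding="utf-8")
    return report


def read_report(path) -> dict:
    """Round-trip reader for :func:`write_report` output."""
    report = json.loads(Path(path).read_text(encoding="utf-8"))
    if report.get("schema_version") != SCHEMA_VERSION:
        raise DomainError(f"unsupported report schema: {report.get('schema_version')!r}")
    return report
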