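"""Tabular container shared by the cohort pipeline, generator and I/O.

A :class:`CohortTable` is a thin wrapper around a pandas DataFrame with a
fixed column schema.  Raw columns mirror :class:`~erykal.core.MeasurementRecord`;
panel columns are added vectorized by :meth:`CohortTable.with_panels` using
the same formulas as the per-record path in :mod:`erykal.core`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    BAND_HI,
    BAND_LO,
    DEFAULT_CL,
    DEFAULT_DILUTION,
    NEUTRAL_PKER,
    DomainError,
    MeasurementRecord,
)

log = logging.getLogger("erykal")

RAW_COLUMNS = [
    "patient_id",
    "time",
    "k_hem",
    "k_pl",
    "ht",
    "cl",
    "hb",
    "mass_kg",
    "dilution",
]
PANEL_COLUMNS = [
    "k_all",
    "k_pl_d",
    "k_er_d",
    "k_er",
    "k_er_st",
    "k_er_exc",
    "p_k_er",
    "band",
    "zone",
]


def _band_labels(k_er: np.ndarray) -> np.ndarray:
    out = np.where(k_er < BAND_LO, "deficit", "normal")
    return np.where(k_er > BAND_HI, "elevated", out)


def _zone_labels(p_k_er: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    out = np.where(p_k_er > NEUTRAL_PKER, "cellular_alkalosis", "cellular_acidosis")
    return np.where(np.abs(p_k_er - NEUTRAL_PKER) <= tol, "neutral", out)


@dataclass
class CohortTable:
    """Ordered collection of measurement records with optional panel columns.

    ``data`` keeps one row per sample in input order; its index is the record
    identifier used in filter reports.  Optional raw cells are NaN when
    missing, never 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("k_hem", "k_pl", "ht") if c not in self.data.columns]
        if missing:
            raise DomainError(f"cohort table missing required columns: {missing}")
        for col in RAW_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        if self.data["dilution"].isna().all():
            self.data["dilution"] = DEFAULT_DILUTION
        else:
            self.data["dilution"] = self.data["dilution"].fillna(DEFAULT_DILUTION)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(cls, records: Iterable[MeasurementRecord]) -> "CohortTable":
        rows = [
            {
                "patient_id": r.patient_id,
                "time": r.time,
                "k_hem": r.k_hem,
                "k_pl": r.k_pl,
                "ht": r.ht,
                "cl": r.cl,
                "hb": r.hb,
                "mass_kg": r.mass_kg,
                "dilution": r.dilution,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=RAW_COLUMNS))

    def records(self) -> list[MeasurementRecord]:
        """Materialize rows as validated :class:`MeasurementRecord` objects."""
        out = []
        for _, row in self.data.iterrows():
            out.append(
                MeasurementRecord(
                    k_hem=float(row["k_hem"]),
                    k_pl=float(row["k_pl"]),
                    ht=float(row["ht"]),
                    cl=None if pd.isna(row["cl"]) else float(row["cl"]),
                    patient_id=None if pd.isna(row["patient_id"]) else str(row["patient_id"]),
                    time=None if pd.isna(row["time"]) else float(row["time"]),
                    hb=None if pd.isna(row["hb"]) else float(row["hb"]),
                    mass_kg=None if pd.isna(row["mass_kg"]) else float(row["mass_kg"]),
                    dilution=float(row["dilution"]),
                )
            )
        return out

    def with_panels(self, cl_default: float = DEFAULT_CL) -> "CohortTable":
        """Return a copy with panel columns computed for every row.

        Vectorized version of the K_er chain and derived panel.  Rows with
        hematocrit outside (0, 100) raise; rows with a negative erythrocyte
        share get NaN panels plus an ``implausible`` flag column (the tabular
        analog of the per-record error).  Missing chloride falls back to
        ``cl_default`` with an INFO log so assumed values are auditable.
        """
        df = self.data.copy()
        if len(df) == 0:
            for col in PANEL_COLUMNS:
                df[col] = pd.Series(dtype=float if not col in ("band", "zone") else object)
            df["implausible"] = pd.Series(dtype=bool)
            return CohortTable(df)
        ht = df["ht"].to_numpy(dtype=float)
        if np.any(~((ht > 0) & (ht < 100))):
            bad = df.index[~((ht > 0) & (ht < 100))].tolist()
            raise DomainError(f"hematocrit out of (0, 100) at rows {bad[:10]}")
        k_hem = df["k_hem"].to_numpy(dtype=float)
        k_pl = df["k_pl"].to_numpy(dtype=float)
        dilution = df["dilution"].to_numpy(dtype=float)
        k_all = k_hem * dilution
        k_pl_d = k_pl * (100.0 - ht) / 100.0
        k_er_d = k_all - k_pl_d
        k_er = k_er_d * 100.0 / ht
        implausible = k_er_d < 0

        cl = df["cl"].to_numpy(dtype=float)
        n_missing_cl = int(np.isnan(cl).sum())
        if n_missing_cl:
            log.info(
                "chloride missing for %d rows; using cl_default=%g for K_er.st",
                n_missing_cl,
                cl_default,
            )
        cl = np.where(np.isnan(cl), cl_default, cl)

        with np.errstate(divide="ignore", invalid="ignore"):
            k_er_st = cl
            k_er_exc = k_er - cl
            p_k_er = np.where(k_er > 0, NEUTRAL_PKER * cl / np.maximum(k_er, 1e-300), np.nan)

        df["k_all"] = k_all
        df["k_pl_d"] = k_pl_d
        df["k_er_d"] = k_er_d
        df["k_er"] = np.where(implausible, np.nan, k_er)
        df["k_er_st"] = np.where(implausible, np.nan, k_er_st)
        df["k_er_exc"] = np.where(implausible, np.nan, k_er_exc)
        df["p_k_er"] = np.where(implausible, np.nan, p_k_er)
        band = _band_labels(k_er).astype(object)
        zone = _zone_labels(p_k_er).astype(object)
        band[implausible | ~(k_er >= 0)] = None
        zone[implausible | ~(k_er > 0)] = None
        df["band"] = band
        df["zone"] = zone
        df["implausible"] = implausible
        if implausible.any():
            log.warning("%d rows flagged implausible (negative K_er.d)", implausible.sum())
        return CohortTable(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
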