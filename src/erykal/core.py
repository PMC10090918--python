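"""Erythrocyte-potassium calculus.

Potassium concentration inside erythrocytes (K_er, mmol/L) is obtained from a
hemolyzed whole-blood sample measured on an ordinary blood-gas analyzer with
ion-selective electrodes.  The sample is diluted (1:12 by protocol), lysed so
intracellular and plasma potassium mix, and the measured hemolysate potassium
``k_hem`` is decomposed back into its plasma and erythrocyte shares using the
hematocrit:

    K_all  = K_hem * dilution
    K_pl.d = K_pl * (100 - Ht) / 100        (plasma share of the hemolysate)
    K_er.d = K_all - K_pl.d                 (erythrocyte share)
    K_er   = K_er.d * 100 / Ht

On top of K_er a derived panel is built by analogy with the plasma acid-base
panel, referenced to plasma chloride (the dominant extracellular anion):

    K_er.st  = Cl                 "standard" erythrocyte potassium
    K_er.exc = K_er - K_er.st     signed excess (base-excess analog)
    pK_er    = 7 * Cl / K_er      pH analog; 7 is the neutral point

pK_er > 7 reads as intracellular (cellular) alkalosis — typically potassium
deficit — and pK_er < 7 as cellular acidosis, the eryptosis signature.
A total-body potassium deficit is estimated as

    deficit = mass_kg * 0.65 * (90 - K_er)   [mmol]

where 0.65 is the cellular mass fraction and 90 mmol/L the lower normal limit
(treatment target).  All concentrations are mmol/L; hematocrit is percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "ImplausibleSampleError",
    "MeasurementRecord",
    "ErPanel",
    "DeficitSpec",
    "BufferCurve",
    "DEFAULT_DILUTION",
    "DEFAULT_CL",
    "DEFICIT_TARGET",
    "CELL_MASS_FRACTION",
    "BAND_LO",
    "BAND_HI",
    "NEUTRAL_PKER",
    "compute_k_er",
    "compute_deficit",
    "derived_panel",
    "classify_band",
    "classify_zone",
    "buffer_curve",
    "nomogram_export",
    "full_panel",
]

DEFAULT_DILUTION = 12.0
DEFAULT_CL = 100.0  # fallback "about normal" plasma chloride, mmol/L
DEFICIT_TARGET = 90.0  # lower limit of normal K_er, mmol/L
CELL_MASS_FRACTION = 0.65
BAND_LO = 90.0
BAND_HI = 110.0
NEUTRAL_PKER = 7.0
PKER_SCALE = 7.0


class DomainError(ValueError):
    """Input outside the mathematical/physiological domain of a formula."""


class ImplausibleSampleError(ValueError):
    """Sample whose numbers are mutually inconsistent (e.g. negative K_er.d).

    Indicates a measurement or unit problem rather than a biological state;
    the value is never silently clamped.
    """


@dataclass(frozen=True)
class MeasurementRecord:
    """One blood sample's raw inputs.

    Required: hemolysate potassium ``k_hem``, plasma potassium ``k_pl``,
    hematocrit ``ht`` (percent, strictly inside (0, 100)), plasma chloride
    ``cl``.  Optional fields stay ``None`` when missing — never 0.
    """

    k_hem: float
    k_pl: float
    ht: float
    cl: Optional[float] = None
    patient_id: Optional[str] = None
    time: Optional[float] = None
    hb: Optional[float] = None
    mass_kg: Optional[float] = None
    dilution: float = DEFAULT_DILUTION

    def __post_init__(self) -> None:
        if not (0.0 < self.ht < 100.0):
            raise DomainError(
                f"hematocrit must be a percent strictly in (0, 100), got {self.ht!r}; "
                "fractional hematocrit (0-1) is rejected, not auto-scaled"
            )
        for name in ("k_hem", "k_pl"):
            v = getattr(self, name)
            if v < 0:
                raise DomainError(f"{name} must be >= 0, got {v!r}")
        if self.cl is not None and self.cl < 0:
            raise DomainError(f"cl must be >= 0, got {self.cl!r}")
        if self.dilution <= 0:
            raise DomainError(f"dilution must be > 0, got {self.dilution!r}")
        if self.mass_kg is not None and self.mass_kg <= 0:
            raise DomainError(f"mass_kg must be > 0, got {self.mass_kg!r}")


@dataclass
class ErPanel:
    """Computed K_er with intermediates, derived panel and labels.

    ``k_er_st + k_er_exc == k_er`` holds exactly by construction.  Derived
    fields are ``None`` until :func:`derived_panel` / :func:`full_panel`
    fills them.
    """

    k_all: float
    k_pl_d: float
    k_er_d: float
    k_er: float
    k_er_st: Optional[float] = None
    k_er_exc: Optional[float] = None
    p_k_er: Optional[float] = None
    band: Optional[str] = None
    zone: Optional[str] = None
    patient_id: Optional[str] = None
    time: Optional[float] = None


@dataclass(frozen=True)
class DeficitSpec:
    """Parameters of the total-body deficit formula.

    ``mass_kg`` is body mass in kilograms.  ``cell_fraction`` (default 0.65)
    is the cellular fraction of body mass; ``target`` (default 90 mmol/L) the
    treatment target / lower normal limit.
    """

    mass_kg: float
    target: float = DEFICIT_TARGET
    cell_fraction: float = CELL_MASS_FRACTION

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise DomainError(f"mass_kg must be > 0, got {self.mass_kg!r}")
        if not (0.0 < self.cell_fraction <= 1.0):
            raise DomainError(
                f"cell_fraction must be in (0, 1], got {self.cell_fraction!r}"
            )


@dataclass(frozen=True)
class BufferCurve:
    """Locus of constant plasma chloride in the (pK_er, K_er.exc) plane.

    Every point satisfies ``k_er_exc == PKER_SCALE * cl / p_k_er - cl``; the
    curve passes through the neutral point (7, 0) when K_er equals Cl.
    """

    cl: float
    k_er: np.ndarray  # parameter values, monotonically increasing
    p_k_er: np.ndarray
    k_er_exc: np.ndarray

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (p_k_er, k_er_exc) pairs."""
        return np.column_stack([self.p_k_er, self.k_er_exc])


def compute_k_er(rec: MeasurementRecord) -> ErPanel:
    """Decompose a hemolysate measurement into the erythrocyte concentration.

    Returns an :class:`ErPanel` with ``k_all``, ``k_pl_d``, ``k_er_d`` and
    ``k_er`` filled (derived fields left for :func:`derived_panel`).

    Raises
    ------
    ImplausibleSampleError
        If the erythrocyte share ``k_er_d`` comes out negative, i.e. the
        hemolysate contains less potassium than plasma alone would supply —
        a measurement or unit error, not a physiological state.
    """
    k_all = rec.k_hem * rec.dilution
    k_pl_d = rec.k_pl * (100.0 - rec.ht) / 100.0
    k_er_d = k_all - k_pl_d
    if k_er_d < 0:
        raise ImplausibleSampleError(
            f"erythrocyte potassium share is negative (k_all={k_all:.3f}, "
            f"plasma share={k_pl_d:.3f}); hemolysate potassium below plasma share"
        )
    k_er = k_er_d * 100.0 / rec.ht
    return ErPanel(
        k_all=k_all,
        k_pl_d=k_pl_d,
        k_er_d=k_er_d,
        k_er=k_er,
        patient_id=rec.patient_id,
        time=rec.time,
    )


def compute_deficit(k_er: float, spec: DeficitSpec) -> float:
    """Total-body potassium deficit, mmol (signed; negative means surplus).

    ``mass_kg * cell_fraction * (target - k_er)``; linear in mass and in the
    distance to target, zero at ``k_er == target`` for any mass, no clamping.
    """
    if k_er < 0:
        raise DomainError(f"k_er must be >= 0, got {k_er!r}")
    return spec.mass_kg * spec.cell_fraction * (spec.target - k_er)


def derived_panel(k_er: float, cl: float) -> tuple[float, float, float]:
    """Derived intracellular acid-base panel ``(k_er_st, k_er_exc, p_k_er)``.

    ``k_er_st = cl`` (standard value), ``k_er_exc = k_er - cl`` (signed
    excess), ``p_k_er = 7 * cl / k_er`` (pH analog, neutral at 7).
    Accepts scalars or numpy arrays.
    """
    k_er = np.asarray(k_er, dtype=float) if np.ndim(k_er) else float(k_er)
    if np.any(np.asarray(k_er) <= 0):
        raise DomainError("k_er must be > 0 (pK_er undefined at 0)")
    if np.any(np.asarray(cl) <= 0):
        raise DomainError("cl must be > 0")
    k_er_st = cl
    k_er_exc = k_er - cl
    p_k_er = PKER_SCALE * cl / k_er
    return k_er_st, k_er_exc, p_k_er


def classify_band(k_er: float) -> str:
    """Band label for K_er: ``deficit`` (<90), ``normal`` (90-110, inclusive),
    ``elevated`` (>110)."""
    if k_er < 0:
        raise DomainError(f"k_er must be >= 0, got {k_er!r}")
    if k_er < BAND_LO:
        return "deficit"
    if k_er <= BAND_HI:
        return "normal"
    return "elevated"


def classify_zone(p_k_er: float, tol: float = 1e-9) -> str:
    """Nomogram zone from pK_er.

    Values above 7 denote cellular alkalosis, below 7 cellular acidosis;
    within ``tol`` of 7 the boundary gets its own ``neutral`` label rather
    than being forced onto a side.
    """
    if p_k_er <= 0:
        raise DomainError(f"p_k_er must be > 0, got {p_k_er!r}")
    if abs(p_k_er - NEUTRAL_PKER) <= tol:
        return "neutral"
    return "cellular_alkalosis" if p_k_er > NEUTRAL_PKER else "cellular_acidosis"


def buffer_curve(
    cl: float,
    k_er_min: float = 60.0,
    k_er_max: float = 210.0,
    n_points: int = 151,
) -> BufferCurve:
    """Constant-chloride curve for the nomogram.

    Evaluates the derived panel along ``n_points`` K_er values spanning
    ``[k_er_min, k_er_max]``; the resulting (pK_er, K_er.exc) pairs satisfy
    ``k_er_exc = 7*cl/p_k_er - cl`` identically.
    """
    if cl <= 0:
        raise DomainError(f"cl must be > 0, got {cl!r}")
    if not (0 < k_er_min < k_er_max):
        raise DomainError(
            f"need 0 < k_er_min < k_er_max, got [{k_er_min!r}, {k_er_max!r}]"
        )
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points!r}")
    k_er = np.linspace(k_er_min, k_er_max, n_points)
    _, k_er_exc, p_k_er = derived_panel(k_er, cl)
    return BufferCurve(cl=cl, k_er=k_er, p_k_er=p_k_er, k_er_exc=k_er_exc)


def full_panel(
    rec: MeasurementRecord,
    cl_default: float = DEFAULT_CL,
    zone_tol: float = 1e-9,
) -> ErPanel:
    """Complete panel for one record: K_er chain, derived panel, labels.

    Uses the record's measured chloride for K_er.st when present; otherwise
    falls back to ``cl_default`` (the "about 100 mmol/L" normal).
    """
    panel = compute_k_er(rec)
    cl = rec.cl if rec.cl is not None and rec.cl > 0 else cl_default
    if panel.k_er > 0:
        st, exc, pk = derived_panel(panel.k_er, cl)
        panel.k_er_st, panel.k_er_exc, panel.p_k_er = st, exc, pk
        panel.zone = classify_zone(pk, tol=zone_tol)
    panel.band = classify_band(panel.k_er)
    return panel


def nomogram_export(
    curves: Sequence[BufferCurve] = (),
    samples: Iterable[ErPanel] = (),
) -> pd.DataFrame:
    """Flat coordinate table of nomogram geometry for plotting/export.

    Columns: ``role`` (curve/sample), ``x`` (pK_er), ``y`` (K_er.exc),
    ``label`` (Cl=... for curves, band for samples), ``zone``.  Curves come
    first in input order, then samples; within a curve, rows follow K_er.
    """
    rows: list[dict] = []
    for curve in curves:
        for pk, exc in zip(curve.p_k_er, curve.k_er_exc):
            rows.append(
                {
                    "role": "curve",
                    "x": pk,
                    "y": exc,
                    "label": f"Cl={curve.cl:g}",
                    "zone": classify_zone(pk),
                }
            )
    for panel in samples:
        if panel.p_k_er is None or panel.k_er_exc is None:
            raise DomainError(
                "sample panels must carry derived values; run full_panel first"
            )
        rows.append(
            {
                "role": "sample",
                "x": panel.p_k_er,
                "y": panel.k_er_exc,
                "label": panel.band if panel.band is not None else "",
                "zone": panel.zone if panel.zone is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=["role", "x", "y", "label", "zone"])
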