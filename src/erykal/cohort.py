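"""Cohort statistics pipeline.

Mirrors how the ICU cohort is processed: extreme K_er values outside a
retention band (default [60, 210] mmol/L, inclusive) are flagged as spikes
and excluded; the kept series is described as M±sd and Me [Q1; Q3]; pairs of
variables are screened with Spearman rank correlation (plasma potassium is
expected to be uncorrelated with K_er, while K_er.exc and pK_er sit on the
chloride buffer curve and correlate near −1); per-patient trajectories track
K_er across ICU days.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError
from .table import CohortTable

__all__ = [
    "SPIKE_LO",
    "SPIKE_HI",
    "FilterReport",
    "SummaryStats",
    "CorrelationResult",
    "filter_spikes",
    "summarize",
    "analyze_cohort",
    "spearman",
    "correlation_screen",
    "histogram_bins",
    "trajectory",
]

SPIKE_LO = 60.0
SPIKE_HI = 210.0


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of the spike filter: input = spikes + kept, disjoint."""

    n_input: int
    n_spikes: int
    n_kept: int
    lo: float = SPIKE_LO
    hi: float = SPIKE_HI
    spike_indices: tuple = ()

    def __post_init__(self) -> None:
        assert self.n_input == self.n_spikes + self.n_kept

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_spikes": self.n_spikes,
            "n_kept": self.n_kept,
            "lo": self.lo,
            "hi": self.hi,
            "spike_indices": list(self.spike_indices),
        }


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of a filtered variable (sample sd, type-7 quartiles)."""

    n: int
    min: float
    max: float
    mean: float
    sd: Optional[float]
    median: float
    q1: float
    q3: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho between two named variables on pairwise-complete rows.

    ``rho`` is None (flagged ``degenerate``) when either series is constant;
    ``p_value`` is None below n = 3.
    """

    var_x: str
    var_y: str
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "var_x": self.var_x,
            "var_y": self.var_y,
            "rho": self.rho,
            "p_value": self.p_value,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def filter_spikes(
    values,
    lo: float = SPIKE_LO,
    hi: float = SPIKE_HI,
) -> tuple[pd.Series, FilterReport]:
    """Flag values outside the retention band [lo, hi] as spikes.

    Bounds are inclusive on the kept side: exactly ``lo`` or ``hi`` is kept.
    Returns the kept series (input order and index preserved) and a
    :class:`FilterReport`; NaN values count as spikes (unmeasurable).
    """
    if not lo < hi:
        raise DomainError(f"need lo < hi, got {lo!r} >= {hi!r}")
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    keep = (s >= lo) & (s <= hi)  # NaN compares False on both sides
    kept = s[keep]
    spikes = s.index[~keep]
    return kept, FilterReport(
        n_input=len(s),
        n_spikes=int((~keep).sum()),
        n_kept=int(keep.sum()),
        lo=lo,
        hi=hi,
        spike_indices=tuple(spikes.tolist()),
    )


def summarize(values) -> SummaryStats:
    """Describe a kept series: min/max, mean ± sample sd, Me [Q1; Q3].

    sd uses the n−1 denominator and is None for a single value; quartiles
    use linear interpolation between order statistics (numpy default).
    """
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise DomainError("cannot summarize an empty series")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return SummaryStats(
        n=int(a.size),
        min=float(a.min()),
        max=float(a.max()),
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)) if a.size >= 2 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho, n <= 10.

    Enumerates all n! orderings of one rank vector; feasible only for small n
    (10! ≈ 3.6M), hence the guard in :func:`spearman`.
    """
    n = len(rx)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(sx @ sy[list(perm)]) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(
    x,
    y,
    var_x: str = "x",
    var_y: str = "y",
    method: str = "t",
) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete missing handling.

    rho is Pearson correlation on average ranks (ties share ranks); the
    p-value uses the t-approximation with n−2 degrees of freedom
    (``method="t"``, the default) or exact permutation enumeration
    (``method="exact"``, available for n ≤ 10).  A constant series makes rho
    undefined: the result is flagged degenerate with no p-value.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.shape != ys.shape:
        raise DomainError(f"length mismatch: {xs.shape} vs {ys.shape}")
    ok = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[ok], ys[ok]
    n = int(xs.size)
    if n < 3:
        raise DomainError(f"Spearman needs n >= 3 pairwise-complete pairs, got {n}")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return CorrelationResult(var_x, var_y, None, None, n, degenerate=True)
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    if np.unique(xs).size == n and np.unique(ys).size == n:
        # tie-free: the d^2 formula is exact integer arithmetic, so perfectly
        # monotone pairs give rho = +/-1 exactly (Pearson-on-ranks would not)
        d2 = float(np.sum((rx - ry) ** 2))
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
        if abs(rho) >= 1.0:
            p_t = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p_t = 2.0 * float(stats.t.sf(abs(t), n - 2))
    else:
        res = stats.spearmanr(xs, ys)
        rho = float(res.statistic)
        p_t = float(res.pvalue)
    if method == "exact":
        if n > 10:
            raise DomainError(f"exact permutation p available only for n <= 10, got {n}")
        p = _exact_permutation_p(rx, ry, rho)
    elif method == "t":
        p = p_t
    else:
        raise DomainError(f"unknown p-value method {method!r}")
    return CorrelationResult(var_x, var_y, rho, p, n)


def correlation_screen(
    table: CohortTable,
    pairs: Sequence[tuple[str, str]] = (
        ("k_er", "k_pl"),
        ("k_er_exc", "p_k_er"),
        ("k_er", "ht"),
        ("k_er", "hb"),
    ),
) -> list[CorrelationResult]:
    """Run Spearman over named column pairs of a panelled cohort table.

    The default pairs are the headline screen: K_er against plasma potassium
    (expected uncorrelated), K_er.exc against pK_er (buffer-curve pair,
    expected near −1), and K_er against hematocrit/hemoglobin (eryptosis
    signature, expected negative).  Pairs whose columns are entirely missing
    are reported with n = 0 rather than raising.
    """
    df = table.data
    results = []
    for vx, vy in pairs:
        for v in (vx, vy):
            if v not in df.columns:
                raise DomainError(
                    f"unknown variable {v!r}; available: {sorted(df.columns)}"
                )
        xs = df[vx].to_numpy(dtype=float)
        ys = df[vy].to_numpy(dtype=float)
        n_ok = int((~(np.isnan(xs) | np.isnan(ys))).sum())
        if n_ok < 3:
            results.append(CorrelationResult(vx, vy, None, None, n_ok, degenerate=True))
        else:
            results.append(spearman(xs, ys, var_x=vx, var_y=vy))
    return results


def histogram_bins(values, bin_width: float, start: Optional[float] = None) -> pd.DataFrame:
    """Left-closed right-open histogram covering [min, max].

    Bins are anchored at ``start`` (default: min rounded down to a multiple
    of ``bin_width``); counts always sum to the number of non-NaN values.
    Returns a DataFrame with columns left, right, count.
    """
    if bin_width <= 0:
        raise DomainError(f"bin_width must be > 0, got {bin_width!r}")
    a = np.asarray(values, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        return pd.DataFrame(columns=["left", "right", "count"])
    if start is None:
        start = math.floor(a.min() / bin_width) * bin_width
    idx = np.floor((a - start) / bin_width).astype(int)
    if idx.min() < 0:
        raise DomainError(f"start={start!r} lies above the data minimum")
    counts = np.bincount(idx)
    left = start + bin_width * np.arange(len(counts))
    return pd.DataFrame({"left": left, "right": left + bin_width, "count": counts})


def analyze_cohort(
    table: CohortTable,
    lo: float = SPIKE_LO,
    hi: float = SPIKE_HI,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    cl_default: float = 100.0,
) -> dict:
    """Full pipeline on a raw cohort table: panels → spike filter → stats.

    Computes panels if absent, filters K_er spikes, summarizes kept K_er and
    the derived panel, and runs the correlation screen on kept rows only.
    Returns a dict with keys ``table`` (panelled CohortTable with ``is_kept``
    flags), ``filter`` (:class:`FilterReport`), ``stats`` (dict of
    :class:`SummaryStats`) and ``correlations``.  An empty table yields zero
    counts rather than an error.
    """
    if "k_er" not in table.data.columns:
        table = table.with_panels(cl_default=cl_default)
    df = table.data
    if len(df) == 0:
        return {
            "table": table,
            "filter": FilterReport(0, 0, 0, lo, hi, ()),
            "stats": {},
            "correlations": [],
        }
    kept, report = filter_spikes(df["k_er"], lo=lo, hi=hi)
    df = df.copy()
    df["is_kept"] = df.index.isin(kept.index)
    kept_table = CohortTable(df[df["is_kept"]].copy())
    stats_out = {}
    for var in ("k_er", "k_er_exc", "p_k_er", "k_pl", "cl"):
        vals = kept_table.data[var].dropna()
        if len(vals):
            stats_out[var] = summarize(vals)
    screen_pairs = pairs
    if screen_pairs is None:
        screen_pairs = [("k_er", "k_pl"), ("k_er_exc", "p_k_er"), ("k_er", "ht"), ("k_er", "hb")]
    correlations = correlation_screen(kept_table, screen_pairs) if report.n_kept >= 3 else []
    return {
        "table": CohortTable(df),
        "filter": report,
        "stats": stats_out,
        "correlations": correlations,
    }


def trajectory(table: CohortTable, patient_id: str) -> pd.DataFrame:
    """Time-ordered K_er series for one patient with per-step deltas.

    Requires panel columns (``with_panels``) and per-row times.  Returns a
    DataFrame sorted by time with columns time, k_er, band, zone, delta_k_er
    (NaN for the first point).
    """
    df = table.data
    if "k_er" not in df.columns:
        raise DomainError("table has no panel columns; call with_panels() first")
    sub = df[df["patient_id"] == patient_id]
    if len(sub) == 0:
        known = sorted({str(p) for p in df["patient_id"].dropna().unique()})
        raise DomainError(f"unknown patient {patient_id!r}; known: {known[:20]}")
    if sub["time"].isna().any():
        raise DomainError(f"patient {patient_id!r} has records without time")
    out = sub.sort_values("time")[["time", "k_er", "band", "zone"]].reset_index(drop=True)
    out["delta_k_er"] = out["k_er"].diff()
    return out
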