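"""Cohort statistics: per-lesion volume table, summaries, exact Wilcoxon test.

The target-volume comparison is paired per lesion (PTV vs PTVg, BITV vs BTV)
and the cohorts are small (here 14 lesions, 8 threshold pairs), so the
Wilcoxon signed-rank test is evaluated *exactly*: zero differences are
dropped (Wilcoxon's original treatment), absolute differences are ranked
with mid-ranks for ties, and the two-tailed p-value is obtained by complete
enumeration of the 2^n equally likely sign assignments via dynamic
programming over achievable rank sums. Mid-ranks are multiples of 1/2, so
doubling them makes every achievable rank sum an integer and the
distribution a simple convolution.

Lesions are treated as independent pairs even when one patient contributes
several — mirroring common clinical practice for pilot cohorts; no
within-patient correlation model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VolumeRecord",
    "PairedTestResult",
    "wilcoxon_exact",
    "summarize",
    "median_range",
    "count_exceptions",
    "load_threshold_table",
    "load_volume_table",
    "records_from_frame",
]

EXACT_MAX_N = 25  # full enumeration up to 2^25 sign assignments


@dataclass(frozen=True)
class VolumeRecord:
    """One per-lesion row of the cohort volume table (all volumes in cc)."""

    patient: int
    lesion: int
    ptv_cc: float
    ptvg_cc: float
    bitv_cc: float
    btv_cc: float
    ctv_cc: float | None = None
    liver_cc: float | None = None

    def __post_init__(self) -> None:
        for name in ("ptv_cc", "ptvg_cc", "bitv_cc", "btv_cc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PairedTestResult:
    """Exact (or large-sample) Wilcoxon signed-rank result."""

    n_pairs: int
    n_nonzero: int
    statistic: float  # smaller of the positive/negative rank sums
    p_value: float
    method: str  # "exact" | "approximate"
    degenerate: bool = False  # all differences zero


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments achieving each doubled positive-rank sum.

    ``double_ranks`` are the (tied, doubled-to-integer) mid-ranks. The
    returned array c has c[s] = #assignments with doubled R+ == s; it sums
    to 2^n and is symmetric about sum(double_ranks)/2.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for dr in double_ranks:
        dr = int(dr)
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[:-dr] if dr else counts
        counts = counts + shifted
    return counts


def wilcoxon_exact(x, y) -> PairedTestResult:
    """Two-tailed paired Wilcoxon signed-rank test, exact for n <= 25.

    Differences d = x - y; zeros dropped; |d| mid-ranked; the statistic is
    W = min(sum of positive ranks, sum of negative ranks) and the exact
    two-tailed p is 2 * P(R+ <= W) under full sign enumeration, capped at 1.
    All-zero differences yield a degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D with n >= 1")
    d = x - y
    n_pairs = len(d)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(n_pairs, 0, 0.0, 1.0, "exact", degenerate=True)

    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    w = min(r_plus, r_minus)

    if n <= EXACT_MAX_N:
        double_ranks = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(double_ranks)
        w2 = int(round(2 * w))
        tail = counts[: w2 + 1].sum()
        p = min(1.0, 2.0 * tail / 2.0**n)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "approximate"
    return PairedTestResult(n_pairs, n, w, float(p), method)


def records_from_frame(df: pd.DataFrame) -> list[VolumeRecord]:
    """Build :class:`VolumeRecord` rows from a volume-table DataFrame."""
    recs = []
    for _, row in df.iterrows():
        recs.append(
            VolumeRecord(
                patient=int(row["patient"]),
                lesion=int(row["lesion"]),
                ptv_cc=float(row["ptv_cc"]),
                ptvg_cc=float(row["ptvg_cc"]),
                bitv_cc=float(row["bitv_cc"]),
                btv_cc=float(row["btv_cc"]),
                ctv_cc=float(row["ctv_cc"]) if pd.notna(row.get("ctv_cc")) else None,
                liver_cc=float(row["liver_cc"]) if pd.notna(row.get("liver_cc")) else None,
            )
        )
    return recs


_VOLUME_COLUMNS = ("ptv_cc", "ptvg_cc", "bitv_cc", "btv_cc")


def summarize(records: list[VolumeRecord]) -> dict:
    """Column summaries and the ratio-of-means comparison rows.

    Per volume column: mean, sample SD (n-1, NaN for a single record), min,
    max. The headline comparisons are ratio-of-means x100 for PTV/PTVg and
    BITV/BTV (ratio of the column means, not the mean of per-row ratios),
    plus the per-row percentage ratios.
    """
    if not records:
        raise ValueError("summarize requires at least one record")
    df = pd.DataFrame([{c: getattr(r, c) for c in _VOLUME_COLUMNS} for r in records])
    cols = {}
    for c in _VOLUME_COLUMNS:
        v = df[c]
        cols[c] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    out = {
        "columns": cols,
        "ratio_of_means_pct": {
            "ptv_over_ptvg": 100.0 * df["ptv_cc"].sum() / df["ptvg_cc"].sum(),
            "bitv_over_btv": 100.0 * df["bitv_cc"].sum() / df["btv_cc"].sum(),
        },
        "per_row_ratio_pct": {
            "ptv_over_ptvg": (100.0 * df["ptv_cc"] / df["ptvg_cc"]).tolist(),
            "bitv_over_btv": (100.0 * df["bitv_cc"] / df["btv_cc"]).tolist(),
        },
        "n": len(records),
    }
    return out


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max); median of an even count is the central-pair mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("median_range requires a non-empty 1-D sequence")
    return float(np.median(v)), float(v.min()), float(v.max())


def count_exceptions(records: list[VolumeRecord]) -> int:
    """Number of lesions whose gated plan did *not* shrink: PTVg >= PTV."""
    if not records:
        raise ValueError("count_exceptions requires at least one record")
    return sum(1 for r in records if r.ptvg_cc >= r.ptv_cc)


# ---------------------------------------------------------------------------
# Packaged cohort fixtures (study threshold and volume tables)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("gatedpet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_threshold_table() -> pd.DataFrame:
    """Per-patient SUV thresholds: columns patient, gated_suv, nongated_suv."""
    return _read_packaged_csv("table1_thresholds.csv")


def load_volume_table() -> pd.DataFrame:
    """Per-lesion target volumes (cc): patient, lesion, ptv_cc, ptvg_cc,
    bitv_cc, btv_cc, ctv_cc, liver_cc."""
    return _read_packaged_csv("table2_volumes.csv")
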