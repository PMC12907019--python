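"""Descriptive statistics over annotation sets.

Covers the standard inventory questions asked of a repeat annotation: how
many records, how much genome they cover, how lengths distribute (with the
long tail counted separately), and — where a destruction-degree attribute is
present — how degraded records are, overall and as a function of length.

Quantiles use linear interpolation between order statistics (numpy's
default); coverage defaults to summed record lengths, with merged-union
(genomic bp covered at least once) one flag away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet

COVERAGE_MODES = ("sum_lengths", "merged_union")


def total_coverage(aset: AnnotationSet, mode: str = "sum_lengths") -> int:
    """Total bp covered: sum of record lengths, or the merged union of
    intervals per chromosome (never larger than the sum)."""
    if mode not in COVERAGE_MODES:
        raise ValueError(f"mode must be one of {COVERAGE_MODES}")
    if len(aset) == 0:
        return 0
    if mode == "sum_lengths":
        return int(aset.lengths.sum())
    total = 0
    for _, grp in aset.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # records are sorted by start; sweep with a running maximum end
        run_end = np.maximum.accumulate(ends)
        new_start = np.maximum(starts, np.concatenate(([starts[0]], run_end[:-1])))
        total += int(np.maximum(ends - new_start, 0).sum())
    return total


@dataclass
class LengthHistogram:
    """Uniform-width length histogram with an explicit overflow bucket."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow_threshold: int
    n_overflow: int

    @property
    def n_total(self) -> int:
        return int(self.counts.sum()) + self.n_overflow

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start": self.bin_edges[:-1].astype(int), "count": self.counts}
        )


def length_histogram(
    aset: AnnotationSet, bin_width: int = 100, overflow_threshold: int = 2500
) -> LengthHistogram:
    """Histogram of record lengths in [0, overflow_threshold), half-open bins
    of ``bin_width`` bp; records strictly longer than the threshold go to the
    overflow count (a record of exactly the threshold length stays binned)."""
    if bin_width < 1:
        raise ValueError("bin_width must be ≥ 1")
    lengths = aset.lengths
    n_over = int((lengths > overflow_threshold).sum())
    edges = np.arange(0, overflow_threshold + bin_width, bin_width)
    if edges[-1] < overflow_threshold + 1:
        edges = np.append(edges, edges[-1] + bin_width)
    kept = lengths[lengths <= overflow_threshold]
    counts, _ = np.histogram(kept, bins=edges)
    return LengthHistogram(
        bin_edges=edges,
        counts=counts,
        overflow_threshold=overflow_threshold,
        n_overflow=n_over,
    )


def long_record_count(aset: AnnotationSet, threshold: int = 2500) -> int:
    """Number of records strictly longer than ``threshold`` bp."""
    if threshold < 0:
        raise ValueError("threshold must be ≥ 0")
    return int((aset.lengths > threshold).sum())


@dataclass
class DestructionSummary:
    """Per-stratum destruction-degree statistics.

    ``stats`` has one row per stratum with n, mean, median, q1, q3;
    ``histograms`` maps stratum key → (bin_start, count) frame at
    ``bin_width`` percentage points.  Records without a destruction value are
    excluded; n reflects that.
    """

    stats: pd.DataFrame
    histograms: dict[tuple, pd.DataFrame]
    bin_width: float


def destruction_summary(
    aset: AnnotationSet,
    strata: Sequence[str] = ("superfamily",),
    min_length: Optional[int] = None,
    bin_width: float = 2.0,
) -> DestructionSummary:
    df = aset.df.assign(source=aset.source_name)
    if min_length is not None:
        df = df.loc[(df["end"] - df["start"]) > min_length]
    df = df.loc[df["destruction"].notna()]
    rows = []
    hists: dict[tuple, pd.DataFrame] = {}
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if df.empty:
        stats = pd.DataFrame(
            columns=[*strata, "n", "mean", "median", "q1", "q3"]
        )
        return DestructionSummary(stats=stats, histograms=hists, bin_width=bin_width)
    for key, grp in df.groupby(list(strata), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        d = grp["destruction"].to_numpy()
        rows.append(
            dict(
                zip(strata, key),
                n=len(d),
                mean=float(np.mean(d)),
                median=float(np.median(d)),
                q1=float(np.quantile(d, 0.25)),
                q3=float(np.quantile(d, 0.75)),
            )
        )
        counts, _ = np.histogram(np.clip(d, 0, 100 - 1e-9), bins=edges)
        hists[key] = pd.DataFrame({"bin_start": edges[:-1], "count": counts})
    return DestructionSummary(
        stats=pd.DataFrame(rows), histograms=hists, bin_width=bin_width
    )


def destruction_by_length(
    aset: AnnotationSet, bin_width: int = 100, max_length: Optional[int] = None
) -> pd.DataFrame:
    """Destruction quartiles per length bin: one row per bin with
    (bin_start, bin_end, n, median, q1, q3); empty bins keep n=0 and NaN
    statistics.  Only records carrying a destruction value contribute."""
    df = aset.df.loc[aset.df["destruction"].notna()].copy()
    df["length"] = df["end"] - df["start"]
    if max_length is None:
        max_length = int(df["length"].max()) if len(df) else bin_width
    edges = np.arange(0, max_length + bin_width, bin_width)
    rows = []
    idx = np.digitize(df["length"].to_numpy(), edges) - 1 if len(df) else np.array([])
    for i in range(len(edges) - 1):
        d = df["destruction"].to_numpy()[idx == i] if len(df) else np.array([])
        rows.append(
            {
                "bin_start": int(edges[i]),
                "bin_end": int(edges[i + 1]),
                "n": int(len(d)),
                "median": float(np.median(d)) if len(d) else np.nan,
                "q1": float(np.quantile(d, 0.25)) if len(d) else np.nan,
                "q3": float(np.quantile(d, 0.75)) if len(d) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def superfamily_table(
    sets: Iterable[AnnotationSet], coverage_mode: str = "sum_lengths"
) -> pd.DataFrame:
    """Per (source × superfamily) inventory: record count, coverage in bp and
    Mb (one decimal), and mean destruction where the attribute exists."""
    rows = []
    for aset in sets:
        for sf, grp in aset.df.groupby("superfamily", sort=True):
            sub = aset.with_df(grp)
            cov = total_coverage(sub, coverage_mode)
            destr = grp["destruction"].dropna()
            rows.append(
                {
                    "source": aset.source_name,
                    "superfamily": sf,
                    "n_records": len(grp),
                    "coverage_bp": cov,
                    "coverage_mb": round(cov / 1_000_000, 1),
                    "mean_destruction": float(destr.mean()) if len(destr) else np.nan,
                }
            )
    return pd.DataFrame(rows)
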