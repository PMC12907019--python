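"""Interval matching between annotation sources with the Sov overlap score.

Two records s1, s2 that overlap by ≥1 bp are scored with

    Sov = (minov + δ) / maxov

where minov is the intersection length, maxov the union span (total extent),
and δ an allowance term.  Two δ variants are provided:

* ``as_printed``:  δ = min(maxov − minov, minov, len(s1), len(s2))
* ``half_capped``: δ = min(maxov − minov, minov, len(s1)/2, len(s2)/2)

Under ``half_capped`` (the default), Sov = 1 exactly when the overlap reaches
half the length of the longer segment is *not* guaranteed — instead the
containment closed form is len(a) ≥ ⅔·len(b) for a ⊆ b; under ``as_printed``
it is len(a) ≥ ½·len(b).  Both are exposed because annotation pipelines in
the literature use either convention; every report records which one was used.

A fragmentation-tolerant secondary criterion rescues defragmented loci: a pair
with Sov < 1 still matches when the overlap covers ≥95% of the shorter record
(≤5% coordinate shift).  The final match rule is the disjunction

    (Sov = 1)  ∨  (Sov < 1  ∧  minov ≥ min(0.95·len(s1), 0.95·len(s2))).

Matching is purely coordinate-based: strand and family identity are ignored
(cross-superfamily matches are reported as a diagnostic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pyranges as pr

from .annotation_io import AnnotationSet, RepeatRecord

logger = logging.getLogger(__name__)

DELTA_VARIANTS = ("as_printed", "half_capped")


@dataclass(frozen=True)
class SovConfig:
    """Constants of the matching procedure.

    ``shift_fraction`` = 0.95 encodes the "no more than 5% coordinate shift"
    allowance; ``sov_match_threshold`` is 1.0 in the reference analysis.
    """

    delta_variant: str = "half_capped"
    sov_match_threshold: float = 1.0
    shift_fraction: float = 0.95
    use_secondary_criterion: bool = True

    def __post_init__(self) -> None:
        if self.delta_variant not in DELTA_VARIANTS:
            raise ValueError(f"delta_variant must be one of {DELTA_VARIANTS}")
        if not 0.0 < self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must lie in (0, 1]")
        if not 0.0 < self.sov_match_threshold <= 1.0:
            raise ValueError("sov_match_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class OverlapPair:
    """One scored overlapping record pair."""

    record_a: RepeatRecord
    record_b: RepeatRecord
    minov: int
    maxov: int
    delta: float
    sov: float
    matched_primary: bool
    matched_secondary: bool
    matched: bool


def sov_score(
    a: tuple[int, int],
    b: tuple[int, int],
    cfg: SovConfig = SovConfig(),
) -> tuple[int, int, float, float]:
    """Score one overlapping interval pair; returns (minov, maxov, delta, sov).

    Intervals are 0-based half-open (start, end) on the same chromosome.
    Raises ``ValueError`` for non-overlapping inputs: pair discovery belongs
    to :func:`find_overlaps`.
    """
    (a0, a1), (b0, b1) = a, b
    minov = min(a1, b1) - max(a0, b0)
    if minov <= 0:
        raise ValueError(f"intervals {a} and {b} do not overlap")
    maxov = max(a1, b1) - min(a0, b0)
    len_a, len_b = a1 - a0, b1 - b0
    if cfg.delta_variant == "half_capped":
        delta = min(maxov - minov, minov, len_a / 2.0, len_b / 2.0)
    else:
        delta = float(min(maxov - minov, minov, len_a, len_b))
    return minov, maxov, delta, (minov + delta) / maxov


def is_match(pair: "OverlapPair | pd.Series", cfg: SovConfig = SovConfig()) -> bool:
    """The disjunctive match rule on an already scored pair."""
    if isinstance(pair, OverlapPair):
        sov, minov = pair.sov, pair.minov
        len_a, len_b = pair.record_a.length, pair.record_b.length
    else:
        sov, minov = pair["sov"], pair["minov"]
        len_a, len_b = pair["len_a"], pair["len_b"]
    primary = sov >= cfg.sov_match_threshold
    secondary = minov >= cfg.shift_fraction * min(len_a, len_b)
    return bool(primary or (cfg.use_secondary_criterion and secondary))


def score_pair(a: RepeatRecord, b: RepeatRecord, cfg: SovConfig = SovConfig()) -> OverlapPair:
    """Convenience scalar path: score + match one overlapping record pair."""
    if a.chrom != b.chrom:
        raise ValueError("records on different chromosomes do not overlap")
    minov, maxov, delta, sov = sov_score(a.interval, b.interval, cfg)
    primary = sov >= cfg.sov_match_threshold
    secondary = minov >= cfg.shift_fraction * min(a.length, b.length)
    return OverlapPair(
        record_a=a,
        record_b=b,
        minov=minov,
        maxov=maxov,
        delta=delta,
        sov=sov,
        matched_primary=primary,
        matched_secondary=secondary,
        matched=primary or (cfg.use_secondary_criterion and secondary),
    )


# ---------------------------------------------------------------------------
# vectorized pair discovery and scoring

PAIR_COLUMNS = (
    "source_a", "id_a", "source_b", "id_b", "chrom",
    "start_a", "end_a", "start_b", "end_b", "len_a", "len_b",
    "minov", "maxov",
)


def find_overlaps(a: AnnotationSet, b: AnnotationSet) -> pd.DataFrame:
    """All record pairs (one from each set) overlapping by ≥1 bp.

    Returns an unscored pair table (columns :data:`PAIR_COLUMNS`), one row per
    pair, strand-blind.  Backed by a pyranges interval join.
    """
    if a.genome_build != b.genome_build:
        raise ValueError(
            f"genome build mismatch: {a.source_name}={a.genome_build!r} "
            f"vs {b.source_name}={b.genome_build!r}"
        )
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))
    gr_a = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": a.df["chrom"],
                "Start": a.df["start"],
                "End": a.df["end"],
                "id_a": a.df["record_id"],
            }
        )
    )
    gr_b = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": b.df["chrom"],
                "Start": b.df["start"],
                "End": b.df["end"],
                "id_b": b.df["record_id"],
            }
        )
    )
    joined = gr_a.join(gr_b, suffix="_b").df
    if joined.empty:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))
    out = pd.DataFrame(
        {
            "source_a": a.source_name,
            "id_a": joined["id_a"].to_numpy(),
            "source_b": b.source_name,
            "id_b": joined["id_b"].to_numpy(),
            "chrom": joined["Chromosome"].astype(str).to_numpy(),
            "start_a": joined["Start"].to_numpy(np.int64),
            "end_a": joined["End"].to_numpy(np.int64),
            "start_b": joined["Start_b"].to_numpy(np.int64),
            "end_b": joined["End_b"].to_numpy(np.int64),
        }
    )
    out["len_a"] = out["end_a"] - out["start_a"]
    out["len_b"] = out["end_b"] - out["start_b"]
    out["minov"] = np.minimum(out["end_a"], out["end_b"]) - np.maximum(
        out["start_a"], out["start_b"]
    )
    out["maxov"] = np.maximum(out["end_a"], out["end_b"]) - np.minimum(
        out["start_a"], out["start_b"]
    )
    out = out.loc[out["minov"] >= 1].reset_index(drop=True)
    return out.sort_values(["chrom", "start_a", "end_a", "id_a", "id_b"]).reset_index(
        drop=True
    )


def score_overlaps(pairs: pd.DataFrame, cfg: SovConfig = SovConfig()) -> pd.DataFrame:
    """Vectorized Sov scoring + match verdicts on a pair table from
    :func:`find_overlaps`; adds delta, sov, matched_primary, matched_secondary
    and matched columns."""
    out = pairs.copy()
    if out.empty:
        for col in ("delta", "sov"):
            out[col] = pd.Series(dtype=float)
        for col in ("matched_primary", "matched_secondary", "matched"):
            out[col] = pd.Series(dtype=bool)
        return out
    minov = out["minov"].to_numpy(float)
    maxov = out["maxov"].to_numpy(float)
    len_a = out["len_a"].to_numpy(float)
    len_b = out["len_b"].to_numpy(float)
    if cfg.delta_variant == "half_capped":
        delta = np.minimum.reduce([maxov - minov, minov, len_a / 2.0, len_b / 2.0])
    else:
        delta = np.minimum.reduce([maxov - minov, minov, len_a, len_b])
    sov = (minov + delta) / maxov
    primary = sov >= cfg.sov_match_threshold
    secondary = minov >= cfg.shift_fraction * np.minimum(len_a, len_b)
    out["delta"] = delta
    out["sov"] = sov
    out["matched_primary"] = primary
    out["matched_secondary"] = secondary
    out["matched"] = primary | (cfg.use_secondary_criterion & secondary)
    return out


def scored_pairs(
    a: AnnotationSet, b: AnnotationSet, cfg: SovConfig = SovConfig()
) -> pd.DataFrame:
    return score_overlaps(find_overlaps(a, b), cfg)


def matched_ids(
    a: AnnotationSet, b: AnnotationSet, cfg: SovConfig = SovConfig()
) -> tuple[set[str], set[str]]:
    """Record ids of A matched in B and of B matched in A (each id once,
    many-to-many pairs allowed)."""
    pairs = scored_pairs(a, b, cfg)
    hit = pairs.loc[pairs["matched"]]
    return set(hit["id_a"]), set(hit["id_b"])


def pairwise_matched(
    a: AnnotationSet, b: AnnotationSet, cfg: SovConfig = SovConfig()
) -> tuple[int, int, int, int]:
    """Per-record matched counts and bp for one source pair:
    (n_A_matched, bp_A_matched, n_B_matched, bp_B_matched)."""
    ids_a, ids_b = matched_ids(a, b, cfg)
    bp_a = int(_bp_of(a, ids_a))
    bp_b = int(_bp_of(b, ids_b))
    return len(ids_a), bp_a, len(ids_b), bp_b


def _bp_of(aset: AnnotationSet, ids: set[str]) -> int:
    sel = aset.df["record_id"].isin(ids)
    return int((aset.df.loc[sel, "end"] - aset.df.loc[sel, "start"]).sum())


# ---------------------------------------------------------------------------
# three-way decomposition


@dataclass
class SourceDecomposition:
    """Matched/shared/unique decomposition for one source against two others."""

    total_n: int
    total_bp: int
    shared_in_all_n: int
    shared_in_all_bp: int
    unique_n: int
    unique_bp: int
    matched_in_exactly_one_n: int


@dataclass
class ConcordanceReport:
    """Pairwise and three-way concordance between named sources.

    ``pairwise[(x, y)]`` counts records of source x having ≥1 match in source
    y (count, bp of those records).  ``per_source[x]`` carries the shared-in-
    all/unique decomposition; ``per_superfamily[sf]`` repeats the whole
    structure restricted to records of one superfamily.  Percentages in the
    tabular outputs are denominated by the column source's totals, to one
    decimal place.
    """

    sources: list[str]
    totals: dict[str, tuple[int, int]]
    pairwise: dict[tuple[str, str], tuple[int, int]]
    per_source: dict[str, SourceDecomposition]
    per_superfamily: dict[str, "ConcordanceReport"] = field(default_factory=dict)
    config: Optional[SovConfig] = None
    cross_superfamily_matches: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Matrix layout: one column per source, rows = source rows plus the
        shared-in-all and unique rows, cells "n (pct%), bp"."""
        cols = {}
        for x in self.sources:
            tot_n, tot_bp = self.totals[x]
            col = {}
            for y in self.sources:
                if x == y:
                    n, bp = tot_n, tot_bp
                else:
                    n, bp = self.pairwise[(x, y)]
                col[y] = _cell(n, bp, tot_n, tot_bp)
            d = self.per_source[x]
            col["shared_in_all"] = _cell(d.shared_in_all_n, d.shared_in_all_bp, tot_n, tot_bp)
            col["unique"] = _cell(d.unique_n, d.unique_bp, tot_n, tot_bp)
            cols[x] = col
        return pd.DataFrame(cols)

    def to_dict(self) -> dict:
        out = {
            "sources": self.sources,
            "delta_variant": self.config.delta_variant if self.config else None,
            "use_secondary_criterion": (
                self.config.use_secondary_criterion if self.config else None
            ),
            "totals": {s: {"n": n, "bp": bp} for s, (n, bp) in self.totals.items()},
            "pairwise": {
                f"{x}->{y}": {"n": n, "bp": bp}
                for (x, y), (n, bp) in self.pairwise.items()
            },
            "per_source": {
                s: {
                    "total_n": d.total_n,
                    "total_bp": d.total_bp,
                    "shared_in_all_n": d.shared_in_all_n,
                    "shared_in_all_bp": d.shared_in_all_bp,
                    "unique_n": d.unique_n,
                    "unique_bp": d.unique_bp,
                    "matched_in_exactly_one_n": d.matched_in_exactly_one_n,
                }
                for s, d in self.per_source.items()
            },
            "cross_superfamily_matches": self.cross_superfamily_matches,
        }
        if self.per_superfamily:
            out["per_superfamily"] = {
                sf: rep.to_dict() for sf, rep in self.per_superfamily.items()
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _cell(n: int, bp: int, tot_n: int, tot_bp: int) -> str:
    pct_n = 100.0 * n / tot_n if tot_n else 0.0
    pct_bp = 100.0 * bp / tot_bp if tot_bp else 0.0
    return f"{n} ({pct_n:.1f}%), {bp} bp ({pct_bp:.1f}%)"


def three_way(
    a: AnnotationSet,
    b: AnnotationSet,
    c: AnnotationSet,
    cfg: SovConfig = SovConfig(),
    by_superfamily: bool = True,
) -> ConcordanceReport:
    """Full three-source decomposition.

    Per source X with the other two Y, Z: shared_in_all = records matched in
    both, unique = records matched in neither; the pairwise cells are the
    per-record matched counts of :func:`pairwise_matched`.
    """
    sets = {s.source_name: s for s in (a, b, c)}
    if len(sets) != 3:
        raise ValueError("three_way needs three distinctly named sources")
    names = [a.source_name, b.source_name, c.source_name]

    pair_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            pair_tables[(x, y)] = scored_pairs(sets[x], sets[y], cfg)

    report = _decompose(sets, names, pair_tables, cfg)
    report.cross_superfamily_matches = sum(
        _count_cross_superfamily(t, sets[x], sets[y])
        for (x, y), t in pair_tables.items()
    )

    if by_superfamily:
        superfams = sorted(
            set().union(*(set(s.df["superfamily"].unique()) for s in sets.values()))
        )
        for sf in superfams:
            sub_sets = {
                n: sets[n].with_df(sets[n].df.loc[sets[n].df["superfamily"] == sf])
                for n in names
            }
            # pairs restricted to rows where both records carry this superfamily
            sub_tables = {}
            for (x, y), t in pair_tables.items():
                ids_x = set(sub_sets[x].df["record_id"])
                ids_y = set(sub_sets[y].df["record_id"])
                sub_tables[(x, y)] = t.loc[
                    t["id_a"].isin(ids_x) & t["id_b"].isin(ids_y)
                ]
            report.per_superfamily[sf] = _decompose(sub_sets, names, sub_tables, cfg)
    return report


def _decompose(
    sets: dict[str, AnnotationSet],
    names: list[str],
    pair_tables: dict[tuple[str, str], pd.DataFrame],
    cfg: SovConfig,
) -> ConcordanceReport:
    matched: dict[tuple[str, str], set[str]] = {}
    for (x, y), t in pair_tables.items():
        hit = t.loc[t["matched"]]
        matched[(x, y)] = set(hit["id_a"])
        matched[(y, x)] = set(hit["id_b"])

    totals = {
        n: (len(sets[n]), int(sets[n].lengths.sum())) for n in names
    }
    pairwise = {}
    per_source = {}
    for x in names:
        others = [y for y in names if y != x]
        for y in others:
            ids = matched[(x, y)]
            pairwise[(x, y)] = (len(ids), _bp_of(sets[x], ids))
        m0, m1 = matched[(x, others[0])], matched[(x, others[1])]
        shared = m0 & m1
        union = m0 | m1
        tot_n, tot_bp = totals[x]
        unique_n = tot_n - len(union)
        all_ids = set(sets[x].df["record_id"])
        unique_bp = _bp_of(sets[x], all_ids - union)
        per_source[x] = SourceDecomposition(
            total_n=tot_n,
            total_bp=tot_bp,
            shared_in_all_n=len(shared),
            shared_in_all_bp=_bp_of(sets[x], shared),
            unique_n=unique_n,
            unique_bp=unique_bp,
            matched_in_exactly_one_n=len(union) - len(shared),
        )
    return ConcordanceReport(
        sources=list(names),
        totals=totals,
        pairwise=pairwise,
        per_source=per_source,
        config=cfg,
    )


def _count_cross_superfamily(
    pairs: pd.DataFrame, a: AnnotationSet, b: AnnotationSet
) -> int:
    if pairs.empty:
        return 0
    sf_a = pairs["id_a"].map(a.df.set_index("record_id")["superfamily"])
    sf_b = pairs["id_b"].map(b.df.set_index("record_id")["superfamily"])
    return int((pairs["matched"] & (sf_a != sf_b)).sum())
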