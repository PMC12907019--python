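"""Synthetic annotation triples with planted cross-source ground truth.

The generator emulates the structure that makes cross-database HERV
concordance hard to measure, without any sequence:

* Every planted *element* has a true genomic footprint made of one or more
  collinear fragments separated by gaps (insertions/rearrangements that broke
  the element).
* Source ``M`` ("merged", HERVd-like) represents each element as ONE record
  spanning all its fragments *including* the gaps, and carries a
  destruction-degree attribute.
* Sources ``F1`` and ``F2`` ("fragment-style", DFAM/RepBase-like) emit one
  record per fragment, with per-boundary jitter and occasional whole-record
  shifts of a few hundred bp.
* Each source loses a small fraction of records (dropout) and gains a number
  of injected source-only records (uniques).

Element lengths follow a three-archetype mixture — short degraded fragments
(decaying over 50–250 bp), solo LTRs (normal modes near 250 and 450 bp) and long
internal/proviral records (mode near 1600 bp with a tail to ~9 kb) — giving
the characteristic bimodal short-length histogram plus a minor long peak.
Destruction on ``M`` is a two-component Beta mixture whose high-destruction
component is tied to records ≤250 bp, so the high mode vanishes when records
longer than 250 bp are selected.

Elements are placed without inter-element overlap so truth-based precision is
well defined; all randomness flows from one root seed through named
substreams, and identical (params, seed) give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, UNASSIGNED
from .classification import FamilyMapEntry

SOURCES = ("M", "F1", "F2")
ARCHETYPES = ("fragment", "solo_ltr", "provirus")

#: substream names in spawn order (fixed: reordering would change streams)
_STREAMS = (
    "placement",
    "lengths",
    "fragmentation",
    "jitter",
    "shift",
    "dropout",
    "destruction",
    "uniques",
)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated annotation triple."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 20_000_000),
        ("chr3", 20_000_000),
        ("chr4", 20_000_000),
    )
    #: planted element counts per superfamily (proportions follow the relative
    #: prevalence of the five ERV superfamilies in human annotation)
    n_elements: tuple[tuple[str, int], ...] = (
        ("ERV1", 2500),
        ("ERV2", 200),
        ("ERV3", 6300),
        ("Gypsy", 400),
        ("Unclassified", 600),
    )
    #: mixture weights over (fragment, solo_ltr, provirus) archetypes
    archetype_weights: tuple[float, float, float] = (0.35, 0.45, 0.20)
    fragment_length_range: tuple[int, int] = (50, 250)
    fragment_length_scale: float = 40.0  # truncated-exponential decay within the range
    solo_ltr_modes: tuple[tuple[float, float], ...] = ((250.0, 25.0), (450.0, 40.0))
    provirus_mode: float = 1600.0
    provirus_sigma: float = 0.45  # lognormal shape; tail reaches ~9 kb
    provirus_max: int = 9000
    min_element_length: int = 50
    #: probability a long element is split into ≥2 collinear fragments;
    #: short elements (below fragmentation_min_length) are detected whole
    fragmentation_prob: float = 0.30
    fragmentation_min_length: int = 500
    fragment_count_poisson: float = 0.8  # k = 2 + Poisson(λ)
    gap_length_range: tuple[int, int] = (50, 600)
    min_fragment_length: int = 30
    #: boundary noise applied to every fragment-style record boundary
    jitter_sd: float = 5.0
    shift_prob: float = 0.02
    shift_bp: int = 300
    dropout: tuple[tuple[str, float], ...] = (("M", 0.02), ("F1", 0.02), ("F2", 0.02))
    unique_injection: tuple[tuple[str, int], ...] = (("M", 200), ("F1", 200), ("F2", 200))
    #: destruction mixture: low mode for intact records, high mode for ≤250 bp
    destruction_low: tuple[float, float] = (2.0, 5.0)  # Beta(a,b) × 100
    destruction_high: tuple[float, float] = (8.0, 2.0)
    short_high_prob: float = 0.85  # P(high component | record ≤ short_cutoff)
    short_cutoff: int = 250
    inter_element_gap: tuple[int, int] = (200, 2000)
    families_per_superfamily: int = 4
    genome_build: str = "sim1"

    @property
    def total_elements(self) -> int:
        return sum(n for _, n in self.n_elements)

    def validate(self) -> None:
        for _, p in self.dropout:
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must lie in [0, 1]")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ValueError("fragmentation_prob must lie in [0, 1]")
        if not 0.0 <= self.shift_prob <= 1.0:
            raise ValueError("shift_prob must lie in [0, 1]")
        if any(n < 0 for _, n in self.n_elements):
            raise ValueError("element counts must be ≥ 0")
        if any(n < 0 for _, n in self.unique_injection):
            raise ValueError("unique counts must be ≥ 0")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValueError("archetype weights must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted element→record linkage.

    One row per emitted record: element_id, source, record_id, superfamily,
    archetype.  Injected source-only records carry archetype ``"unique"`` and
    a reserved element id, so every emitted record appears in exactly one row.
    """

    table: pd.DataFrame

    def records_of(self, element_id: str, source: str) -> list[str]:
        t = self.table
        sel = (t["element_id"] == element_id) & (t["source"] == source)
        return list(t.loc[sel, "record_id"])

    def element_of(self, source: str) -> pd.Series:
        """record_id → element_id mapping for one source."""
        t = self.table.loc[self.table["source"] == source]
        return t.set_index("record_id")["element_id"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SyntheticTruth":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def default_family_map(params: SimParams = SimParams()) -> dict[str, FamilyMapEntry]:
    """Mapping table covering every family name the generator emits."""
    entries: dict[str, FamilyMapEntry] = {}
    for sf, _ in params.n_elements:
        for j in range(params.families_per_superfamily):
            for suffix, role in (("", "LTR"), ("-int", "internal")):
                fam = f"{sf}F{j}{suffix}"
                entries[fam] = FamilyMapEntry(
                    family=fam, superfamily=sf, group=f"{sf}G{j % 2}", role=role
                )
    return entries


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _draw_lengths(
    params: SimParams, archetypes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(archetypes)
    lengths = np.zeros(n, dtype=np.int64)
    m_frag = archetypes == "fragment"
    lo, hi = params.fragment_length_range
    n_frag = int(m_frag.sum())
    # truncated exponential on [lo, hi] via inverse CDF: short degraded
    # fragments thin out toward the upper end of the range
    u = rng.random(n_frag)
    scale = params.fragment_length_scale
    cdf_hi = 1.0 - np.exp(-(hi - lo) / scale)
    lengths[m_frag] = lo + np.round(-scale * np.log1p(-u * cdf_hi)).astype(np.int64)
    m_solo = archetypes == "solo_ltr"
    n_solo = int(m_solo.sum())
    modes = rng.integers(0, len(params.solo_ltr_modes), size=n_solo)
    mus = np.array([m for m, _ in params.solo_ltr_modes])[modes]
    sds = np.array([s for _, s in params.solo_ltr_modes])[modes]
    lengths[m_solo] = np.round(rng.normal(mus, sds)).astype(np.int64)
    m_prov = archetypes == "provirus"
    n_prov = int(m_prov.sum())
    mu = np.log(params.provirus_mode) + params.provirus_sigma**2
    draw = rng.lognormal(mu, params.provirus_sigma, size=n_prov)
    lengths[m_prov] = np.minimum(np.round(draw), params.provirus_max).astype(np.int64)
    return np.maximum(lengths, params.min_element_length)


def _fragment_element(
    core: int, k: int, params: SimParams, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Split a core length into k pieces (each ≥ min_fragment_length) with
    k−1 gaps; returns (piece lengths, gap lengths)."""
    mn = params.min_fragment_length
    spare = core - k * mn
    cuts = np.sort(rng.integers(0, spare + 1, size=k - 1))
    parts = np.diff(np.concatenate(([0], cuts, [spare]))) + mn
    gaps = rng.integers(*params.gap_length_range, size=k - 1, endpoint=True)
    return [int(p) for p in parts], [int(g) for g in gaps]


def simulate(params: SimParams = SimParams()) -> tuple[tuple[AnnotationSet, ...], SyntheticTruth]:
    """Generate the (M, F1, F2) annotation triple and its truth table."""
    params.validate()
    rngs = _rngs(params.seed)
    n_total = params.total_elements

    superfams = np.repeat(
        [sf for sf, _ in params.n_elements], [n for _, n in params.n_elements]
    )
    archetypes = rngs["lengths"].choice(
        ARCHETYPES, size=n_total, p=list(params.archetype_weights)
    )
    core_lengths = _draw_lengths(params, archetypes, rngs["lengths"])
    fam_idx = rngs["lengths"].integers(0, params.families_per_superfamily, size=n_total)

    # fragmentation: provirus-length elements need ≥ 2·min_fragment length
    frag_rng = rngs["fragmentation"]
    fragmented = frag_rng.random(n_total) < params.fragmentation_prob
    fragmented &= core_lengths >= max(
        params.fragmentation_min_length, 2 * params.min_fragment_length + 1
    )
    n_parts = np.ones(n_total, dtype=np.int64)
    n_parts[fragmented] = 2 + frag_rng.poisson(
        params.fragment_count_poisson, size=int(fragmented.sum())
    )
    n_parts = np.minimum(n_parts, core_lengths // params.min_fragment_length)
    n_parts = np.maximum(n_parts, 1)

    pieces: list[list[int]] = []
    gaps: list[list[int]] = []
    for i in range(n_total):
        if n_parts[i] >= 2:
            p, g = _fragment_element(int(core_lengths[i]), int(n_parts[i]), params, frag_rng)
        else:
            p, g = [int(core_lengths[i])], []
        pieces.append(p)
        gaps.append(g)
    spans = np.array([sum(p) + sum(g) for p, g in zip(pieces, gaps)], dtype=np.int64)

    # placement: shuffle element order, then lay out left→right with random
    # inter-element gaps, filling chromosomes in sequence
    place_rng = rngs["placement"]
    order = place_rng.permutation(n_total)
    inter = place_rng.integers(*params.inter_element_gap, size=n_total, endpoint=True)
    chrom_names = [c for c, _ in params.genome]
    chrom_lens = [l for _, l in params.genome]
    starts = np.zeros(n_total, dtype=np.int64)
    chrom_of = np.zeros(n_total, dtype=np.int64)
    ci, cursor = 0, 0
    # reserve a tail region on the last chromosome for injected uniques
    unique_reserve = 4 * sum(n for _, n in params.unique_injection) * 600 + 10_000
    for pos, i in enumerate(order):
        cursor += int(inter[pos])
        while ci < len(chrom_lens) and cursor + spans[i] > chrom_lens[ci] - (
            unique_reserve if ci == len(chrom_lens) - 1 else 0
        ):
            ci += 1
            cursor = int(inter[pos])
        if ci >= len(chrom_lens):
            raise ValueError(
                f"genome too small to place {n_total} elements "
                f"(total span ≈ {int(spans.sum() + inter.sum())} bp)"
            )
        starts[i] = cursor
        chrom_of[i] = ci
        cursor += int(spans[i])

    element_ids = np.array([f"e{i:06d}" for i in range(n_total)])
    families = np.array(
        [
            f"{sf}F{j}" + ("-int" if arch == "provirus" else "")
            for sf, j, arch in zip(superfams, fam_idx, archetypes)
        ]
    )

    # destruction on M records: high component tied to short records
    destr_rng = rngs["destruction"]
    m_len = spans  # merged record length = span incl. gaps
    lo_a, lo_b = params.destruction_low
    hi_a, hi_b = params.destruction_high
    destr = destr_rng.beta(lo_a, lo_b, size=n_total) * 100.0
    short = m_len <= params.short_cutoff
    take_high = short & (destr_rng.random(n_total) < params.short_high_prob)
    destr[take_high] = destr_rng.beta(hi_a, hi_b, size=int(take_high.sum())) * 100.0

    drop = dict(params.dropout)
    drop_rng = rngs["dropout"]
    jit_rng = rngs["jitter"]
    shift_rng = rngs["shift"]

    sets: dict[str, AnnotationSet] = {}
    truth_rows: list[tuple[str, str, str, str, str]] = []

    for src in SOURCES:
        recs: dict[str, list] = {c: [] for c in (
            "record_id", "chrom", "start", "end", "strand", "family",
            "repeat_class", "superfamily", "destruction",
        )}
        counter = 0
        keep_elem = drop_rng.random(n_total) >= drop.get(src, 0.0) if src == "M" else None
        for i in range(n_total):
            chrom = chrom_names[chrom_of[i]]
            clen = chrom_lens[chrom_of[i]]
            if src == "M":
                if not keep_elem[i]:
                    continue
                rid = f"{src}_{counter:07d}"
                counter += 1
                recs["record_id"].append(rid)
                recs["chrom"].append(chrom)
                recs["start"].append(int(starts[i]))
                recs["end"].append(int(starts[i] + spans[i]))
                recs["strand"].append(".")
                recs["family"].append(families[i])
                recs["repeat_class"].append("LTR")
                recs["superfamily"].append(UNASSIGNED)
                recs["destruction"].append(float(round(destr[i], 4)))
                truth_rows.append((element_ids[i], src, rid, superfams[i], archetypes[i]))
            else:
                # one record per fragment, jittered and occasionally shifted
                pos = int(starts[i])
                for j, plen in enumerate(pieces[i]):
                    s, e = pos, pos + plen
                    pos = e + (gaps[i][j] if j < len(gaps[i]) else 0)
                    if drop_rng.random() < drop.get(src, 0.0):
                        continue
                    js, je = jit_rng.normal(0, params.jitter_sd, size=2)
                    s2 = int(round(s + js))
                    e2 = int(round(e + je))
                    if shift_rng.random() < params.shift_prob:
                        off = int(params.shift_bp) * (1 if shift_rng.random() < 0.5 else -1)
                        s2 += off
                        e2 += off
                    s2 = max(0, min(s2, clen - 2))
                    e2 = max(s2 + 1, min(e2, clen))
                    rid = f"{src}_{counter:07d}"
                    counter += 1
                    recs["record_id"].append(rid)
                    recs["chrom"].append(chrom)
                    recs["start"].append(s2)
                    recs["end"].append(e2)
                    recs["strand"].append(".")
                    recs["family"].append(families[i])
                    recs["repeat_class"].append("LTR")
                    recs["superfamily"].append(UNASSIGNED)
                    recs["destruction"].append(np.nan)
                    truth_rows.append(
                        (element_ids[i], src, rid, superfams[i], archetypes[i])
                    )
        sets[src] = AnnotationSet(
            pd.DataFrame(recs) if recs["record_id"] else _empty(),
            source_name=src,
            genome_build=params.genome_build,
        )

    # injected source-only records in the reserved tail of the last chromosome
    uniq_rng = rngs["uniques"]
    last_chrom = chrom_names[-1]
    last_len = chrom_lens[-1]
    zone_start = last_len - unique_reserve
    cursor = zone_start
    uniq = dict(params.unique_injection)
    for src in SOURCES:
        n_u = uniq.get(src, 0)
        if n_u == 0:
            continue
        df = sets[src].df
        add: dict[str, list] = {c: [] for c in df.columns}
        counter = len(df)
        for u in range(n_u):
            ulen = int(uniq_rng.integers(*params.fragment_length_range, endpoint=True))
            cursor += int(uniq_rng.integers(300, 900))
            if cursor + ulen > last_len:
                raise ValueError("unique-injection zone exhausted; enlarge genome")
            rid = f"{src}_{counter:07d}"
            counter += 1
            sf = str(uniq_rng.choice([s for s, _ in params.n_elements]))
            add["record_id"].append(rid)
            add["chrom"].append(last_chrom)
            add["start"].append(cursor)
            add["end"].append(cursor + ulen)
            add["strand"].append(".")
            add["family"].append(f"{sf}F0")
            add["repeat_class"].append("LTR")
            add["superfamily"].append(UNASSIGNED)
            add["destruction"].append(
                float(round(uniq_rng.beta(hi_a, hi_b) * 100.0, 4)) if src == "M" else np.nan
            )
            truth_rows.append((f"uniq_{src}_{u:05d}", src, rid, sf, "unique"))
            cursor += ulen
        sets[src] = AnnotationSet(
            pd.concat([df, pd.DataFrame(add)], ignore_index=True),
            source_name=src,
            genome_build=params.genome_build,
        )

    truth = SyntheticTruth(
        pd.DataFrame(
            truth_rows,
            columns=["element_id", "source", "record_id", "superfamily", "archetype"],
        )
    )
    return (sets["M"], sets["F1"], sets["F2"]), truth


def _empty() -> pd.DataFrame:
    from .annotation_io import _empty_frame

    return _empty_frame()


# ---------------------------------------------------------------------------
# truth-based recovery scoring


def recovery_metrics(
    scored_pairs: Mapping[tuple[str, str], pd.DataFrame] | pd.DataFrame,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Sensitivity/precision of cross-source element recovery.

    For each source pair (X, Y): sensitivity is the fraction of planted
    elements represented by ≥1 record in *both* sources for which at least one
    matched record pair links records of that element; precision is the
    fraction of matched record pairs that link records of the same element.
    Accepts one scored-pair table or a mapping keyed by (source_a, source_b).
    """
    if isinstance(scored_pairs, pd.DataFrame):
        tables = {}
        for (sa, sb), grp in scored_pairs.groupby(["source_a", "source_b"], sort=True):
            tables[(sa, sb)] = grp
    else:
        tables = dict(scored_pairs)

    t = truth.table
    known_ids = set(t["record_id"])
    rows = []
    for (sa, sb), pairs in tables.items():
        ids = set(pairs["id_a"]) | set(pairs["id_b"])
        if not ids <= known_ids:
            missing = sorted(ids - known_ids)[:3]
            raise ValueError(f"record ids absent from truth table: {missing} ...")
        elem_a = truth.element_of(sa)
        elem_b = truth.element_of(sb)
        planted = t.loc[t["archetype"] != "unique"]
        in_a = set(planted.loc[planted["source"] == sa, "element_id"])
        in_b = set(planted.loc[planted["source"] == sb, "element_id"])
        both = in_a & in_b

        hit = pairs.loc[pairs["matched"]]
        ea = hit["id_a"].map(elem_a)
        eb = hit["id_b"].map(elem_b)
        same = ea == eb
        recovered = set(ea[same]) & both
        n_matched = int(len(hit))
        rows.append(
            {
                "source_a": sa,
                "source_b": sb,
                "n_elements_in_both": len(both),
                "n_recovered": len(recovered),
                "sensitivity": len(recovered) / len(both) if both else np.nan,
                "n_matched_pairs": n_matched,
                "n_same_element_pairs": int(same.sum()),
                "precision": float(same.sum()) / n_matched if n_matched else np.nan,
            }
        )
    return pd.DataFrame(rows)
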