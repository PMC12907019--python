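import numpy as np
import pandas as pd
import pytest

from hervconcord import AnnotationSet, RepeatRecord, SimParams, simulate


def make_set(intervals, source="S", chrom="chr1", build="hg", **kw):
    """Build an AnnotationSet from (start, end) tuples or
    (chrom, start, end) triples."""
    recs = []
    for i, iv in enumerate(intervals):
        if len(iv) == 3:
            c, s, e = iv
        else:
            c, (s, e) = chrom, iv
        recs.append(
            RepeatRecord(record_id=f"{source}{i}", chrom=c, start=s, end=e, **kw)
        )
    return AnnotationSet(recs, source_name=source, genome_build=build)


def random_set(rng, n, source, n_chroms=3, span=100_000, max_len=800, build="hg"):
    chroms = rng.integers(0, n_chroms, size=n)
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    recs = [
        RepeatRecord(
            record_id=f"{source}{i}",
            chrom=f"chr{chroms[i] + 1}",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
        )
        for i in range(n)
    ]
    return AnnotationSet(recs, source_name=source, genome_build=build)


def brute_force_pairs(a: AnnotationSet, b: AnnotationSet) -> set:
    """All-pairs O(n·m) overlap enumeration — the oracle for find_overlaps."""
    out = set()
    for ra in a.df.itertuples(index=False):
        for rb in b.df.itertuples(index=False):
            if ra.chrom != rb.chrom:
                continue
            if min(ra.end, rb.end) - max(ra.start, rb.start) >= 1:
                out.add((ra.record_id, rb.record_id))
    return out


SMALL_SIM = SimParams(
    seed=11,
    genome=(("chr1", 4_000_000), ("chr2", 4_000_000)),
    n_elements=(("ERV1", 300), ("ERV2", 40), ("ERV3", 500), ("Gypsy", 60), ("Unclassified", 100)),
    unique_injection=(("M", 30), ("F1", 30), ("F2", 30)),
)


@pytest.fixture(scope="session")
def small_triple():
    """A ~1000-element simulated triple with default noise levels."""
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def default_triple():
    """The reference-condition triple (10 000 elements, default params)."""
    return simulate(SimParams(seed=1))
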