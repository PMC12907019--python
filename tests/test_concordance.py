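"""Sov scoring, the disjunctive match rule and the three-way decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hervconcord import (
    SovConfig,
    find_overlaps,
    is_match,
    pairwise_matched,
    score_overlaps,
    score_pair,
    scored_pairs,
    sov_score,
    three_way,
)

from conftest import brute_force_pairs, make_set, random_set

HALF = SovConfig(delta_variant="half_capped")
PRINTED = SovConfig(delta_variant="as_printed")
SOV_ONLY = SovConfig(use_secondary_criterion=False)

# the published worked example: a RepBase LOR1-int locus vs its counterparts
REPBASE = (48138333, 48140169)
HERVD = (48138680, 48141264)
DFAM = (48138659, 48141279)


class TestSovScore:
    def test_identical_intervals_sov_one_both_variants(self):
        for cfg in (HALF, PRINTED):
            minov, maxov, delta, sov = sov_score((100, 200), (100, 200), cfg)
            assert (minov, maxov, delta, sov) == (100, 100, 0, 1.0)

    def test_worked_example_half_capped(self):
        minov, maxov, delta, sov = sov_score(REPBASE, HERVD, HALF)
        assert (minov, maxov) == (1489, 2931)
        assert delta == 918.0  # len(RepBase)/2
        assert sov == pytest.approx(0.8212, abs=1e-4)

    def test_worked_example_as_printed_reaches_one(self):
        minov, maxov, delta, sov = sov_score(REPBASE, HERVD, PRINTED)
        assert delta == 1442.0  # maxov - minov
        assert sov == 1.0

    def test_quarter_overlap_same_under_both_variants(self):
        for cfg in (HALF, PRINTED):
            minov, maxov, delta, sov = sov_score((0, 100), (50, 400), cfg)
            assert (minov, maxov) == (50, 400)
            assert sov == 0.25

    def test_non_overlapping_inputs_rejected(self):
        with pytest.raises(ValueError):
            sov_score((0, 100), (100, 200))

    @given(
        a0=st.integers(0, 1000), la=st.integers(1, 500),
        b0=st.integers(0, 1000), lb=st.integers(1, 500),
        variant=st.sampled_from(["half_capped", "as_printed"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetry_and_bounds(self, a0, la, b0, lb, variant):
        a, b = (a0, a0 + la), (b0, b0 + lb)
        if min(a[1], b[1]) - max(a[0], b[0]) < 1:
            return
        cfg = SovConfig(delta_variant=variant)
        res_ab = sov_score(a, b, cfg)
        res_ba = sov_score(b, a, cfg)
        assert res_ab == res_ba
        minov, maxov, delta, sov = res_ab
        assert 0 < sov <= 1
        assert minov <= min(la, lb) <= max(la, lb) <= maxov

    def test_containment_closed_form_small_sweep(self):
        # a ⊆ b: sov=1 iff len(a) ≥ len(b)/2 (printed) / ≥ ⅔·len(b) (half-capped)
        for lb in range(1, 40):
            b = (0, lb)
            for la in range(1, lb + 1):
                a = (0, la)
                assert (sov_score(a, b, PRINTED)[3] == 1.0) == (la >= lb / 2)
                assert (sov_score(a, b, HALF)[3] == 1.0) == (la >= 2 * lb / 3)


class TestIsMatch:
    def test_identical_intervals_match(self):
        a = make_set([(100, 200)], source="A").records[0]
        b = make_set([(100, 200)], source="B").records[0]
        assert score_pair(a, b).matched

    def test_contained_fragment_rescued_by_secondary_criterion(self):
        # merged [0,1000) vs fragment [0,300): Sov < 1 either way, but the
        # overlap covers 100% ≥ 95% of the fragment
        frag = make_set([(0, 300)], source="A").records[0]
        merged = make_set([(0, 1000)], source="B").records[0]
        pair = score_pair(frag, merged, HALF)
        assert pair.sov < 1
        assert pair.matched_secondary and pair.matched
        assert not score_pair(frag, merged, SOV_ONLY).matched

    def test_insufficient_overlap_not_matched(self):
        a = make_set([(0, 100)], source="A").records[0]
        b = make_set([(50, 400)], source="B").records[0]
        pair = score_pair(a, b)
        assert pair.minov == 50 < 0.95 * 100
        assert not pair.matched

    def test_shifted_worked_example_fails_both_criteria(self):
        # ~300 bp shift exceeds the 5% allowance on a ~2 kb locus
        a = make_set([REPBASE], source="A").records[0]
        b = make_set([HERVD], source="B").records[0]
        pair = score_pair(a, b, HALF)
        assert not pair.matched
        d = make_set([DFAM], source="B").records[0]
        assert not score_pair(a, d, HALF).matched


class TestFindOverlaps:
    def test_halfopen_touch_is_not_overlap(self):
        a = make_set([(0, 100)], source="A")
        b = make_set([(100, 200)], source="B")
        assert len(find_overlaps(a, b)) == 0

    def test_minimal_one_bp_overlap(self):
        a = make_set([(0, 100)], source="A")
        b = make_set([(99, 200)], source="B")
        pairs = find_overlaps(a, b)
        assert len(pairs) == 1
        assert pairs.iloc[0]["minov"] == 1

    def test_build_mismatch_rejected(self):
        a = make_set([(0, 100)], source="A", build="hg38")
        b = make_set([(0, 100)], source="B", build="hg19")
        with pytest.raises(ValueError, match="build"):
            find_overlaps(a, b)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_set(rng, int(rng.integers(1, 200)), "A")
        b = random_set(rng, int(rng.integers(1, 200)), "B")
        pairs = find_overlaps(a, b)
        got = set(zip(pairs["id_a"], pairs["id_b"]))
        assert got == brute_force_pairs(a, b)
        assert len(pairs) == len(got)  # each pair appears once

    def test_empty_inputs(self):
        a = make_set([], source="A")
        b = make_set([(0, 10)], source="B")
        assert len(find_overlaps(a, b)) == 0


class TestPairwiseMatched:
    def test_merged_vs_fragments_combined_criterion(self):
        merged = make_set([(0, 1000)], source="A")
        frags = make_set([(0, 300), (350, 650), (700, 1000)], source="B")
        n_a, bp_a, n_b, bp_b = pairwise_matched(merged, frags, HALF)
        assert (n_a, n_b) == (1, 3)
        assert bp_a == 1000 and bp_b == 900

    def test_merged_vs_fragments_sov_only_matches_none(self):
        merged = make_set([(0, 1000)], source="A")
        frags = make_set([(0, 300), (350, 650), (700, 1000)], source="B")
        cfg = SovConfig(delta_variant="half_capped", use_secondary_criterion=False)
        assert pairwise_matched(merged, frags, cfg) == (0, 0, 0, 0)

    def test_disjoint_sets_all_zero(self):
        a = make_set([(0, 100)], source="A")
        b = make_set([(500, 600)], source="B")
        assert pairwise_matched(a, b) == (0, 0, 0, 0)

    def test_lowering_shift_fraction_never_decreases_matches(self):
        rng = np.random.default_rng(5)
        a = random_set(rng, 150, "A")
        b = random_set(rng, 150, "B")
        counts = []
        for frac in (1.0, 0.95, 0.8, 0.5, 0.2):
            cfg = SovConfig(shift_fraction=frac)
            n_a, _, n_b, _ = pairwise_matched(a, b, cfg)
            counts.append((n_a, n_b))
        for prev, cur in zip(counts, counts[1:]):
            assert cur[0] >= prev[0] and cur[1] >= prev[1]


class TestThreeWay:
    def test_identical_singletons_all_shared(self):
        sets = [make_set([(0, 100)], source=s) for s in "ABC"]
        rep = three_way(*sets)
        for s in "ABC":
            d = rep.per_source[s]
            assert d.shared_in_all_n == 1
            assert d.unique_n == 0

    def test_partner_missing_in_one_source(self):
        a = make_set([(0, 100)], source="A")
        b = make_set([(0, 100)], source="B")
        c = make_set([], source="C")
        rep = three_way(a, b, c)
        d = rep.per_source["A"]
        assert d.shared_in_all_n == 0
        assert d.unique_n == 0
        assert d.matched_in_exactly_one_n == 1

    def test_conservation_per_source(self, small_triple):
        (m, f1, f2), _ = small_triple
        rep = three_way(m, f1, f2)
        for s, d in rep.per_source.items():
            assert d.unique_n + d.shared_in_all_n + d.matched_in_exactly_one_n == d.total_n
            assert d.shared_in_all_n <= min(
                rep.pairwise[(s, o)][0] for o in rep.sources if o != s
            )

    def test_superfamily_breakdown_totals(self, small_triple):
        from hervconcord import assign_superfamilies, default_family_map
        from conftest import SMALL_SIM

        (m, f1, f2), _ = small_triple
        fmap = default_family_map(SMALL_SIM)
        sets = [assign_superfamilies(s, fmap)[0] for s in (m, f1, f2)]
        rep = three_way(*sets, by_superfamily=True)
        for s in rep.sources:
            by_sf = sum(
                sub.totals[s][0] for sub in rep.per_superfamily.values()
            )
            assert by_sf == rep.totals[s][0]

    def test_report_serializes(self, small_triple, tmp_path):
        import json

        (m, f1, f2), _ = small_triple
        rep = three_way(m, f1, f2)
        rep.to_json(tmp_path / "r.json")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["totals"]["M"]["n"] == len(m)
        frame = rep.to_frame()
        assert set(frame.columns) == {"M", "F1", "F2"}


class TestScoreOverlapsVectorized:
    def test_agrees_with_scalar_path(self):
        rng = np.random.default_rng(3)
        a = random_set(rng, 120, "A")
        b = random_set(rng, 120, "B")
        for cfg in (HALF, PRINTED, SOV_ONLY):
            pairs = scored_pairs(a, b, cfg)
            recs_a = {r.record_id: r for r in a.records}
            recs_b = {r.record_id: r for r in b.records}
            for row in pairs.itertuples(index=False):
                pair = score_pair(recs_a[row.id_a], recs_b[row.id_b], cfg)
                assert pair.sov == pytest.approx(row.sov)
                assert pair.matched == row.matched
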