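import numpy as np
import pytest
from hypothesis import given, strategies as st

from orgweave.models import AlignmentHit
from orgweave.transfers import (TransferConfig, TransferRegion, TransferSegment,
                                assign_segment_sources, classify_region,
                                detect_transfers, filter_hits,
                                merge_segments_into_regions, summarize_transfers,
                                validate_junctions)

CFG = TransferConfig()


def hit(length, identity, source="mito", contig="c1", start=1_000):
    return AlignmentHit("org", contig, 0, length, start, start + length, "+",
                        identity, length, source_tag=source)


def seg(start, end, source="M", contig="c1"):
    return TransferSegment(contig, start, end, source, 95.0)


class TestFilterBoundaries:
    @pytest.mark.parametrize("length,identity,kept", [
        (100, 99.0, False),   # strictly greater than 100 bp required
        (101, 85.0, True),    # inclusive minimum identity
        (5_000, 84.9, False),
        (101, 84.99, False),
        (102, 100.0, True),
    ])
    def test_length_and_identity_semantics(self, length, identity, kept):
        result = filter_hits([hit(length, identity)], CFG)
        assert bool(result) is kept

    @given(st.lists(st.tuples(st.integers(50, 400), st.floats(70, 100)), max_size=30),
           st.floats(85, 95), st.integers(100, 200))
    def test_raising_thresholds_never_grows_the_hit_set(self, specs, min_ident, min_len):
        hits = [hit(l, i) for l, i in specs]
        base = set(map(id, filter_hits(hits, CFG)))
        stricter = TransferConfig(min_hit_length=max(min_len, CFG.min_hit_length),
                                  min_identity=max(min_ident, CFG.min_identity))
        assert set(map(id, filter_hits(hits, stricter))) <= base


class TestAmbiguity:
    def test_high_reciprocal_overlap_becomes_ambiguous(self):
        m = [hit(1_000, 95, "mito", start=1_000)]
        p = [hit(800, 92, "plastid", start=1_100)]
        segments = assign_segment_sources(m, p, CFG)
        assert [s.source for s in segments] == ["A"]
        assert (segments[0].start, segments[0].end) == (1_000, 2_000)
        assert segments[0].best_identity == 95

    def test_low_overlap_stays_distinct(self):
        m = [hit(1_000, 95, "mito", start=1_000)]     # [1000, 2000)
        p = [hit(1_050, 92, "plastid", start=1_950)]  # [1950, 3000): overlap 50/1000
        segments = assign_segment_sources(m, p, CFG)
        assert sorted(s.source for s in segments) == ["M", "P"]

    def test_mito_only_input_gives_all_m(self):
        segments = assign_segment_sources([hit(500, 95, "mito")], [], CFG)
        assert {s.source for s in segments} == {"M"}

    def test_overlapping_same_source_hits_collapse(self):
        m = [hit(500, 90, "mito", start=1_000), hit(500, 95, "mito", start=1_200)]
        segments = assign_segment_sources(m, [], CFG)
        assert len(segments) == 1
        assert (segments[0].start, segments[0].end) == (1_000, 1_700)
        assert segments[0].best_identity == 95


class TestMerge:
    def test_gap_below_cutoff_merges(self):
        regions = merge_segments_into_regions([seg(1_000, 1_400), seg(1_650, 2_000)], CFG)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1_000, 2_000)

    def test_gap_exactly_at_cutoff_does_not_merge(self):
        regions = merge_segments_into_regions([seg(1_000, 1_400), seg(1_700, 2_000)], CFG)
        assert len(regions) == 2

    def test_nested_segments_absorbed(self):
        regions = merge_segments_into_regions([seg(1_000, 5_000), seg(2_000, 3_000)], CFG)
        assert len(regions) == 1 and regions[0].end == 5_000

    def test_different_contigs_never_merge(self):
        regions = merge_segments_into_regions(
            [seg(0, 100, contig="c1"), seg(50, 150, contig="c2")], CFG)
        assert len(regions) == 2

    @staticmethod
    def _closure_oracle(segments, max_gap):
        """O(n^2) transitive closure over the pairwise gap relation."""
        n = len(segments)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = segments[i], segments[j]
                if a.contig_id != b.contig_id:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap < max_gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(segments[i])
        return {frozenset((s.start, s.end) for s in g) for g in groups.values()}

    @given(st.lists(st.tuples(st.integers(0, 5_000), st.integers(1, 800)),
                    min_size=1, max_size=50))
    def test_merge_equals_transitive_closure_oracle(self, spec):
        segments = [seg(s, s + l) for s, l in spec]
        regions = merge_segments_into_regions(segments, CFG)
        got = {frozenset((s.start, s.end) for s in r.segments) for r in regions}
        assert got == self._closure_oracle(segments, CFG.max_merge_gap)

    @given(st.permutations(range(6)))
    def test_merge_is_permutation_invariant(self, order):
        base = [seg(0, 100), seg(250, 400), seg(900, 1_000),
                seg(950, 1_200), seg(2_000, 2_100), seg(2_150, 2_300)]
        shuffled = [base[i] for i in order]
        ref = [(r.start, r.end) for r in merge_segments_into_regions(base, CFG)]
        got = [(r.start, r.end) for r in merge_segments_into_regions(shuffled, CFG)]
        assert got == ref

    def test_merge_is_idempotent(self):
        segments = [seg(0, 100), seg(250, 400), seg(900, 1_000)]
        once = merge_segments_into_regions(segments, CFG)
        again = merge_segments_into_regions(
            [seg(r.start, r.end) for r in once], CFG)
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in once]


class TestClassification:
    @pytest.mark.parametrize("sources,expected", [
        (["M"], "NUMT"),
        (["P"], "NUPT"),
        (["M", "P"], "NUMPT"),
        (["A"], "NUM_PT"),
        (["M", "A"], "NUMT"),
        (["P", "A", "P"], "NUPT"),
    ])
    def test_category_from_source_set(self, sources, expected):
        segments = [seg(i * 1_000, i * 1_000 + 500, src) for i, src in enumerate(sources)]
        region = TransferRegion("c1", 0, len(sources) * 1_000, segments)
        assert classify_region(region) == expected

    def test_empty_region_is_error(self):
        with pytest.raises(ValueError):
            classify_region(TransferRegion("c1", 0, 100, []))

    def test_summary_counts_and_lengths_are_consistent(self):
        regions = detect_transfers(
            [hit(500, 95, "mito", start=1_000), hit(500, 95, "mito", start=10_000)],
            [hit(500, 95, "plastid", start=1_600)], CFG)
        summary = summarize_transfers(regions)
        assert summary["count"].sum() == len(regions)
        assert summary["total_length"].sum() == sum(r.total_length for r in regions)
        by_cat = dict(zip(summary["category"], summary["count"]))
        assert by_cat["NUMPT"] == 1 and by_cat["NUMT"] == 1


def read_aln(start, end, contig="c1", name="r1"):
    return AlignmentHit(name, contig, 0, end - start, start, end, "+", 99.0,
                        end - start, source_tag="read")


class TestJunctionValidation:
    def region(self):
        return TransferRegion("c1", 1_000, 2_000, [seg(1_000, 2_000)], category="NUMT")

    def test_read_spanning_both_sides_validates(self):
        (r,) = validate_junctions([self.region()], [read_aln(900, 1_200)], CFG)
        assert r.left_validated == "yes"

    def test_span_one_short_of_cutoff_fails(self):
        (r,) = validate_junctions([self.region()], [read_aln(951, 1_200)], CFG)
        assert r.left_validated == "no"

    def test_boundary_without_reads_is_untested(self):
        (r,) = validate_junctions([self.region()], [read_aln(5_000, 6_000)], CFG)
        assert (r.left_validated, r.right_validated) == ("untested", "untested")

    def test_each_boundary_judged_separately(self):
        (r,) = validate_junctions([self.region()],
                                  [read_aln(900, 1_200), read_aln(1_900, 2_100)], CFG)
        assert (r.left_validated, r.right_validated) == ("yes", "yes")


class TestPipeline:
    def test_empty_hit_tables_give_empty_output(self):
        regions = detect_transfers([], [], CFG)
        assert regions == []
        summary = summarize_transfers(regions)
        assert summary["count"].sum() == 0 and summary["total_length"].sum() == 0

    def test_every_region_gets_exactly_one_category(self):
        rng = np.random.default_rng(13)
        mito = [hit(int(l), 90, "mito", start=int(s))
                for s, l in zip(rng.integers(0, 100_000, 40), rng.integers(150, 2_000, 40))]
        plastid = [hit(int(l), 90, "plastid", start=int(s))
                   for s, l in zip(rng.integers(0, 100_000, 40), rng.integers(150, 2_000, 40))]
        regions = detect_transfers(mito, plastid, CFG)
        assert all(r.category in ("NUMT", "NUPT", "NUM_PT", "NUMPT") for r in regions)
        assert summarize_transfers(regions)["count"].sum() == len(regions)
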