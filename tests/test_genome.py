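"""Restriction digestion, fragment binning and promoter geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capv2g.genome import (
    GeneModel,
    GenomicInterval,
    RestrictionFragment,
    UnitMap,
    bin_fragments,
    digest_sequence,
    nearest_gene,
    promoter_window,
)


def spans(fragments):
    return [(f.interval.start, f.interval.end) for f in fragments]


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAAA", [(0, 8)]),                # no cut site
            ("NNGATCNN", [(0, 2), (2, 8)]),        # single internal cut
            ("GATCGATC", [(0, 4), (4, 8)]),        # cut at index 0: no empty fragment
            ("gatcgatc", [(0, 4), (4, 8)]),        # case-insensitive
            ("AG", [(0, 2)]),                      # motif longer than sequence
        ],
    )
    def test_cut_positions(self, seq, expected):
        assert spans(digest_sequence(seq, "chr1")) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest_sequence("", "chr1")

    def test_ambiguous_bases_never_match(self):
        # N cannot stand in for any motif base
        assert spans(digest_sequence("GATNGNTC", "chr1")) == [(0, 8)]

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
    def test_fragments_tile_sequence(self, seq):
        frags = digest_sequence(seq, "chrX")
        assert frags[0].interval.start == 0
        assert frags[-1].interval.end == len(seq)
        for a, b in zip(frags[:-1], frags[1:]):
            assert a.interval.end == b.interval.start
        assert sum(len(f.interval) for f in frags) == len(seq)
        assert [f.fragment_id for f in frags] == list(range(len(frags)))


class TestBinning:
    def make(self, lengths):
        frags, pos = [], 0
        for i, ln in enumerate(lengths):
            frags.append(
                RestrictionFragment(i, GenomicInterval("chr1", pos, pos + ln))
            )
            pos += ln
        return frags

    @pytest.mark.parametrize(
        "n_frags,k,sizes",
        [(8, 4, [4, 4]), (9, 4, [4, 4, 1]), (1, 4, [1]), (7, 3, [3, 3, 1])],
    )
    def test_bin_sizes(self, n_frags, k, sizes):
        frags = self.make([100] * n_frags)
        bins = bin_fragments(frags, k)
        assert [len(b.member_fragment_ids) for b in bins] == sizes
        # conservation: every fragment in exactly one bin
        members = [fid for b in bins for fid in b.member_fragment_ids]
        assert members == list(range(n_frags))

    def test_degenerate_bin_interval_equals_fragment(self):
        frags = self.make([250])
        (b,) = bin_fragments(frags, 4)
        assert (b.interval.start, b.interval.end) == (0, 250)

    def test_bin_interval_spans_members(self):
        frags = self.make([100, 50, 200, 75, 30])
        bins = bin_fragments(frags, 4)
        assert (bins[0].interval.start, bins[0].interval.end) == (0, 425)
        assert (bins[1].interval.start, bins[1].interval.end) == (425, 455)

    def test_non_tiling_fragments_rejected(self):
        frags = [
            RestrictionFragment(0, GenomicInterval("chr1", 0, 100)),
            RestrictionFragment(1, GenomicInterval("chr1", 150, 200)),
        ]
        with pytest.raises(ValueError):
            bin_fragments(frags)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            bin_fragments(self.make([100]), 0)


class TestPromoterWindow:
    def test_plus_strand(self):
        g = GeneModel("g1", "G1", "chr1", 10_000, "+")
        w = promoter_window(g)
        assert (w.interval.start, w.interval.end) == (8500, 10_500)

    def test_minus_strand_mirrors_transcription_direction(self):
        g = GeneModel("g1", "G1", "chr1", 10_000, "-")
        w = promoter_window(g)
        assert (w.interval.start, w.interval.end) == (9501, 11_501)

    def test_clamped_at_chromosome_start(self):
        g = GeneModel("g1", "G1", "chr1", 100, "+")
        w = promoter_window(g, chrom_length=50_000)
        assert (w.interval.start, w.interval.end) == (0, 600)

    def test_window_length_is_2000_when_unclamped(self):
        for strand in "+-":
            g = GeneModel("g1", "G1", "chr1", 40_000, strand)
            assert len(promoter_window(g, 100_000).interval) == 2000

    def test_tss_outside_chromosome_rejected(self):
        g = GeneModel("g1", "G1", "chr1", 10_000, "+")
        with pytest.raises(ValueError):
            promoter_window(g, chrom_length=5000)


class TestNearestGene:
    GENES = [
        GeneModel("gA", "A", "chr1", 6000, "+"),
        GeneModel("gB", "B", "chr1", 4000, "+"),
        GeneModel("gC", "C", "chr2", 100, "+"),
    ]

    def test_unique_minimum(self):
        genes = [
            GeneModel("g1", "1", "chr1", 4000, "+"),
            GeneModel("g2", "2", "chr1", 7000, "+"),
        ]
        assert nearest_gene("chr1", 5000, genes) == "g1"

    def test_tie_breaks_lexicographically(self):
        assert nearest_gene("chr1", 5000, self.GENES) == "gA"

    def test_position_on_tss(self):
        assert nearest_gene("chr1", 4000, self.GENES) == "gB"

    def test_no_gene_on_chromosome(self):
        with pytest.raises(LookupError):
            nearest_gene("chr9", 100, self.GENES)


class TestUnitMap:
    def tiling(self, boundaries):
        frags = [
            RestrictionFragment(i, GenomicInterval("chr1", a, b))
            for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:]))
        ]
        return UnitMap.from_fragments({"chr1": frags}), frags

    def test_containment_and_boundary_span(self):
        units, _ = self.tiling([0, 2, 8])
        assert units.assign(GenomicInterval("chr1", 2, 8)) == [("chr1", 1)]
        assert units.assign(GenomicInterval("chr1", 1, 3)) == [
            ("chr1", 0), ("chr1", 1),
        ]

    def test_out_of_range_and_unknown_chromosome_yield_empty(self):
        units, _ = self.tiling([0, 2, 8])
        assert units.assign(GenomicInterval("chr1", 8, 9)) == []
        assert units.assign(GenomicInterval("chr5", 0, 10)) == []

    def test_matches_per_nucleotide_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cuts = np.unique(rng.integers(1, 200, size=8))
            boundaries = [0, *cuts.tolist(), 200]
            units, frags = self.tiling(boundaries)
            s = int(rng.integers(0, 199))
            e = int(rng.integers(s + 1, 201))
            expected = [
                ("chr1", f.fragment_id)
                for f in frags
                if any(f.interval.start <= p < f.interval.end
                       for p in range(s, e))
            ]
            assert units.assign(GenomicInterval("chr1", s, e)) == expected
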