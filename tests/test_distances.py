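"""p-distance / K2P computation and rank-level summaries."""

import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdtools.distances import (
    DistanceUndefinedError,
    PairwiseCounts,
    k2p,
    k2p_distance,
    p_distance,
    pairwise_counts,
    rank_summary,
    rank_summary_from_records,
)

dna = st.text(alphabet="ACGT", min_size=4, max_size=60)


class TestPairwiseCounts:
    def test_identical_sequences(self):
        c = pairwise_counts("ACGT", "ACGT")
        assert (c.p_transitions, c.p_transversions, c.p_distance) == (0, 0, 0)

    def test_single_transversion(self):
        c = pairwise_counts("ACGT", "ACGA")
        assert c.sites_compared == 4
        assert c.p_transitions == 0
        assert c.p_transversions == 0.25
        assert c.p_distance == 0.25

    def test_pairwise_deletion_of_ambiguous_sites(self):
        c = pairwise_counts("ACGTN", "ACATN", already_aligned=True)
        assert c.sites_compared == 4
        assert c.p_transitions == 0.25  # G<->A
        assert c.p_transversions == 0

    def test_no_comparable_sites_flagged(self):
        with pytest.raises(DistanceUndefinedError):
            pairwise_counts("NNNN", "NNNN", already_aligned=True)

    @settings(deadline=None, max_examples=60)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        ca = pairwise_counts(a, b)
        cb = pairwise_counts(b, a)
        assert ca.sites_compared == cb.sites_compared
        assert ca.n_transitions == cb.n_transitions
        assert ca.n_transversions == cb.n_transversions


class TestK2P:
    def test_zero_divergence(self):
        assert k2p(PairwiseCounts(100, 0, 0)) == 0.0

    def test_closed_form_value(self):
        # P=0.1, Q=0.05: d = -1/2 ln(0.75 * sqrt(0.9))
        c = PairwiseCounts(100, 10, 5)
        assert k2p(c) == pytest.approx(0.17018, abs=1e-5)
        assert k2p(c) == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.9)))

    def test_saturation_flagged(self):
        with pytest.raises(DistanceUndefinedError, match="saturated"):
            k2p(PairwiseCounts(100, 45, 20))  # 1-2P-Q = -0.1

    @settings(deadline=None, max_examples=80)
    @given(dna, dna)
    def test_correction_never_shrinks(self, a, b):
        try:
            c = pairwise_counts(a, b)
            d = k2p(c)
        except DistanceUndefinedError:
            return
        assert d >= c.p_distance - 1e-12
        if c.p_distance == 0:
            assert d == 0

    def test_ratio_tends_to_one_at_low_divergence(self):
        # mutation-count ladder on a fixed 400-mer
        base = ("ACGT" * 100)
        ratios = []
        for n_mut in (40, 20, 8, 4, 2, 1):
            mutated = list(base)
            for i in range(n_mut):
                pos = 10 * i
                mutated[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[mutated[pos]]
            c = pairwise_counts(base, "".join(mutated), already_aligned=True)
            ratios.append(k2p(c) / c.p_distance)
        assert all(r >= 1.0 for r in ratios)
        assert ratios == sorted(ratios, reverse=True)
        assert ratios[-1] == pytest.approx(1.0, abs=5e-3)


class TestRankSummary:
    def test_identical_sequences_across_groups(self):
        s = rank_summary(["ACGTACGT", "ACGTACGT"], ["g1", "g2"], rank="genus")
        assert (s.mean, s.max, s.min) == (0.0, 0.0, 0.0)

    def test_matches_bruteforce_between_group_enumeration(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAATTAAAA", "AAAATTAATT"]
        labels = ["g1", "g1", "g2", "g2"]
        expected = []
        for i, j in combinations(range(4), 2):
            if labels[i] != labels[j]:
                expected.append(p_distance(seqs[i], seqs[j]))
        s = rank_summary(seqs, labels, rank="genus", model="p")
        assert s.n_pairs == 4
        assert s.mean == pytest.approx(100 * sum(expected) / len(expected))
        assert s.max == pytest.approx(100 * max(expected))
        assert s.min == pytest.approx(100 * min(expected))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            rank_summary(["ACGT", "ACGA"], ["g", "g"], rank="genus")

    def test_coarser_rank_pairs_nest_within_finer_rank_pairs(self, sim_refdb):
        # records in different families are necessarily in different genera,
        # so the between-family pair set nests inside the between-genus one
        fam = rank_summary_from_records(sim_refdb, "family", "p")
        gen = rank_summary_from_records(sim_refdb, "genus", "p")
        assert fam.n_pairs + fam.n_undefined <= gen.n_pairs + gen.n_undefined
        assert fam.max <= gen.max or fam.max == pytest.approx(gen.max)

    def test_all_pairs_variant_includes_within_group(self):
        seqs = ["ACGTACGT", "ACGAACGT", "TTTTTTTT"]
        labels = ["g1", "g1", "g2"]
        between = rank_summary(seqs, labels, "genus", between_groups=True)
        allpairs = rank_summary(seqs, labels, "genus", between_groups=False)
        assert allpairs.n_pairs == 3 and between.n_pairs == 2
        assert allpairs.min <= between.min


def test_k2p_distance_on_unaligned_pair():
    a = "ACGTACGTACGTACGTACGT"
    assert k2p_distance(a, a) == 0.0
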