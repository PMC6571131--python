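"""Consensus building, primer-pair scanning and in-silico PCR."""

import numpy as np
import pytest

from cpdtools.iupac import DegenerateSequence, revcomp
from cpdtools.primers import (
    DesignConstraints,
    PrimerPair,
    ReferenceRecord,
    consensus_site,
    in_silico_pcr,
    scan_conserved_windows,
    scan_primer_candidates,
)
from cpdtools.refdata import (
    CPD_FWD,
    NEXTERA_FWD_ADAPTER,
    NEXTERA_RVS_ADAPTER,
    cpd_fwd_site_sequences,
)


class TestConsensusSite:
    def test_single_sequence_identity(self):
        assert consensus_site(["ACGT"]).symbols == "ACGT"

    def test_positionwise_collapse(self):
        assert consensus_site(["ACGT", "ACGA"]).symbols == "ACGW"

    def test_reference_panel_site_collapse(self):
        # the 36 published forward-site variants collapse to the primer
        assert consensus_site(cpd_fwd_site_sequences()).symbols == CPD_FWD

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            consensus_site(["ACGT", "ACG"])

    def test_all_gap_column_rejected_with_index(self):
        with pytest.raises(ValueError, match="column 1"):
            consensus_site(["A-GT", "A-GA"])

    def test_degeneracy_monotone_under_adding_sequences(self):
        sites = cpd_fwd_site_sequences()
        full = consensus_site(sites).fold_degeneracy
        for k in (1, 5, 12, 30):
            assert consensus_site(sites[:k]).fold_degeneracy <= full


def _build_alignment(rng, n_rows=10, insert_lengths=None):
    """Aligned rows with planted conserved fwd (17) and rvs (20) sites
    flanking a variable insert; truth known by construction."""
    fwd_site = "GATATCTGACCTCAAGG"  # concrete; one wobble added per row below
    rvs_site = "CCTTCACAGTAGTAACAAAT"  # binding site on the plus strand
    if insert_lengths is None:
        insert_lengths = [428 + i % 7 for i in range(n_rows)]
    max_len = max(insert_lengths)
    ancestor = "".join(rng.choice(list("ACGT"), size=max_len))
    rows = []
    for i in range(n_rows):
        flank_l = "".join(rng.choice(list("ACGT"), size=30))
        flank_r = "".join(rng.choice(list("ACGT"), size=30))
        ins = list(ancestor)
        mut = rng.random(max_len) < 0.15
        for j in np.nonzero(mut)[0]:
            ins[j] = rng.choice([b for b in "ACGT" if b != ins[j]])
        ins = "".join(ins[: insert_lengths[i]])
        ins = ins + "-" * (max_len - insert_lengths[i])  # gap-padded column block
        site = list(fwd_site)
        site[2] = "T" if i % 2 else "C"  # wobble at codon third position
        rows.append(flank_l + "".join(site) + ins + rvs_site + flank_r)
    return rows, fwd_site, rvs_site


class TestScanPrimerCandidates:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(5)
        rows, fwd_site, rvs_site = _build_alignment(rng)
        constraints = DesignConstraints(
            primer_length_range=(17, 20),
            max_degenerate_positions=5,
            amplicon_length_range=(465, 471),
            codon_frame_required=True,
            terminal_conserved_codons=1,
            codon_frame=30 % 3,  # fwd site starts at column 30
        )
        return rows, fwd_site, rvs_site, constraints

    def test_planted_pair_recovered_rank_one(self, planted):
        rows, fwd_site, rvs_site, constraints = planted
        candidates, _ = scan_primer_candidates(rows, constraints)
        assert candidates
        best = candidates[0]
        expected_fwd = list(fwd_site)
        expected_fwd[2] = "Y"  # C/T wobble collapses
        assert best.pair.fwd.symbols == "".join(expected_fwd)
        assert best.pair.rvs.symbols == revcomp(rvs_site)
        assert best.amplicon_length_range == (465, 471)

    def test_zero_degeneracy_budget_yields_empty_with_tally(self, planted):
        rows, _, _, constraints = planted
        constraints.max_degenerate_positions = 0
        candidates, tally = scan_primer_candidates(rows, constraints)
        assert candidates == []
        assert tally["degeneracy"] > 0

    def test_row_order_invariance(self, planted):
        rows, _, _, constraints = planted
        fwd = scan_primer_candidates(rows, constraints)[0]
        rev = scan_primer_candidates(rows[::-1], constraints)[0]
        assert [(c.pair.fwd.symbols, c.pair.rvs.symbols, c.fwd_start, c.rvs_end)
                for c in fwd] == [
            (c.pair.fwd.symbols, c.pair.rvs.symbols, c.fwd_start, c.rvs_end)
            for c in rev
        ]

    def test_single_row_window_count_closed_form(self):
        rng = np.random.default_rng(1)
        row = "".join(rng.choice(list("ACGT"), size=120))
        constraints = DesignConstraints(
            primer_length_range=(15, 18),
            codon_frame_required=False,
            terminal_conserved_codons=0,
        )
        windows, _ = scan_conserved_windows([row], constraints, role="fwd")
        expected = sum(120 - L + 1 for L in range(15, 19))
        assert len(windows) == expected


def _planted_genome(rng, pair, insert_len=431, flank=400, circular=False):
    fwd_site = next(iter(sorted(pair.fwd.expansions())))
    rvs_site = revcomp(sorted(pair.rvs.expansions())[0])
    insert = "".join(rng.choice(list("ACGT"), size=insert_len))
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    seq = left + fwd_site + insert + rvs_site + right
    return ReferenceRecord(id="G1", sequence=seq, circular=circular), insert


class TestInSilicoPcr:
    def test_planted_site_single_hit(self, cpd_pair):
        rng = np.random.default_rng(3)
        rec, insert = _planted_genome(rng, cpd_pair)
        hits = in_silico_pcr(rec, cpd_pair)
        assert len(hits) == 1
        h = hits[0]
        assert h.length == 431 + 17 + 20 == 468
        assert (h.mismatches_fwd, h.mismatches_rvs) == (0, 0)
        assert h.insert(cpd_pair) == insert
        assert h.product == rec.sequence[h.start: h.end]

    def test_no_matching_site_returns_empty(self, cpd_pair):
        rng = np.random.default_rng(4)
        rec = ReferenceRecord(
            id="G0", sequence="".join(rng.choice(list("ACGT"), size=2000))
        )
        assert in_silico_pcr(rec, cpd_pair) == []

    def test_minus_strand_hit_normalized(self, cpd_pair):
        rng = np.random.default_rng(5)
        rec, _ = _planted_genome(rng, cpd_pair)
        flipped = ReferenceRecord(
            id="G2",
            sequence=DegenerateSequence(rec.sequence).revcomp().symbols,
        )
        hits = in_silico_pcr(flipped, cpd_pair)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].length == 468

    def test_circular_origin_spanning_hit(self, cpd_pair):
        rng = np.random.default_rng(6)
        rec, _ = _planted_genome(rng, cpd_pair, flank=400)
        # rotate so the amplicon spans the origin
        seq = rec.sequence
        rotated = seq[600:] + seq[:600]
        circ = ReferenceRecord(id="G3", sequence=rotated, circular=True)
        hits = in_silico_pcr(circ, cpd_pair)
        assert any(h.length == 468 and h.end > len(rotated) for h in hits)
        linear = ReferenceRecord(id="G4", sequence=rotated, circular=False)
        assert all(h.length != 468 for h in in_silico_pcr(linear, cpd_pair))

    def test_mismatch_tolerance(self, cpd_pair):
        rng = np.random.default_rng(7)
        rec, _ = _planted_genome(rng, cpd_pair)
        seq = list(rec.sequence)
        seq[400] = {"G": "C", "A": "C", "T": "C", "C": "G"}[seq[400]]  # break fwd site pos 0
        broken = ReferenceRecord(id="G5", sequence="".join(seq))
        assert in_silico_pcr(broken, cpd_pair, max_mismatch_per_primer=0) == []
        hits = in_silico_pcr(broken, cpd_pair, max_mismatch_per_primer=1)
        assert len(hits) == 1 and hits[0].mismatches_fwd == 1

    def test_screened_product_reenters_pipeline_cleanly(self, cpd_pair):
        from cpdtools.pipeline import primer_screen

        rng = np.random.default_rng(8)
        rec, insert = _planted_genome(rng, cpd_pair)
        hit = in_silico_pcr(rec, cpd_pair)[0]
        screen = primer_screen(hit.product, cpd_pair, size_window=(465, 471))
        assert screen.accepted and screen.insert == insert


def test_adapter_extended_products_match_library_band(sim_refs, sim_templates):
    # Nextera prefixes add 33 + 34 = 67 nt; CPD amplicons of 465-471 give
    # library products of 532-538, the ~535 bp gel band
    extra = len(NEXTERA_FWD_ADAPTER) + len(NEXTERA_RVS_ADAPTER)
    assert extra == 67
    lib_lengths = {len(a) + extra for _, a in sim_templates}
    assert all(532 <= L <= 538 for L in lib_lengths)
    assert all(abs(L - 535) <= 3 for L in lib_lengths)


def test_primer_pair_length_bounds():
    with pytest.raises(ValueError, match="length"):
        PrimerPair(DegenerateSequence("ACGTACGTACGT"), DegenerateSequence("A" * 20))
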