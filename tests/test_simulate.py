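"""Synthetic reference panels, read simulation and recovery metrics."""

import numpy as np
import pytest

from cpdtools.pipeline import PipelineConfig, pairwise_identity, run_pipeline
from cpdtools.primers import in_silico_pcr
from cpdtools.simulate import (
    CommunitySpec,
    _largest_remainder,
    amplicons_from_references,
    evaluate_recovery,
    reference_database,
    simulate_reads,
    simulate_references,
)


class TestSimulateReferences:
    def test_single_taxon_amplifiable_with_zero_mismatches(self):
        sim = simulate_references(1, seed=3)
        hits = in_silico_pcr(sim.records[0], sim.pair)
        assert len(hits) == 1
        assert (hits[0].mismatches_fwd, hits[0].mismatches_rvs) == (0, 0)
        assert hits[0].insert(sim.pair) == sim.inserts[sim.records[0].id]

    def test_between_taxon_identities_below_species_threshold(self):
        sim = simulate_references(5, between_taxon_divergence=0.12, seed=4)
        inserts = list(sim.inserts.values())
        for i in range(len(inserts)):
            for j in range(i):
                assert pairwise_identity(inserts[i], inserts[j]) < 99.0

    def test_fixed_seed_reproducibility(self):
        a = simulate_references(4, seed=9)
        b = simulate_references(4, seed=9)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
        assert a.inserts == b.inserts

    def test_amplicon_lengths_sweep_published_span(self):
        sim = simulate_references(14, seed=5)
        lengths = {
            in_silico_pcr(r, sim.pair)[0].length for r in sim.records
        }
        assert lengths == set(range(465, 472))

    def test_nested_taxonomy(self):
        sim = simulate_references(8, species_per_genus=2, seed=6)
        genera = {r.genus for r in sim.records}
        families = {r.family for r in sim.records}
        assert len(genera) == 4 and len(families) == 2
        assert set(sim.order_map) == families

    def test_divergence_bounds_validated(self):
        with pytest.raises(ValueError):
            simulate_references(2, between_taxon_divergence=0.7)


class TestSimulateReads:
    def test_fixed_seed_reproducibility(self, sim_templates, sim_refs):
        spec = CommunitySpec(proportions=[0.5, 0.5], n_read_pairs=50,
                             substitution_error_rate=0.01, chimera_rate=0.1,
                             seed=21)
        r1, t1 = simulate_reads(sim_templates[:2], spec, sim_refs.pair)
        r2, t2 = simulate_reads(sim_templates[:2], spec, sim_refs.pair)
        assert [(p.seq1, p.qual1, p.seq2, p.qual2) for p in r1] == [
            (p.seq1, p.qual1, p.seq2, p.qual2) for p in r2
        ]
        assert t1.source == t2.source

    def test_exact_sampling_matches_largest_remainder(self, sim_templates,
                                                      sim_refs):
        spec = CommunitySpec(proportions=[0.6, 0.3, 0.1], n_read_pairs=100,
                             substitution_error_rate=0.0, sampling="exact",
                             seed=1)
        _, truth = simulate_reads(sim_templates, spec, sim_refs.pair)
        assert truth.realized_counts == {
            "Species1": 60, "Species2": 30, "Species3": 10
        }

    def test_single_template_clean_run_tabulates_at_hundred_percent(
            self, sim_templates, sim_refs, sim_refdb):
        spec = CommunitySpec(proportions=[1.0], n_read_pairs=100,
                             substitution_error_rate=0.0, chimera_rate=0.0,
                             seed=2)
        reads, _ = simulate_reads(sim_templates[:1], spec, sim_refs.pair)
        result = run_pipeline(reads, sim_refdb, sim_refs.pair, PipelineConfig())
        pct = result.taxon_table.percents["all"]
        assert list(pct) == [100.0]
        assert result.taxon_table.haplotypes["all"].sum() == 1

    def test_truth_ids_match_emitted_reads(self, sim_templates, sim_refs):
        spec = CommunitySpec(proportions=[0.7, 0.3], n_read_pairs=40,
                             chimera_rate=0.2, seed=3)
        reads, truth = simulate_reads(sim_templates[:2], spec, sim_refs.pair)
        assert {p.id for p in reads} == set(truth.source)
        assert all(truth.is_chimera[r] == (truth.source[r] == "")
                   for r in truth.source)

    def test_error_rate_monotonically_stresses_pipeline(self, sim_templates,
                                                        sim_refs, sim_refdb):
        fracs = []
        for rate in (0.0, 0.01, 0.05):
            spec = CommunitySpec(proportions=[0.5, 0.3, 0.2],
                                 n_read_pairs=300,
                                 substitution_error_rate=rate, seed=8)
            reads, _ = simulate_reads(sim_templates, spec, sim_refs.pair)
            res = run_pipeline(reads, sim_refdb, sim_refs.pair, PipelineConfig())
            lg = res.ledger["all"]
            counts = res.taxon_table.contigs.get("all")
            others = int(counts.get("others", 0)) if counts is not None else 0
            lost = (lg["primer_rejected"] + lg["unmerged"] + lg["qc_discarded"]
                    + lg["low_abundance"] + others)
            fracs.append(lost / lg["input_pairs"])
        assert fracs == sorted(fracs)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CommunitySpec(proportions=[0.5, 0.4], n_read_pairs=10)


class TestRecoveryMetrics:
    def test_perfect_run(self, sim_templates, sim_refs, sim_refdb):
        spec = CommunitySpec(proportions=[0.6, 0.3, 0.1], n_read_pairs=200,
                             substitution_error_rate=0.0, sampling="exact",
                             seed=4)
        reads, truth = simulate_reads(sim_templates, spec, sim_refs.pair)
        result = run_pipeline(reads, sim_refdb, sim_refs.pair, PipelineConfig())
        m = evaluate_recovery(result, truth, PipelineConfig())
        assert m.haplotype_recall == 1.0
        assert m.proportion_l1 == pytest.approx(0.0, abs=1e-12)
        assert m.chimera_false_flags == 0

    def test_template_below_min_contigs_reduces_recall(self, sim_refs,
                                                       sim_refdb):
        sim5 = simulate_references(5, seed=31)
        templates = amplicons_from_references(sim5.records, sim5.pair)
        refdb = reference_database(sim5)
        # 1 read for the last template: dropped by the <2-contig rule
        spec = CommunitySpec(
            proportions=[0.4, 0.3, 0.16, 0.135, 0.005], n_read_pairs=200,
            substitution_error_rate=0.0, sampling="exact", seed=5,
        )
        reads, truth = simulate_reads(templates, spec, sim5.pair)
        result = run_pipeline(reads, refdb, sim5.pair, PipelineConfig())
        m = evaluate_recovery(result, truth, PipelineConfig())
        assert m.haplotype_recall == pytest.approx(0.8)

    def test_largest_remainder_apportionment(self):
        assert _largest_remainder([0.5, 0.5], 3) == [2, 1]
        assert _largest_remainder([0.6, 0.3, 0.1], 10) == [6, 3, 1]
        assert sum(_largest_remainder([1 / 3] * 3, 100)) == 100
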