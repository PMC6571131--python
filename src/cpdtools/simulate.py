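"""Synthetic references, community mixtures and paired reads with known truth.

The generator emulates the structure the pipeline expects from real data: a
panel of "mitogenomes" carrying two conserved primer-binding sites flanking
a variable insert, community read mixtures with known proportions,
Phred-style quality decay along each read, substitution errors concentrated
where quality is low, and single-breakpoint PCR chimeras.  Everything is
driven by an explicit seed and is byte-reproducible.

Substitution errors are distributed across read positions proportionally to
the per-base error probability implied by the Phred profile, so (as on a
real instrument) they cluster at the 3' ends of the mates — which is also
the overlap region, where pair merging corrects most of them.  Indels are
not simulated: the primer screen rejects indel-bearing termini by design
and substitutions dominate MiSeq error profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .iupac import DegenerateSequence
from .pipeline import PipelineConfig, PipelineResult, ReadPair, pairwise_identity
from .primers import PrimerPair, ReferenceRecord, in_silico_pcr
from .refdata import cpd_primer_pair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            transition_fraction: float = 0.5) -> str:
    """Substitute each site independently at ``rate``; half the events are
    transitions (mitochondrial markers are transition-rich)."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if rng.random() < transition_fraction:
            out[i] = _TRANSITION[out[i]]
        else:
            choices = [b for b in "ACGT" if b != out[i] and _TRANSITION[out[i]] != b]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@dataclass
class SimulatedReferences:
    """A reference panel plus the ground truth it was built from."""

    records: list[ReferenceRecord]
    inserts: dict[str, str]  # record id -> true insert
    order_map: dict[str, str]  # family -> order (nested taxonomy)
    pair: PrimerPair


def simulate_references(
    n_taxa: int,
    insert_length_range: tuple[int, int] = (428, 434),
    between_taxon_divergence: float = 0.12,
    within_taxon_divergence: float = 0.01,
    primer_pair: PrimerPair | None = None,
    seed: int = 0,
    species_per_genus: int = 1,
    flank_length: int = 500,
) -> SimulatedReferences:
    """Generate a nested-taxonomy reference panel amplifiable by the pair.

    Each record is random flank + a concrete expansion of the forward
    primer + insert + the reverse-complemented reverse-primer site + random
    flank, so in-silico PCR finds exactly one zero-mismatch product per
    record.  Genera diverge from a common ancestor at half the target
    between-taxon divergence (so pairs differ by about the full amount);
    species within a genus diverge at the within-taxon rate; two genera
    share a family and two families an order.  Insert lengths sweep the
    configured range deterministically, so a panel of at least
    ``hi - lo + 1`` taxa realizes every amplicon length the marker shows.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0 < between_taxon_divergence < 0.5:
        raise ValueError("between_taxon_divergence must be in (0, 0.5)")
    pair = primer_pair or cpd_primer_pair()
    rng = np.random.default_rng(seed)
    lo, hi = insert_length_range
    ancestor = _random_seq(rng, hi)
    if between_taxon_divergence * lo < 1:
        warnings.warn("expected between-taxon substitutions < 1; taxa may be identical")

    fwd_expansions = sorted(pair.fwd.expansions())
    rvs_expansions = sorted(pair.rvs.expansions())

    records: list[ReferenceRecord] = []
    inserts: dict[str, str] = {}
    order_map: dict[str, str] = {}
    n_genera = -(-n_taxa // species_per_genus)
    taxon = 0
    for g in range(n_genera):
        genus_insert = _mutate(ancestor, between_taxon_divergence / 2.0, rng)
        family = f"Family{g // 2 + 1}"
        order_map[family] = f"Order{g // 4 + 1}"
        for s in range(species_per_genus):
            if taxon >= n_taxa:
                break
            insert = _mutate(genus_insert, within_taxon_divergence, rng)
            target = lo + taxon % (hi - lo + 1)
            if target < len(insert):
                drop = set(rng.choice(len(insert), size=len(insert) - target,
                                      replace=False).tolist())
                insert = "".join(b for i, b in enumerate(insert) if i not in drop)
            fwd_site = fwd_expansions[rng.integers(len(fwd_expansions))]
            rvs_site = DegenerateSequence(
                rvs_expansions[rng.integers(len(rvs_expansions))]
            ).revcomp().symbols
            seq = (
                _random_seq(rng, flank_length)
                + fwd_site + insert + rvs_site
                + _random_seq(rng, flank_length)
            )
            rec_id = f"SIM{taxon + 1:03d}"
            records.append(
                ReferenceRecord(
                    id=rec_id,
                    sequence=seq,
                    taxonomy=(family, f"Genus{g + 1}", f"Species{taxon + 1}"),
                )
            )
            inserts[rec_id] = insert
            taxon += 1
    return SimulatedReferences(records, inserts, order_map, pair)


def reference_database(simrefs: SimulatedReferences) -> list[ReferenceRecord]:
    """Insert-level taxonomy records for identity-threshold assignment.

    Assignment compares query inserts against the marker region itself, so
    the database holds each reference's primer-trimmed insert rather than
    the whole simulated genome.
    """
    return [
        ReferenceRecord(id=rec.id, sequence=simrefs.inserts[rec.id],
                        taxonomy=rec.taxonomy)
        for rec in simrefs.records
    ]


def amplicons_from_references(
    refs: Sequence[ReferenceRecord], pair: PrimerPair
) -> list[tuple[str, str]]:
    """(species name, primer-inclusive amplicon) per reference, via PCR."""
    out = []
    for rec in refs:
        hits = in_silico_pcr(rec, pair, max_mismatch_per_primer=0)
        if not hits:
            raise ValueError(f"reference {rec.id} is not amplifiable by the pair")
        out.append((rec.species or rec.id, hits[0].product))
    return out


@dataclass
class CommunitySpec:
    """Read-simulation settings for one community mixture.

    ``proportions`` must align with the template list and sum to one.
    ``sampling`` is "multinomial" (realistic sampling noise) or "exact"
    (largest-remainder apportionment: read counts exactly proportional,
    for deterministic end-to-end checks).  Chimeric pairs replace ordinary
    ones at ``chimera_rate``; their breakpoints fall in the middle band of
    the amplicon, where template switching leaves a detectable segment from
    each parent.
    """

    proportions: Sequence[float]
    n_read_pairs: int
    read_length: int = 300
    substitution_error_rate: float = 0.001
    quality_start: int = 37
    quality_decay: float = 0.03
    quality_jitter: int = 2
    chimera_rate: float = 0.0
    chimera_breakpoint_band: tuple[float, float] = (0.25, 0.75)
    sampling: str = "multinomial"
    group: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        for name in ("substitution_error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sampling not in ("multinomial", "exact"):
            raise ValueError("sampling must be 'multinomial' or 'exact'")


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated reads."""

    taxa: list[str]
    proportions: dict[str, float]  # planted
    realized_counts: dict[str, int]  # non-chimeric pairs actually emitted
    source: dict[str, str]  # read id -> taxon ("" for chimeras)
    is_chimera: dict[str, bool]
    chimera_parents: dict[str, tuple[str, str]]
    template_inserts: dict[str, str]  # taxon -> primer-trimmed insert


def _largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_reads(
    templates: Sequence[tuple[str, str]],
    spec: CommunitySpec,
    pair: PrimerPair | None = None,
) -> tuple[list[ReadPair], TruthTable]:
    """Emit paired reads from a community of amplicon templates.

    Each pair is the first/last ``read_length`` bases of its amplicon (mate
    2 reverse-complemented), with Phred qualities from a linear decay plus
    seeded jitter and substitution errors distributed according to those
    qualities.  Read ids encode nothing about the truth.
    """
    if len(templates) != len(spec.proportions):
        raise ValueError("one proportion per template required")
    pair = pair or cpd_primer_pair()
    min_amplicon = min(len(a) for _, a in templates)
    if min_amplicon < 2 * spec.read_length - (len(templates[0][1])):
        pass  # reads always overlap when amplicon < 2 * read_length
    if min_amplicon <= spec.read_length // 2:
        raise ValueError("amplicon too short for meaningful pairing")
    rng = np.random.default_rng(spec.seed)
    names = [t for t, _ in templates]
    amps = {t: a for t, a in templates}

    n = spec.n_read_pairs
    if spec.sampling == "exact":
        n_chim = int(round(spec.chimera_rate * n))
        counts = _largest_remainder(spec.proportions, n - n_chim)
        labels = ["\0chimera"] * n_chim + [
            names[i] for i, c in enumerate(counts) for _ in range(c)
        ]
        rng.shuffle(labels)
    else:
        labels = []
        for _ in range(n):
            if spec.chimera_rate and rng.random() < spec.chimera_rate:
                labels.append("\0chimera")
            else:
                labels.append(names[rng.choice(len(names), p=list(spec.proportions))])

    fwd_len, rvs_len = len(pair.fwd), len(pair.rvs)
    truth = TruthTable(
        taxa=names,
        proportions=dict(zip(names, spec.proportions)),
        realized_counts={t: 0 for t in names},
        source={},
        is_chimera={},
        chimera_parents={},
        template_inserts={t: a[fwd_len: len(a) - rvs_len] for t, a in templates},
    )

    reads: list[ReadPair] = []
    rl = spec.read_length
    for i, label in enumerate(labels):
        rid = f"read{i:07d}"
        if label == "\0chimera":
            ia, ib = rng.choice(len(names), size=2, replace=False,
                                p=list(spec.proportions)) if len(names) > 1 else (0, 0)
            a, b = amps[names[ia]], amps[names[ib]]
            L = min(len(a), len(b))
            klo = int(np.ceil(spec.chimera_breakpoint_band[0] * L))
            khi = int(np.floor(spec.chimera_breakpoint_band[1] * L))
            k = int(rng.integers(klo, khi + 1))
            amplicon = a[:k] + b[k:]
            truth.is_chimera[rid] = True
            truth.chimera_parents[rid] = (names[ia], names[ib])
            truth.source[rid] = ""
        else:
            amplicon = amps[label]
            truth.is_chimera[rid] = False
            truth.source[rid] = label
            truth.realized_counts[label] += 1
        s1 = amplicon[:rl]
        s2 = _revcomp(amplicon)[:rl]
        q1 = _quality_vector(rng, len(s1), spec)
        q2 = _quality_vector(rng, len(s2), spec)
        s1 = _apply_errors(s1, q1, spec, rng)
        s2 = _apply_errors(s2, q2, spec, rng)
        reads.append(ReadPair(id=rid, seq1=s1, qual1=q1, seq2=s2, qual2=q2,
                              group=spec.group))
    return reads, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _quality_vector(rng: np.random.Generator, length: int,
                    spec: CommunitySpec) -> list[int]:
    base = spec.quality_start - spec.quality_decay * np.arange(length)
    if spec.quality_jitter:
        base = base + rng.integers(-spec.quality_jitter,
                                   spec.quality_jitter + 1, size=length)
    return np.clip(np.rint(base), 2, 41).astype(int).tolist()


def _apply_errors(seq: str, quals: Sequence[int], spec: CommunitySpec,
                  rng: np.random.Generator) -> str:
    if spec.substitution_error_rate == 0.0:
        return seq
    w = np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    p = spec.substitution_error_rate * len(seq) * w / w.sum()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if not hits.size:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass
class RecoveryMetrics:
    haplotype_recall: float
    proportion_l1: float
    chimera_sensitivity: float | None
    chimera_false_flags: int
    n_chimeric_uniques: int


def evaluate_recovery(
    result: PipelineResult,
    truth: TruthTable,
    config: PipelineConfig,
    group: str = "all",
) -> RecoveryMetrics:
    """Compare a pipeline run against the simulator's truth table.

    Recall: planted templates matched by some representative at the
    representative-match identity.  L1: sum of |recovered - planted|
    proportion over planted taxa, plus any tabulated mass under names not
    matching a planted taxon.  Chimera sensitivity/false flags are judged
    at the unique-sequence level: a unique counts as chimeric when the
    majority of its member reads were planted chimeras (requires the run to
    have been traced; see ``run_pipeline(..., trace=True)``).
    """
    reps = result.representatives
    cutoff = 100.0 * config.rep_match_identity
    recovered = sum(
        1 for t in truth.taxa
        if any(pairwise_identity(truth.template_inserts[t], r.sequence) >= cutoff
               for r in reps)
    )
    recall = recovered / len(truth.taxa)

    percents = result.taxon_table.percents
    p_hat = (percents[group] / 100.0).to_dict() if group in percents else {}
    l1 = sum(abs(p_hat.get(t, 0.0) - truth.proportions[t]) for t in truth.taxa)
    l1 += sum(v for name, v in p_hat.items() if name not in _name_aliases(truth, reps))

    sens, false_flags, n_chim = _chimera_scores(result, truth, group)
    return RecoveryMetrics(
        haplotype_recall=recall,
        proportion_l1=l1,
        chimera_sensitivity=sens,
        chimera_false_flags=false_flags,
        n_chimeric_uniques=n_chim,
    )


def _name_aliases(truth: TruthTable, reps) -> set[str]:
    """Tabulated taxon names that correspond to a planted taxon."""
    aliases = set(truth.taxa)
    cutoff = 98.0
    for rep in reps:
        for t, insert in truth.template_inserts.items():
            if pairwise_identity(insert, rep.sequence) >= cutoff:
                aliases.add(rep.taxon.assigned_name)
    return aliases


def _chimera_scores(result: PipelineResult, truth: TruthTable, group: str):
    trace = result.insert_by_read.get(group)
    if trace is None:
        return None, 0, 0
    member_reads: dict[str, list[str]] = {}
    for rid, insert in trace.items():
        member_reads.setdefault(insert, []).append(rid)
    chimeric_inserts = {
        insert
        for insert, rids in member_reads.items()
        if sum(truth.is_chimera[r] for r in rids) * 2 > len(rids)
    }
    flagged = {u.insert for u in result.chimeras_by_group.get(group, [])}
    template_inserts = set(truth.template_inserts.values())
    false_flags = len(flagged & template_inserts)
    if not chimeric_inserts:
        return None, false_flags, 0
    sens = len(flagged & chimeric_inserts) / len(chimeric_inserts)
    return sens, false_flags, len(chimeric_inserts)
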