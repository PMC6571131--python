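"""Amplicon metabarcoding pipeline: paired reads to proportion tables.

Stages, in order, per sample group (groups are typically months of a
survey, but any label works):

1. quality trimming — truncate each mate at the first base below Q20 and
   drop mates shorter than 100 nt;
2. pair merging — overlap-align the mates (minimum 7 bp overlap) and build
   a quality-aware consensus;
3. size/primer screening — keep merged reads of the expected amplicon size
   whose termini match the primer pair exactly, and trim the primers off;
4. dereplication and chimera removal — collapse identical inserts, then
   flag single-breakpoint two-parent hybrids against more abundant
   sequences (UCHIME-style abundance skew prior);
5. clustering — greedy centroid clustering in abundance order, once at a
   strict identity (99.6%) to pick *representative haplotypes* (clusters
   holding >= 10% of a group's reads, taxonomically assigned and named
   "<taxon> Type k"), and once at 98% for tabulation;
6. assignment — identity thresholds against a reference database
   (>= 99% species, 90-99% genus, < 90% unidentified) and against the
   representative database (>= 98%, else "others"); clusters with fewer
   than two reads are dropped;
7. tabulation — per-group contig counts, percentages and haplotype counts.

Sequence identity is defined once for all stages: end-gap-free global
alignment identity (matches over aligned columns, terminal gap columns
excluded), in percent.  Every count a read-pair can end up in is tracked,
so the per-group ledger sums exactly to the input pair count.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .iupac import DegenerateSequence
from .primers import PrimerPair, ReferenceRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class PipelineConfig:
    """Every tunable cutoff of the pipeline, with the published defaults.

    Identity-type fields are fractions in (0, 1]; they are compared against
    percent identities internally.  ``size_window`` applies to the merged,
    primer-inclusive read.
    """

    q_min: int = 20
    len_min: int = 100
    min_overlap: int = 7
    size_window: tuple[int, int] = (465, 471)
    rep_cluster_identity: float = 0.996
    hap_cluster_identity: float = 0.98
    rep_min_proportion: float = 0.10
    species_identity: float = 0.99
    genus_identity_floor: float = 0.90
    rep_match_identity: float = 0.98
    min_contigs: int = 2
    chimera_abundance_skew: float = 2.0
    chimera_parent_identity: float = 0.995
    chimera_max_parents: int = 8
    chimera_satellite_identity: float = 0.996
    max_n_in_insert: int = 2
    merge_min_identity: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.genus_identity_floor < self.species_identity <= 1:
            raise ValueError("need 0 < genus_identity_floor < species_identity <= 1")
        if not self.rep_cluster_identity > self.hap_cluster_identity:
            raise ValueError("rep_cluster_identity must exceed hap_cluster_identity")
        if self.min_contigs < 1:
            raise ValueError("min_contigs must be >= 1")


@dataclass
class ReadPair:
    """One paired-end read with Phred quality vectors and a group label."""

    id: str
    seq1: str
    qual1: Sequence[int]
    seq2: str
    qual2: Sequence[int]
    group: str = "all"

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class UniqueSequence:
    """A dereplicated insert with per-group read (contig) counts."""

    insert: str
    abundance_by_group: dict[str, int] = field(default_factory=dict)

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance_by_group.values())


@dataclass
class HaplotypeCluster:
    """Greedy cluster: centroid (most abundant founder) plus members."""

    centroid: UniqueSequence
    members: list[UniqueSequence] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return self.centroid.total_abundance + sum(
            m.total_abundance for m in self.members
        )

    def abundance_in(self, group: str) -> int:
        n = self.centroid.abundance_by_group.get(group, 0)
        return n + sum(m.abundance_by_group.get(group, 0) for m in self.members)


@dataclass(frozen=True)
class Assignment:
    """Taxonomic call for one query against a reference database."""

    query_id: str
    top_hit_id: str
    identity: float  # percent
    category: str  # species | genus | unidentified | rep_match | others
    assigned_name: str


@dataclass(frozen=True)
class RepresentativeHaplotype:
    """An abundant cluster centroid promoted into the reference set."""

    name: str
    sequence: str
    taxon: Assignment
    type_index: int


# ---------------------------------------------------------------------------
# read-level stages


def quality_trim(
    seq: str, quals: Sequence[int], q_min: int = 20, len_min: int = 100
) -> tuple[str, Sequence[int]] | None:
    """Truncate at the first base below ``q_min``; drop if shorter than
    ``len_min`` afterwards.  Returns None for a discarded read."""
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    q = np.asarray(quals)
    below = np.nonzero(q < q_min)[0]
    cut = int(below[0]) if below.size else len(seq)
    if cut < len_min:
        return None
    return seq[:cut], quals[:cut]


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_read(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def merge_pair(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    min_overlap: int = 7,
    min_identity: float = 0.8,
) -> tuple[str, list[int]] | None:
    """Overlap-merge two mates into one consensus sequence.

    Mate 2 is reverse-complemented, then the overlap length maximizing the
    +1 match / -1 mismatch score is chosen among overlaps of at least
    ``min_overlap`` bases and at least ``min_identity`` identity.  In the
    overlap, agreeing bases keep the higher quality; disagreements keep the
    higher-quality base with quality ``|q1 - q2|``, or N (quality 2) on a
    tie.  Returns None when no qualifying overlap exists.
    """
    r2 = _revcomp_read(seq2)
    q2 = list(qual2)[::-1]
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(r2.encode(), dtype=np.uint8)
    best = None  # (score, overlap_len)
    for ov in range(min_overlap, min(len(a), len(b)) + 1):
        eq = a[len(a) - ov:] == b[:ov]
        matches = int(eq.sum())
        if matches < min_identity * ov:
            continue
        score = 2 * matches - ov
        if best is None or score > best[0]:
            best = (score, ov)
    if best is None:
        return None
    ov = best[1]
    off = len(seq1) - ov
    merged = list(seq1[:off])
    mq = list(qual1[:off])
    for i in range(ov):
        b1, b2 = seq1[off + i], r2[i]
        p1, p2 = qual1[off + i], q2[i]
        if b1 == b2:
            merged.append(b1)
            mq.append(max(p1, p2))
        elif p1 != p2:
            merged.append(b1 if p1 > p2 else b2)
            mq.append(abs(p1 - p2))
        else:
            merged.append("N")
            mq.append(2)
    merged_s = "".join(merged) + r2[ov:]
    mq.extend(q2[ov:])
    return merged_s, mq


@dataclass(frozen=True)
class ScreenResult:
    insert: str | None
    reason: str | None  # size | fwd_mismatch | rvs_mismatch | no_primer | excess_n

    @property
    def accepted(self) -> bool:
        return self.insert is not None


def primer_screen(
    merged: str,
    pair: PrimerPair,
    size_window: tuple[int, int] = (465, 471),
    max_n_in_insert: int = 2,
) -> ScreenResult:
    """Size-and-primer screen of a merged read; returns the trimmed insert.

    The read is accepted only if its length falls in ``size_window`` and
    both termini match the primers with zero mismatches under IUPAC
    semantics (orientation normalized by locating the forward primer at the
    5' end of either strand).  Inserts with more than ``max_n_in_insert``
    ambiguous bases are rejected as unresolved merge conflicts.
    """
    lo, hi = size_window
    if not lo <= len(merged) <= hi:
        return ScreenResult(None, "size")
    rvs_site = pair.rvs.revcomp().symbols
    fwd_len, rvs_len = len(pair.fwd), len(pair.rvs)
    for oriented in (merged, _revcomp_read(merged)):
        if pair.fwd.matches(oriented[:fwd_len]):
            tail = oriented[len(oriented) - rvs_len:]
            if not DegenerateSequence(rvs_site).matches(tail):
                return ScreenResult(None, "rvs_mismatch")
            insert = oriented[fwd_len: len(oriented) - rvs_len]
            if insert.count("N") > max_n_in_insert:
                return ScreenResult(None, "excess_n")
            return ScreenResult(insert, None)
    # forward primer found nowhere: distinguish a mismatched terminus from
    # a read that shows no primer structure at all
    for oriented in (merged, _revcomp_read(merged)):
        if DegenerateSequence(rvs_site).matches(oriented[len(oriented) - rvs_len:]):
            return ScreenResult(None, "fwd_mismatch")
    return ScreenResult(None, "no_primer")


def dereplicate(inserts: Iterable[tuple[str, str]]) -> list[UniqueSequence]:
    """Collapse identical inserts into :class:`UniqueSequence` records.

    Input is (insert, group) pairs; output is sorted by total abundance
    descending, then sequence lexicographically (deterministic).
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for insert, group in inserts:
        counts[insert][group] += 1
    uniques = [
        UniqueSequence(insert=s, abundance_by_group=dict(c))
        for s, c in counts.items()
    ]
    uniques.sort(key=lambda u: (-u.total_abundance, u.insert))
    return uniques


# ---------------------------------------------------------------------------
# identity


def _alignment_ops(a: str, b: str) -> list[tuple[int, str]]:
    res = edlib.align(a, b, task="path", mode="NW")
    return [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]


def identity_with_span(a: str, b: str) -> tuple[float, int]:
    """End-gap-free global alignment identity (percent) and aligned span.

    Matches over aligned columns, excluding terminal gap runs; internal
    gaps count as non-match columns.  Symmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 100.0, len(a)
    if a > b:  # canonical order: optimal alignments are not unique
        a, b = b, a
    ops = _alignment_ops(a, b)
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    columns = sum(n for n, _ in ops)
    if columns == 0:
        return 0.0, 0
    matches = sum(n for n, op in ops if op == "=")
    return 100.0 * matches / columns, columns


def pairwise_identity(a: str, b: str) -> float:
    """Percent sequence identity under the pipeline's single definition."""
    return identity_with_span(a, b)[0]


# ---------------------------------------------------------------------------
# chimera detection


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Per-query-position 0/1 match indicator against one parent.

    Built by projecting the global alignment onto query coordinates;
    parent-only columns (deletions from the query) are not charged to any
    query position.
    """
    out = np.zeros(len(query), dtype=np.int32)
    if query == parent:
        out[:] = 1
        return out
    qpos = 0
    for n, op in _alignment_ops(query, parent):
        if op == "=":
            out[qpos: qpos + n] = 1
            qpos += n
        elif op in ("X", "M"):
            qpos += n
        elif op == "I":  # query-only columns: mismatch positions
            qpos += n
        # 'D': parent-only, no query position consumed
    return out


def chimera_flag(
    query: UniqueSequence,
    pool: Sequence[UniqueSequence],
    config: PipelineConfig,
) -> tuple[bool, dict]:
    """Single-breakpoint two-parent chimera test against abundant sequences.

    Candidate parents must be at least ``chimera_abundance_skew`` times as
    abundant as the query (chimeras arise late in PCR, so parents outnumber
    them).  The query is flagged iff its best single-parent identity is
    below the species threshold while some parent-prefix + parent-suffix
    concatenation reconstructs it at an overall identity of at least
    ``chimera_parent_identity``.  The reconstruction identity is assessed
    over the whole query rather than per segment: a fixed per-segment
    fraction would allow zero mismatches on any segment shorter than
    1/(1 - threshold) bases, making the test unstable against a single
    sequencing error near the breakpoint.  Divergent-but-real sequences
    have no high-identity two-parent model and pass through.
    """
    skew = config.chimera_abundance_skew
    cands = [
        u for u in pool
        if u.insert != query.insert
        and u.total_abundance >= skew * query.total_abundance
    ]
    diag: dict = {"n_candidates": len(cands)}
    if len(cands) < 2:
        return False, diag
    scored = sorted(
        ((pairwise_identity(query.insert, c.insert), c) for c in cands),
        key=lambda t: -t[0],
    )
    best_single = scored[0][0]
    diag["best_single_identity"] = best_single
    if best_single >= 100.0 * config.species_identity:
        return False, diag
    # Shortlist candidate parents by identity, but require shortlisted
    # parents to come from distinct haplotypes (below the tabulation
    # clustering identity of each other): error satellites and
    # near-duplicates carry no new parental information and would crowd the
    # second true parent out of the list.
    div_cutoff = 100.0 * config.hap_cluster_identity
    top: list[UniqueSequence] = []
    for _, c in scored:
        if len(top) >= config.chimera_max_parents:
            break
        if any(pairwise_identity(c.insert, t.insert) >= div_cutoff for t in top):
            continue
        top.append(c)
    L = len(query.insert)
    budget = (1.0 - config.chimera_parent_identity) * L + 1e-9
    profiles = {
        id(c): np.concatenate(
            ([0], np.cumsum(_match_profile(query.insert, c.insert)))
        )
        for c in top
    }
    best_model = None  # (mismatches, breakpoint, pa, pb)
    for pa in top:
        cum_a = profiles[id(pa)]
        for pb in top:
            if pa is pb:
                continue
            cum_b = profiles[id(pb)]
            # mismatches of the model A[:k] + B[k:] against the query:
            # (k - cum_a[k]) + (L - k - (cum_b[L] - cum_b[k]))
            mm = L - cum_b[L] - cum_a + cum_b
            k = int(mm[1:L].argmin()) + 1
            mm_k = float(mm[k])
            if best_model is None or mm_k < best_model[0]:
                best_model = (mm_k, k, pa, pb)
    if best_model is not None and best_model[0] <= budget:
        diag.update(
            model_mismatches=best_model[0],
            breakpoint=best_model[1],
            parent_a=best_model[2].insert,
            parent_b=best_model[3].insert,
        )
        return True, diag
    return False, diag


def flag_chimeras(
    uniques: Sequence[UniqueSequence], config: PipelineConfig
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Partition uniques into (kept, flagged), processing in abundance order.

    Sequences already flagged as chimeric are excluded from later queries'
    candidate pools, so a chimera never serves as a parent.  A sequence
    within ``chimera_satellite_identity`` of an already-flagged, at least
    equally abundant chimera is flagged as its error satellite: that radius
    is the sequencing-error distance also used to collapse error variants
    into representative haplotypes, so such a sequence is almost surely an
    error copy of the chimera rather than an independent molecule.
    """
    ordered = sorted(uniques, key=lambda u: (-u.total_abundance, u.insert))
    sat_cutoff = 100.0 * config.chimera_satellite_identity
    kept: list[UniqueSequence] = []
    flagged: list[UniqueSequence] = []
    for u in ordered:
        if any(
            pairwise_identity(u.insert, f.insert) >= sat_cutoff for f in flagged
        ):
            flagged.append(u)
            continue
        is_chim, _ = chimera_flag(u, kept, config)
        (flagged if is_chim else kept).append(u)
    return kept, flagged


# ---------------------------------------------------------------------------
# clustering and assignment


def greedy_cluster(
    uniques: Sequence[UniqueSequence], identity_cutoff: float
) -> list[HaplotypeCluster]:
    """Greedy centroid clustering in input order.

    Each sequence joins the first existing centroid it matches at
    ``identity_cutoff`` (a fraction) or founds a new cluster; every new
    centroid is therefore below the cutoff against all earlier centroids at
    founding time.  Input should be dereplicated and abundance-sorted.
    """
    cutoff_pct = 100.0 * identity_cutoff
    clusters: list[HaplotypeCluster] = []
    for u in uniques:
        for cl in clusters:
            if pairwise_identity(u.insert, cl.centroid.insert) >= cutoff_pct:
                cl.members.append(u)
                break
        else:
            clusters.append(HaplotypeCluster(centroid=u))
    return clusters


def assign_taxonomy(
    seq: str,
    refdb: Sequence[ReferenceRecord],
    config: PipelineConfig,
    query_id: str = "query",
) -> Assignment:
    """Identity-threshold taxonomy call against a reference database.

    Top hit is the maximum-identity reference (ties: longer aligned span,
    then reference id ascending).  At or above the species threshold the
    query takes the hit's species name; between the genus floor and the
    species threshold it becomes "<Genus> sp."; below the floor it is
    "unidentified <Family>".
    """
    if not refdb:
        raise ValueError("empty reference database")
    if any(r.taxonomy is None for r in refdb):
        raise ValueError("all reference records need full taxonomy")
    best = None
    for ref in refdb:
        ident, span = identity_with_span(seq, ref.sequence)
        key = (-ident, -span, ref.id)
        if best is None or key < best[0]:
            best = (key, ident, ref)
    _, identity, ref = best
    if identity >= 100.0 * config.species_identity:
        category, name = "species", ref.species
    elif identity >= 100.0 * config.genus_identity_floor:
        category, name = "genus", f"{ref.genus} sp."
    else:
        category, name = "unidentified", f"unidentified {ref.family}"
    return Assignment(
        query_id=query_id,
        top_hit_id=ref.id,
        identity=identity,
        category=category,
        assigned_name=name,
    )


def select_representatives(
    clusters_by_group: Mapping[str, Sequence[HaplotypeCluster]],
    refdb: Sequence[ReferenceRecord],
    config: PipelineConfig,
) -> list[RepresentativeHaplotype]:
    """Pick, assign and name the representative haplotypes.

    Within each group, clusters holding at least ``rep_min_proportion`` of
    that group's reads qualify.  Qualifying centroids are deduplicated
    across groups at the strict clustering identity, assigned against the
    reference database, and numbered "Type k" per assigned taxon in
    descending abundance order.
    """
    selected: list[tuple[str, int]] = []  # (centroid insert, abundance)
    for group, clusters in clusters_by_group.items():
        total = sum(cl.abundance_in(group) for cl in clusters)
        if total == 0:
            continue
        for cl in clusters:
            n = cl.abundance_in(group)
            if n >= config.rep_min_proportion * total:
                selected.append((cl.centroid.insert, n))
    # cross-group dedup at the representative clustering identity
    selected.sort(key=lambda t: (-t[1], t[0]))
    cutoff = 100.0 * config.rep_cluster_identity
    deduped: list[list] = []  # [insert, abundance]
    for insert, n in selected:
        for entry in deduped:
            if pairwise_identity(insert, entry[0]) >= cutoff:
                entry[1] += n
                break
        else:
            deduped.append([insert, n])

    assigned = [
        (insert, n, assign_taxonomy(insert, refdb, config, query_id=f"rep{i}"))
        for i, (insert, n) in enumerate(deduped)
    ]
    by_taxon: dict[str, list] = defaultdict(list)
    for insert, n, asg in assigned:
        by_taxon[asg.assigned_name].append((insert, n, asg))
    reps: list[RepresentativeHaplotype] = []
    for taxon in sorted(by_taxon):
        entries = sorted(by_taxon[taxon], key=lambda t: (-t[1], t[0]))
        for k, (insert, _n, asg) in enumerate(entries, start=1):
            reps.append(
                RepresentativeHaplotype(
                    name=f"{taxon} Type {k}",
                    sequence=insert,
                    taxon=asg,
                    type_index=k,
                )
            )
    return reps


def match_representatives(
    clusters_by_group: Mapping[str, Sequence[HaplotypeCluster]],
    repdb: Sequence[RepresentativeHaplotype],
    config: PipelineConfig,
) -> tuple[dict[str, dict[str, int]], dict[str, dict[str, int]], dict[str, int]]:
    """Name each tabulation cluster after its representative, or "others".

    Clusters with fewer than ``min_contigs`` reads in a group are removed
    before tabulation.  Returns (contig counts, haplotype counts, removed
    read counts), each keyed by group.
    """
    counts: dict[str, dict[str, int]] = {}
    haps: dict[str, dict[str, int]] = {}
    removed: dict[str, int] = {}
    cutoff = 100.0 * config.rep_match_identity
    for group, clusters in clusters_by_group.items():
        gcounts: dict[str, int] = defaultdict(int)
        ghaps: dict[str, int] = defaultdict(int)
        dropped = 0
        for cl in clusters:
            n = cl.abundance_in(group)
            if n == 0:
                continue
            if n < config.min_contigs:
                dropped += n
                continue
            name = "others"
            best = -1.0
            for rep in repdb:
                ident = pairwise_identity(cl.centroid.insert, rep.sequence)
                if ident > best:
                    best = ident
                    name = rep.name if ident >= cutoff else "others"
            gcounts[name] += n
            ghaps[name] += 1
        counts[group] = dict(gcounts)
        haps[group] = dict(ghaps)
        removed[group] = dropped
    return counts, haps, removed


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class ProportionTable:
    """Per-group contig counts, percentages and haplotype counts.

    ``contigs`` and ``haplotypes`` are DataFrames indexed by row name
    (taxon or haplotype name) with one column per group; ``percents``
    derives from ``contigs`` column-wise.
    """

    contigs: pd.DataFrame
    haplotypes: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.contigs.columns)

    @property
    def totals(self) -> pd.Series:
        return self.contigs.sum(axis=0)

    @property
    def percents(self) -> pd.DataFrame:
        totals = self.totals.replace(0, np.nan)
        return (100.0 * self.contigs / totals).fillna(0.0)


def proportion_table(
    counts_by_group: Mapping[str, Mapping[str, int]],
    haplotypes_by_group: Mapping[str, Mapping[str, int]] | None = None,
) -> ProportionTable:
    """Assemble a :class:`ProportionTable` from per-group named counts.

    Rows are ordered by total contig count descending (then name); groups
    keep their input order.  Haplotype counts default to the number of
    distinct named rows contributing, i.e. 1 per non-zero cell, when not
    supplied.
    """
    groups = list(counts_by_group)
    if not groups:
        raise ValueError("no sample groups")
    names = sorted(
        {n for g in groups for n in counts_by_group[g]},
        key=lambda n: (-sum(counts_by_group[g].get(n, 0) for g in groups), n),
    )
    contigs = pd.DataFrame(
        {g: [counts_by_group[g].get(n, 0) for n in names] for g in groups},
        index=names,
        dtype=int,
    )
    if haplotypes_by_group is None:
        haplotypes = (contigs > 0).astype(int)
    else:
        haplotypes = pd.DataFrame(
            {g: [haplotypes_by_group[g].get(n, 0) for n in names] for g in groups},
            index=names,
            dtype=int,
        )
    return ProportionTable(contigs=contigs, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineResult:
    """Everything a run produces, plus the read-accounting ledger."""

    taxon_table: ProportionTable
    type_table: ProportionTable
    representatives: list[RepresentativeHaplotype]
    uniques_by_group: dict[str, list[UniqueSequence]]
    chimeras_by_group: dict[str, list[UniqueSequence]]
    ledger: dict[str, dict[str, int]]
    screen_reasons: dict[str, Counter]
    #: per group, read id -> screened insert (read-level trace)
    insert_by_read: dict[str, dict[str, str]] = field(default_factory=dict)

    def conservation_ok(self) -> bool:
        """Do the per-group ledger entries sum exactly to the input pairs?"""
        for group, lg in self.ledger.items():
            spent = (
                lg["qc_discarded"]
                + lg["unmerged"]
                + lg["primer_rejected"]
                + lg["chimeric"]
                + lg["low_abundance"]
                + lg["tabulated"]
            )
            if spent != lg["input_pairs"]:
                return False
        return True


def run_pipeline(
    read_pairs: Iterable[ReadPair],
    refdb: Sequence[ReferenceRecord],
    pair: PrimerPair,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on paired reads grouped by sample label."""
    config = config or PipelineConfig()
    inserts_by_group: dict[str, list[str]] = defaultdict(list)
    insert_by_read: dict[str, dict[str, str]] = defaultdict(dict)
    ledger: dict[str, dict[str, int]] = defaultdict(
        lambda: dict(
            input_pairs=0, qc_discarded=0, unmerged=0, primer_rejected=0,
            chimeric=0, low_abundance=0, tabulated=0,
        )
    )
    reasons: dict[str, Counter] = defaultdict(Counter)

    for rp in read_pairs:
        lg = ledger[rp.group]
        lg["input_pairs"] += 1
        t1 = quality_trim(rp.seq1, rp.qual1, config.q_min, config.len_min)
        t2 = quality_trim(rp.seq2, rp.qual2, config.q_min, config.len_min)
        if t1 is None or t2 is None:
            lg["qc_discarded"] += 1
            continue
        merged = merge_pair(
            t1[0], t1[1], t2[0], t2[1],
            min_overlap=config.min_overlap,
            min_identity=config.merge_min_identity,
        )
        if merged is None:
            lg["unmerged"] += 1
            continue
        screen = primer_screen(
            merged[0], pair, config.size_window, config.max_n_in_insert
        )
        if not screen.accepted:
            lg["primer_rejected"] += 1
            reasons[rp.group][screen.reason] += 1
            continue
        inserts_by_group[rp.group].append(screen.insert)
        insert_by_read[rp.group][rp.id] = screen.insert

    uniques_by_group: dict[str, list[UniqueSequence]] = {}
    chimeras_by_group: dict[str, list[UniqueSequence]] = {}
    rep_clusters: dict[str, list[HaplotypeCluster]] = {}
    hap_clusters: dict[str, list[HaplotypeCluster]] = {}
    for group, inserts in inserts_by_group.items():
        uniques = dereplicate((s, group) for s in inserts)
        kept, flagged = flag_chimeras(uniques, config)
        uniques_by_group[group] = kept
        chimeras_by_group[group] = flagged
        ledger[group]["chimeric"] = sum(u.total_abundance for u in flagged)
        rep_clusters[group] = greedy_cluster(kept, config.rep_cluster_identity)
        hap_clusters[group] = greedy_cluster(kept, config.hap_cluster_identity)

    repdb = select_representatives(rep_clusters, refdb, config)
    counts, haps, removed = match_representatives(hap_clusters, repdb, config)
    for group in counts:
        ledger[group]["low_abundance"] = removed[group]
        ledger[group]["tabulated"] = sum(counts[group].values())

    if counts:
        type_table = proportion_table(counts, haps)
        rep_taxon = {rep.name: rep.taxon.assigned_name for rep in repdb}
        taxon_counts = {g: _aggregate(counts[g], rep_taxon) for g in counts}
        taxon_haps = {g: _aggregate(haps[g], rep_taxon) for g in haps}
        taxon_table = proportion_table(taxon_counts, taxon_haps)
    else:  # every read filtered out: empty tables, ledger still balances
        empty = pd.DataFrame({g: [] for g in ledger}, dtype=int)
        type_table = ProportionTable(contigs=empty, haplotypes=empty.copy())
        taxon_table = ProportionTable(contigs=empty.copy(),
                                      haplotypes=empty.copy())
    return PipelineResult(
        taxon_table=taxon_table,
        type_table=type_table,
        representatives=repdb,
        uniques_by_group=uniques_by_group,
        chimeras_by_group=chimeras_by_group,
        ledger={g: dict(v) for g, v in ledger.items()},
        screen_reasons={g: Counter(c) for g, c in reasons.items()},
        insert_by_read={g: dict(v) for g, v in insert_by_read.items()},
    )


def _aggregate(named: Mapping[str, int], rep_taxon: Mapping[str, str]) -> dict[str, int]:
    out: dict[str, int] = defaultdict(int)
    for name, n in named.items():
        out[rep_taxon.get(name, name)] += n
    return dict(out)
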