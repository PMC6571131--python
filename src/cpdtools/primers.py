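"""Degenerate primer design and in-silico PCR over reference mitogenomes.

A taxon-specific degenerate primer pair is designed from a multiple
alignment of reference genomes: conserved windows are collapsed position-wise
to IUPAC consensus symbols, degeneracy is restricted to codon third (wobble)
positions, and the 3' terminus of each primer is kept fully conserved so the
polymerase extends from an exact match.  Candidate pairs are then validated
by predicting amplicons on each reference (in-silico PCR).

Coordinates are 0-based half-open on the plus strand throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .iupac import DegenerateSequence, collapse_to_iupac

GENOME_SCALE_MIN_LENGTH = 1_000
DEFAULT_MAX_PRODUCT_LENGTH = 5_000


@dataclass
class ReferenceRecord:
    """A reference sequence with taxonomy, the unit of in-silico PCR.

    ``taxonomy`` is a (family, genus, species) triple; records lacking it can
    still be amplified but cannot serve as a taxonomic reference database.
    ``circular`` marks circular molecules (mitogenomes), which are scanned
    across the origin.
    """

    id: str
    sequence: str
    taxonomy: tuple[str, str, str] | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")

    @property
    def family(self) -> str | None:
        return self.taxonomy[0] if self.taxonomy else None

    @property
    def genus(self) -> str | None:
        return self.taxonomy[1] if self.taxonomy else None

    @property
    def species(self) -> str | None:
        return self.taxonomy[2] if self.taxonomy else None


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, each written 5'->3' on its own strand."""

    fwd: DegenerateSequence
    rvs: DegenerateSequence
    name: str = "pair"

    def __post_init__(self) -> None:
        for label, primer in (("fwd", self.fwd), ("rvs", self.rvs)):
            if not 15 <= len(primer) <= 30:
                raise ValueError(
                    f"{label} primer length {len(primer)} outside [15, 30]"
                )

    @property
    def total_fold_degeneracy(self) -> int:
        return self.fwd.fold_degeneracy * self.rvs.fold_degeneracy

    @property
    def primer_span(self) -> int:
        """Total primer-derived bases in each amplicon."""
        return len(self.fwd) + len(self.rvs)


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product, primer-inclusive, plus-strand coordinates.

    For circular templates a hit may span the origin, in which case ``end``
    exceeds the template length and coordinates are understood modulo it.
    """

    ref_id: str
    start: int
    end: int
    mismatches_fwd: int
    mismatches_rvs: int
    product: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def insert(self, pair: PrimerPair) -> str:
        """The amplicon with both primer regions removed."""
        return self.product[len(pair.fwd): len(self.product) - len(pair.rvs)]


@dataclass
class DesignConstraints:
    """What a candidate primer pair must satisfy.

    ``codon_frame`` is the column index (modulo 3) of the first codon
    position in the alignment — the reading frame must be supplied by the
    caller, it is not inferred.  ``terminal_conserved_codons`` forces that
    many codons at each primer's 3' terminus to be degeneracy-free.
    """

    primer_length_range: tuple[int, int] = (15, 30)
    max_degenerate_positions: int = 5
    amplicon_length_range: tuple[int, int] = (400, 600)
    codon_frame_required: bool = True
    terminal_conserved_codons: int = 1
    codon_frame: int = 0

    def __post_init__(self) -> None:
        if self.primer_length_range[0] > self.primer_length_range[1]:
            raise ValueError("empty primer length range")
        if self.amplicon_length_range[0] > self.amplicon_length_range[1]:
            raise ValueError("empty amplicon length range")
        if self.max_degenerate_positions < 0:
            raise ValueError("max_degenerate_positions must be >= 0")


@dataclass(frozen=True)
class PrimerCandidate:
    """A ranked design result: the pair plus its alignment footprint."""

    pair: PrimerPair
    fwd_start: int
    rvs_end: int
    amplicon_length_range: tuple[int, int]


def consensus_site(site_sequences: list[str]) -> DegenerateSequence:
    """Position-wise IUPAC collapse of equal-length aligned site sequences.

    Gaps and N are ignored when collecting the observed base set of a
    column; a column with no concrete base at all is rejected.
    """
    if not site_sequences:
        raise ValueError("need at least one sequence")
    seqs = [s.upper().replace("U", "T") for s in site_sequences]
    length = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"sequence {i} has length {len(s)}, expected {length}"
            )
    symbols = []
    for col in range(length):
        observed = {s[col] for s in seqs} & set("ACGT")
        if not observed:
            raise ValueError(f"column {col} has no concrete base (all gap/N)")
        symbols.append(collapse_to_iupac(observed))
    return DegenerateSequence("".join(symbols))


def _window_ok(
    rows: list[str],
    start: int,
    length: int,
    constraints: DesignConstraints,
    three_prime: str,
    tally: Counter,
) -> DegenerateSequence | None:
    """Validate one alignment window as a primer site; count rejections.

    ``three_prime`` is "right" for a forward primer (3' end at the window's
    right edge) and "left" for a reverse primer.
    """
    window = [r[start: start + length] for r in rows]
    if any("-" in w for w in window):
        tally["gap"] += 1
        return None
    try:
        cons = consensus_site(window)
    except ValueError:
        tally["ambiguous"] += 1
        return None
    degenerate = [i for i, s in enumerate(cons.position_sets) if len(s) > 1]
    if len(degenerate) > constraints.max_degenerate_positions:
        tally["degeneracy"] += 1
        return None
    if constraints.codon_frame_required:
        for i in degenerate:
            if (start + i - constraints.codon_frame) % 3 != 2:
                tally["wobble_frame"] += 1
                return None
    n_term = 3 * constraints.terminal_conserved_codons
    if n_term:
        term = range(length - n_term, length) if three_prime == "right" else range(n_term)
        if any(i in term for i in degenerate):
            tally["terminal_codon"] += 1
            return None
    return cons


def scan_conserved_windows(
    rows: list[str],
    constraints: DesignConstraints,
    role: str = "fwd",
) -> tuple[list[tuple[int, int, DegenerateSequence]], Counter]:
    """All alignment windows usable as a primer site in the given role.

    Returns ``(windows, rejection_tally)`` where each window is
    ``(start_column, length, consensus)``.
    """
    if role not in ("fwd", "rvs"):
        raise ValueError("role must be 'fwd' or 'rvs'")
    three_prime = "right" if role == "fwd" else "left"
    n_cols = len(rows[0])
    if any(len(r) != n_cols for r in rows):
        raise ValueError("alignment rows differ in length")
    lo, hi = constraints.primer_length_range
    tally: Counter = Counter()
    out = []
    for length in range(lo, hi + 1):
        for start in range(n_cols - length + 1):
            cons = _window_ok(rows, start, length, constraints, three_prime, tally)
            if cons is not None:
                out.append((start, length, cons))
    return out, tally


def scan_primer_candidates(
    alignment: list[ReferenceRecord] | list[str],
    constraints: DesignConstraints,
) -> tuple[list[PrimerCandidate], Counter]:
    """Rank every primer pair satisfying the constraints on every row.

    Because each primer is the IUPAC collapse of its window, every returned
    pair matches every alignment row with zero mismatches by construction.
    Ranking is (total fold degeneracy asc, amplicon-length-range width asc,
    leftmost forward position asc, reverse position asc) — deterministic and
    invariant under row order.
    """
    rows = [
        r.sequence if isinstance(r, ReferenceRecord) else r.upper().replace("U", "T")
        for r in alignment
    ]
    fwd_windows, fwd_tally = scan_conserved_windows(rows, constraints, "fwd")
    rvs_windows, rvs_tally = scan_conserved_windows(rows, constraints, "rvs")
    tally = fwd_tally + rvs_tally

    # per-row cumulative ungapped lengths for O(1) amplicon sizing
    cums = []
    for row in rows:
        c = [0]
        for ch in row:
            c.append(c[-1] + (ch != "-"))
        cums.append(c)

    amp_lo, amp_hi = constraints.amplicon_length_range
    candidates = []
    for f_start, f_len, f_cons in fwd_windows:
        for r_start, r_len, r_cons in rvs_windows:
            if r_start < f_start + f_len:
                continue
            r_end = r_start + r_len
            lengths = [c[r_end] - c[f_start] for c in cums]
            lo_len, hi_len = min(lengths), max(lengths)
            if lo_len < amp_lo or hi_len > amp_hi:
                tally["amplicon_length"] += 1
                continue
            pair = PrimerPair(
                fwd=f_cons,
                rvs=r_cons.revcomp(),
                name=f"pair_c{f_start}_c{r_end}",
            )
            candidates.append(
                PrimerCandidate(pair, f_start, r_end, (lo_len, hi_len))
            )
    candidates.sort(
        key=lambda c: (
            c.pair.total_fold_degeneracy,
            c.amplicon_length_range[1] - c.amplicon_length_range[0],
            c.fwd_start,
            c.rvs_end,
            -(len(c.pair.fwd) + len(c.pair.rvs)),  # prefer the more specific primers
            c.pair.fwd.symbols,
            c.pair.rvs.symbols,
        )
    )
    return candidates, tally


def _scan_sites(seq: str, primer: DegenerateSequence, max_mismatch: int):
    """Yield (start, mismatches) of every primer match on one strand."""
    plen = len(primer)
    sets = primer.position_sets
    for start in range(len(seq) - plen + 1):
        mm = 0
        for s, base in zip(sets, seq[start: start + plen]):
            if base not in s:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            yield start, mm


def in_silico_pcr(
    ref: ReferenceRecord,
    pair: PrimerPair,
    max_mismatch_per_primer: int = 0,
    max_product_length: int = DEFAULT_MAX_PRODUCT_LENGTH,
) -> list[AmpliconHit]:
    """Predict every PCR product of a primer pair on one template.

    Both strands are searched and hits are normalized to plus-strand
    coordinates.  Matching is primer IUPAC symbol against template concrete
    base; template N never matches.  Circular templates are scanned across
    the origin by appending a ``max_product_length - 1`` prefix copy.
    Zero hits is a valid empty result.
    """
    genome = ref.sequence
    L = len(genome)
    if L < GENOME_SCALE_MIN_LENGTH:
        warnings.warn(
            f"record {ref.id}: length {L} is below genome scale "
            f"({GENOME_SCALE_MIN_LENGTH} nt)",
            stacklevel=2,
        )
    seq = genome + genome[: max_product_length - 1] if ref.circular else genome

    hits: dict[tuple[int, int, str], AmpliconHit] = {}

    def scan_strand(strand_seq: str, strand: str) -> None:
        rvs_site = pair.rvs.revcomp()  # reverse primer's binding site, plus orientation
        fwd_starts = list(_scan_sites(strand_seq, pair.fwd, max_mismatch_per_primer))
        rvs_starts = list(_scan_sites(strand_seq, rvs_site, max_mismatch_per_primer))
        for f_start, f_mm in fwd_starts:
            for r_start, r_mm in rvs_starts:
                r_end = r_start + len(rvs_site)
                if r_start < f_start + len(pair.fwd):
                    continue
                if r_end - f_start > max_product_length:
                    continue
                if strand == "+":
                    start, end = f_start, r_end
                    product = seq[start:end]
                else:  # map minus-strand coords back to plus strand
                    n = len(strand_seq)
                    start, end = n - r_end, n - f_start
                    product = strand_seq[f_start:r_end]
                key_start = start % L if ref.circular else start
                key = (key_start, end - start, strand)
                if key not in hits:
                    hits[key] = AmpliconHit(
                        ref_id=ref.id,
                        start=key_start,
                        end=key_start + (end - start),
                        mismatches_fwd=f_mm,
                        mismatches_rvs=r_mm,
                        product=product,
                        strand=strand,
                    )

    scan_strand(seq, "+")
    scan_strand(_revcomp_subject(seq), "-")
    return sorted(hits.values(), key=lambda h: (h.start, h.end, h.strand))


_SUBJECT_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


def _revcomp_subject(seq: str) -> str:
    """Reverse complement of a template; unknown symbols become N."""
    cleaned = "".join(c if c in "ACGTRYSWKMBDHVN" else "N" for c in seq)
    return cleaned.translate(_SUBJECT_COMPLEMENT)[::-1]
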