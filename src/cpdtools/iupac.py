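"""IUPAC-aware nucleotide primitives.

Degenerate primers are written in the 15-letter IUPAC nucleotide alphabet,
where each symbol stands for a non-empty subset of {A, C, G, T}.  Everything
else in the package (consensus building, in-silico PCR, primer screening)
reduces to the handful of set operations defined here.

Input is tolerant: lowercase letters are accepted and ``U`` is read as ``T``,
because public-database records mix conventions.  Internally everything is
uppercase DNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

#: IUPAC symbol -> set of concrete bases it stands for.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Exact inverse of :data:`IUPAC_TO_BASES`.
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Symbol-level complement table (complement of the base set, re-collapsed).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: BASES_TO_IUPAC[frozenset(_COMPLEMENT_BASE[b] for b in bases)]
    for code, bases in IUPAC_TO_BASES.items()
}


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA-style U to T."""
    return seq.upper().replace("U", "T")


def iupac_expand(code: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC symbol stands for.

    Raises ``ValueError`` naming the offending symbol for anything outside
    the 15-letter alphabet.
    """
    code = normalize(code)
    try:
        return IUPAC_TO_BASES[code]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol {code!r}") from None


def collapse_to_iupac(bases) -> str:
    """Collapse a non-empty set of concrete bases to the minimal IUPAC symbol.

    Exact inverse of :func:`iupac_expand`: the returned symbol expands to
    precisely the input set.
    """
    key = frozenset(normalize(b) for b in bases)
    if not key:
        raise ValueError("cannot collapse an empty base set")
    if not key <= frozenset("ACGT"):
        bad = sorted(key - frozenset("ACGT"))
        raise ValueError(f"non-concrete bases in set: {bad}")
    return BASES_TO_IUPAC[key]


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` is one of the concrete bases ``code`` stands for.

    The subject side (``base``) is a genome/read base: anything outside
    {A,C,G,T} — including N — is treated as a mismatch, since an unknown
    base is not evidence of primer binding.
    """
    base = normalize(base)
    if base not in _COMPLEMENT_BASE:
        return False
    return base in iupac_expand(code)


@dataclass(frozen=True)
class DegenerateSequence:
    """A nucleotide string over the IUPAC alphabet.

    Each position maps to a non-empty subset of {A,C,G,T}; the *fold
    degeneracy* is the number of distinct concrete sequences the string
    represents (product of per-position set sizes).
    """

    symbols: str

    def __post_init__(self) -> None:
        norm = normalize(self.symbols)
        if not norm:
            raise ValueError("empty sequence")
        for i, c in enumerate(norm):
            if c not in IUPAC_TO_BASES:
                raise ValueError(f"unknown IUPAC symbol {c!r} at position {i}")
        object.__setattr__(self, "symbols", norm)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    @property
    def position_sets(self) -> list[frozenset[str]]:
        return [IUPAC_TO_BASES[c] for c in self.symbols]

    @property
    def n_degenerate(self) -> int:
        """Count of positions standing for more than one base."""
        return sum(1 for s in self.position_sets if len(s) > 1)

    @property
    def fold_degeneracy(self) -> int:
        fold = 1
        for s in self.position_sets:
            fold *= len(s)
        return fold

    def expansions(self) -> Iterator[str]:
        """Yield every concrete sequence this degenerate string represents."""
        for combo in product(*(sorted(s) for s in self.position_sets)):
            yield "".join(combo)

    def revcomp(self) -> "DegenerateSequence":
        """Reverse complement, degenerate codes mapped to their complements.

        An involution: ``seq.revcomp().revcomp() == seq``.
        """
        return DegenerateSequence(
            "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.symbols))
        )

    def matches(self, subject: str, max_mismatch: int = 0) -> bool:
        """IUPAC-aware comparison against an equal-length concrete window."""
        return self.count_mismatches(subject, stop_after=max_mismatch + 1) <= max_mismatch

    def count_mismatches(self, subject: str, stop_after: int | None = None) -> int:
        """Number of subject positions not covered by the symbol's base set.

        ``stop_after`` allows early exit once that many mismatches are seen.
        """
        if len(subject) != len(self.symbols):
            raise ValueError("subject window length differs from primer length")
        mm = 0
        for code_set, base in zip(self.position_sets, subject):
            if base not in code_set:
                mm += 1
                if stop_after is not None and mm >= stop_after:
                    return mm
        return mm


def revcomp(seq: str | DegenerateSequence) -> str:
    """Reverse complement of an IUPAC string (string-in, string-out)."""
    if isinstance(seq, DegenerateSequence):
        return seq.revcomp().symbols
    return DegenerateSequence(seq).revcomp().symbols


def degeneracy_profile(primer: str | DegenerateSequence) -> tuple[int, int]:
    """(number of degenerate positions, fold degeneracy) of a primer."""
    if not isinstance(primer, DegenerateSequence):
        primer = DegenerateSequence(primer)
    return primer.n_degenerate, primer.fold_degeneracy
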