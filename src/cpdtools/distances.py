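"""Pairwise evolutionary distances and rank-level marker summaries.

The marker-comparison question is: does an amplicon region vary enough to
tell species apart?  Two standard measures are used — the uncorrected
p-distance (fraction of differing sites) and the Kimura two-parameter (K2P)
distance, which corrects for multiple hits while distinguishing transitions
(A<->G, C<->T, proportion P) from transversions (proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence has a gap or an ambiguous base are excluded
pairwise (pairwise deletion).  Summaries at a taxonomic rank average over
all unordered pairs of sequences belonging to *different* groups at that
rank (between-group distances); an all-pairs variant is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import edlib

_BASES = set("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class DistanceUndefinedError(ValueError):
    """Raised when a pairwise distance has no comparable sites or the K2P
    logarithm argument is non-positive (saturation)."""


@dataclass(frozen=True)
class PairwiseCounts:
    """Site counts behind one pairwise distance.

    ``p_transitions`` (P) and ``p_transversions`` (Q) are fractions of the
    compared sites; the p-distance is their sum.
    """

    sites_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def p_transitions(self) -> float:
        return self.n_transitions / self.sites_compared

    @property
    def p_transversions(self) -> float:
        return self.n_transversions / self.sites_compared

    @property
    def p_distance(self) -> float:
        return (self.n_transitions + self.n_transversions) / self.sites_compared


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two sequences, returned as gapped strings."""
    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def pairwise_counts(a: str, b: str, already_aligned: bool = False) -> PairwiseCounts:
    """Count transitions and transversions over comparable sites.

    Only columns where both symbols are concrete bases contribute
    (pairwise deletion of gaps, N and other ambiguity codes).  Symmetric in
    its arguments.  Raises :class:`DistanceUndefinedError` when no site is
    comparable, rather than silently reporting zero distance.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if not already_aligned:
        # canonicalize argument order: optimal alignments are not unique,
        # and symmetry must hold exactly
        if a > b:
            a, b = b, a
        a, b = align_pair(a, b)
    elif len(a) != len(b):
        raise ValueError("already_aligned sequences must have equal length")
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            sites += 1
            if x != y:
                if frozenset((x, y)) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if sites == 0:
        raise DistanceUndefinedError("no comparable sites between sequences")
    return PairwiseCounts(sites, ts, tv)


def k2p(counts: PairwiseCounts) -> float:
    """Kimura two-parameter distance from transition/transversion fractions.

    Undefined (saturated) when 1 - 2P - Q <= 0 or 1 - 2Q <= 0.  Always at
    least the p-distance, with equality only at zero divergence.
    """
    P, Q = counts.p_transitions, counts.p_transversions
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise DistanceUndefinedError(
            f"K2P saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(a: str, b: str, already_aligned: bool = False) -> float:
    return pairwise_counts(a, b, already_aligned).p_distance


def k2p_distance(a: str, b: str, already_aligned: bool = False) -> float:
    return k2p(pairwise_counts(a, b, already_aligned))


@dataclass(frozen=True)
class RankSummary:
    """Mean/max/min percent distance over contributing pairs at one rank."""

    rank: str
    model: str
    mean: float
    max: float
    min: float
    n_pairs: int
    n_undefined: int
    between_groups: bool = True


def rank_summary(
    sequences: Sequence[str],
    labels: Sequence[str],
    rank: str,
    model: str = "p",
    already_aligned: bool = False,
    between_groups: bool = True,
) -> RankSummary:
    """Summarize pairwise distances at a taxonomic rank.

    ``labels`` assigns each sequence its group at the requested rank.  With
    ``between_groups`` (default) only pairs from different groups
    contribute, mirroring a between-group mean distance; set it False for an
    all-pairs summary.  Pairs whose distance is undefined (saturation, no
    comparable sites) are excluded and counted in ``n_undefined``.
    """
    if model not in ("p", "k2p"):
        raise ValueError("model must be 'p' or 'k2p'")
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if between_groups and len(set(labels)) < 2:
        raise ValueError(f"need at least two groups at rank {rank!r}")
    values = []
    undefined = 0
    for i, j in combinations(range(len(sequences)), 2):
        if between_groups and labels[i] == labels[j]:
            continue
        try:
            counts = pairwise_counts(sequences[i], sequences[j], already_aligned)
            d = counts.p_distance if model == "p" else k2p(counts)
        except DistanceUndefinedError:
            undefined += 1
            continue
        values.append(d)
    if not values:
        raise DistanceUndefinedError("no defined pairwise distances at this rank")
    return RankSummary(
        rank=rank,
        model=model,
        mean=100.0 * sum(values) / len(values),
        max=100.0 * max(values),
        min=100.0 * min(values),
        n_pairs=len(values),
        n_undefined=undefined,
        between_groups=between_groups,
    )


def rank_summary_from_records(
    records,
    rank: str,
    model: str = "p",
    order_map: dict[str, str] | None = None,
    **kwargs,
) -> RankSummary:
    """Rank summary over :class:`~cpdtools.primers.ReferenceRecord` objects.

    ``rank`` is 'family' or 'genus' (taken from each record's taxonomy) or
    'order', which needs an explicit family->order mapping since record
    taxonomy stops at family.
    """
    seqs = [r.sequence for r in records]
    if rank == "family":
        labels = [r.family for r in records]
    elif rank == "genus":
        labels = [r.genus for r in records]
    elif rank == "order":
        if order_map is None:
            raise ValueError("rank 'order' requires an order_map (family -> order)")
        labels = [order_map[r.family] for r in records]
    else:
        raise ValueError(f"unknown rank {rank!r}")
    if any(lb is None for lb in labels):
        raise ValueError("every record needs taxonomy at the requested rank")
    return rank_summary(seqs, labels, rank, model, **kwargs)
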