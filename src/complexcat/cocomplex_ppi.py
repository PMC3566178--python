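"""Co-complex protein pairs and their overlap with reference PPI sets.

A catalogue's quality can be judged by how many of its co-complex pairs —
unordered pairs of proteins sharing at least one complex — also appear as
binary protein–protein interactions in independent PPI databases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

from .catalogue_builder import ProteinComplex

__all__ = ["PairOverlapReport", "cocomplex_pairs", "overlap_report", "canonical_pair"]

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair as a sorted 2-tuple; self-pairs are rejected."""
    if a == b:
        raise ValueError(f"self-pair ({a!r},{b!r}) is not a valid protein pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class PairOverlapReport:
    """Co-complex pair count plus per-reference overlap counts and ratios.

    ``ratio`` entries are percentages (100·overlap/co-complex pairs),
    reported at two-decimal precision.
    """

    n_cocomplex_pairs: int
    overlaps: Mapping[str, int]
    ratios: Mapping[str, float]

    @classmethod
    def from_counts(cls, n_pairs: int, overlaps: Mapping[str, int]) -> "PairOverlapReport":
        if n_pairs <= 0:
            raise ValueError("overlap ratio undefined for an empty co-complex pair set")
        ratios = {name: round(100.0 * k / n_pairs, 2) for name, k in overlaps.items()}
        return cls(n_pairs, dict(overlaps), ratios)


def cocomplex_pairs(complexes: Iterable[ProteinComplex]) -> set[Pair]:
    """Union of all unordered member pairs over the catalogue."""
    pairs: set[Pair] = set()
    for c in complexes:
        pairs.update(itertools.combinations(sorted(c.members), 2))
    return pairs


def overlap_report(
    pairs: set[Pair], references: Mapping[str, set[Pair]]
) -> PairOverlapReport:
    """Intersection counts and percentage ratios against each named reference."""
    overlaps = {name: len(pairs & ref) for name, ref in references.items()}
    return PairOverlapReport.from_counts(len(pairs), overlaps)
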