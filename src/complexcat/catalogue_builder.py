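"""Compilation of a non-redundant protein-complex catalogue.

Complexes pooled from several source databases are highly redundant: the
same biological unit appears repeatedly with slightly different member
lists.  Compilation ranks every complex by a significance score — the mean
GO biological-process semantic similarity over its member pairs — and then
scans the ranking once.  Whenever a lower-ranked complex overlaps a
retained one beyond the overlapping threshold (Jaccard), it is removed:
merged into the retained complex if the two are nearly identical (Jaccard
above the merging threshold), discarded otherwise, on the grounds that a
union of merely similar complexes would be an arbitrary unit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .go_semantics import AnnotationMap, GoDag, UndefinedSimilarity, gene_similarity

__all__ = [
    "ProteinComplex",
    "CompilationConfig",
    "CompilationResult",
    "jaccard",
    "complex_significance",
    "score_catalogue",
    "compile_catalogue",
    "count_redundancy",
    "catalogue_stats",
    "recovery_rate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinComplex:
    """A protein complex: an identifier, its source database and a member set."""

    id: str
    source: str
    members: frozenset[str]
    significance: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"complex {self.id!r} has an empty member set")
        if any(not m for m in self.members):
            raise ValueError(f"complex {self.id!r} contains an empty member symbol")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CompilationConfig:
    """Thresholds of the compilation scan.

    ``overlap_thres`` marks two complexes as redundant; ``merge_thres``
    (strictly larger) separates near-identical pairs, which are merged,
    from merely similar ones, where only the higher-scoring complex is
    kept.  ``grow_absorber`` controls whether later Jaccard comparisons use
    the merged (growing) member set or the original one.
    """

    overlap_thres: float = 0.5
    merge_thres: float = 0.8
    grow_absorber: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_thres < self.merge_thres < 1.0:
            raise ValueError(
                "need 0 < overlap_thres < merge_thres < 1, got "
                f"({self.overlap_thres}, {self.merge_thres})"
            )


@dataclass
class CompilationResult:
    retained: list[ProteinComplex]
    merged: list[tuple[str, str, float]] = field(default_factory=list)  # absorber, absorbed, J
    discarded: list[tuple[str, str, float]] = field(default_factory=list)  # keeper, discarded, J

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.merged) + len(self.discarded)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard coefficient |a∩b| / |a∪b| of two non-empty member sets."""
    if not a or not b:
        raise ValueError("Jaccard coefficient of an empty set is undefined")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def complex_significance(c: ProteinComplex, annot: AnnotationMap, dag: GoDag) -> float:
    """Mean pairwise gene semantic similarity over the complex members.

    Pairs involving an unannotated gene are excluded from the average (not
    scored 0), so sparsely annotated complexes are not penalised; the
    number of excluded pairs is logged.  Singletons and complexes with no
    defined pair score 0, which ranks them last in compilation.
    """
    vals: list[float] = []
    skipped = 0
    for g1, g2 in itertools.combinations(sorted(c.members), 2):
        try:
            vals.append(gene_similarity(annot, dag, g1, g2))
        except UndefinedSimilarity:
            skipped += 1
    if skipped:
        log.debug("complex %s: %d pair(s) excluded (unannotated gene)", c.id, skipped)
    if not vals:
        return 0.0
    return sum(vals) / len(vals)


def score_catalogue(
    complexes: list[ProteinComplex], annot: AnnotationMap, dag: GoDag
) -> list[ProteinComplex]:
    """Return the catalogue with significance filled in for every complex."""
    return [
        replace(c, significance=complex_significance(c, annot, dag)) for c in complexes
    ]


def _ranked(complexes: list[ProteinComplex]) -> list[ProteinComplex]:
    # stable, reproducible: score desc, then size desc, then id asc
    return sorted(complexes, key=lambda c: (-c.significance, -c.size, c.id))


def compile_catalogue(
    complexes: list[ProteinComplex], cfg: CompilationConfig = CompilationConfig()
) -> CompilationResult:
    """Single ranked scan that merges or discards redundant complexes.

    Complexes are ranked once by descending significance.  For each
    retained complex, every later complex whose Jaccard overlap exceeds
    ``cfg.overlap_thres`` is removed: absorbed (member union) when the
    overlap also exceeds ``cfg.merge_thres``, discarded otherwise.  By
    default absorbed members immediately extend the retainer for subsequent
    comparisons.  The output preserves the initial rank order.
    """
    for c in complexes:
        if c.significance is None:
            raise ValueError(f"complex {c.id!r} has no significance score; score first")
    order = _ranked(complexes)
    members: dict[str, frozenset[str]] = {c.id: c.members for c in order}
    removed: set[str] = set()
    result = CompilationResult(retained=[])
    for i, ci in enumerate(order):
        if ci.id in removed:
            continue
        compare_set = members[ci.id] if cfg.grow_absorber else ci.members
        for cj in order[i + 1 :]:
            if cj.id in removed:
                continue
            j = jaccard(compare_set, cj.members)
            if j > cfg.overlap_thres:
                removed.add(cj.id)
                if j > cfg.merge_thres:
                    members[ci.id] = members[ci.id] | cj.members
                    if cfg.grow_absorber:
                        compare_set = members[ci.id]
                    result.merged.append((ci.id, cj.id, j))
                else:
                    result.discarded.append((ci.id, cj.id, j))
        result.retained.append(replace(ci, members=members[ci.id]))
    return result


def count_redundancy(complexes: list[ProteinComplex], overlap_thres: float = 0.5) -> int:
    """Number of unordered complex pairs with Jaccard strictly above the threshold."""
    return sum(
        1
        for a, b in itertools.combinations(complexes, 2)
        if jaccard(a.members, b.members) > overlap_thres
    )


def catalogue_stats(complexes: list[ProteinComplex]) -> dict[str, float | int]:
    """Complex count, distinct proteins, overlapping proteins and mean size."""
    if not complexes:
        log.warning("empty catalogue: average size undefined, reported as 0")
        return {
            "n_complexes": 0,
            "n_proteins": 0,
            "n_overlapping_proteins": 0,
            "average_size": 0.0,
        }
    occurrence: dict[str, int] = {}
    for c in complexes:
        for m in c.members:
            occurrence[m] = occurrence.get(m, 0) + 1
    return {
        "n_complexes": len(complexes),
        "n_proteins": len(occurrence),
        "n_overlapping_proteins": sum(1 for n in occurrence.values() if n >= 2),
        "average_size": sum(c.size for c in complexes) / len(complexes),
    }


def recovery_rate(
    retained: list[ProteinComplex],
    truth: list[frozenset[str]],
    min_jaccard: float = 0.8,
) -> float:
    """Fraction of ground-truth member sets matched by a distinct retained complex.

    Each retained complex may account for at most one truth set (greedy
    best match), so duplicated retentions cannot inflate the rate.
    """
    if not truth:
        return 1.0
    available = {c.id: c.members for c in retained}
    hits = 0
    for t in truth:
        best_id, best_j = None, 0.0
        for cid, m in available.items():
            j = jaccard(m, t)
            if j > best_j:
                best_id, best_j = cid, j
        if best_id is not None and best_j >= min_jaccard:
            hits += 1
            del available[best_id]
    return hits / len(truth)
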