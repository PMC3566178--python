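"""Wang-style semantic similarity over a Gene Ontology DAG.

Each term's meaning is modelled by the weighted contribution (S-value) of
every ancestor term reached through ``is_a``/``part_of`` edges: the term
itself contributes 1, and each step toward the root multiplies the
contribution by an edge-type weight in (0, 1).  Two terms are similar to
the extent that their ancestor profiles share heavily-weighted terms, and
two genes are similar through a best-match average over their annotation
sets.  The biological-process sub-ontology is the intended input; the code
itself is agnostic to the namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GoDag",
    "TermAncestorProfile",
    "AnnotationMap",
    "ancestor_profile",
    "term_similarity",
    "gene_similarity",
    "UndefinedSimilarity",
]

#: canonical contribution weights of the Wang method
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class UndefinedSimilarity(ValueError):
    """Raised when a gene has no annotation, so its similarity is undefined."""


@dataclass(frozen=True)
class TermAncestorProfile:
    """S-values of a term and all its ancestors.

    ``s_values[t]`` is the semantic contribution of ancestor ``t`` to the
    target term; the target itself always has S-value 1.  ``sv`` is the
    semantic value of the term, the sum over the profile.
    """

    term: str
    s_values: Mapping[str, float]
    sv: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sv", float(sum(self.s_values.values())))


class GoDag:
    """A typed, acyclic child->parent term graph.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent, relation)`` triples; relation must be
        a key of ``weights``.
    terms
        Optional extra isolated terms (terms with no edges).
    weights
        Per-relation contribution weight, each strictly inside (0, 1).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]] = (),
        terms: Iterable[str] = (),
        weights: Mapping[str, float] | None = None,
    ) -> None:
        self.weights = dict(weights or DEFAULT_EDGE_WEIGHTS)
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"edge weight for {rel!r} must lie in (0,1), got {w}")
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel not in self.weights:
                raise ValueError(f"unknown edge relation {rel!r}")
            g.add_edge(child, parent, relation=rel, weight=self.weights[rel])
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"term graph contains a cycle: {cycle}")
        self._g = g
        self._profile = lru_cache(maxsize=None)(self._compute_profile)

    # -- introspection -----------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def terms(self) -> list[str]:
        return list(self._g.nodes)

    def parents(self, term: str) -> list[str]:
        return list(self._g.successors(term))

    def _require(self, term: str) -> None:
        if term not in self._g:
            raise KeyError(f"unknown term {term!r}")

    # -- S-value machinery -------------------------------------------------
    def _compute_profile(self, term: str) -> TermAncestorProfile:
        self._require(term)
        anc = nx.descendants(self._g, term) | {term}  # child->parent: "descendants" = ancestors
        sub = self._g.subgraph(anc)
        s: dict[str, float] = {term: 1.0}
        # children before parents within the ancestor closure
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            s[node] = max(
                sub.edges[c, node]["weight"] * s[c] for c in sub.predecessors(node)
            )
        return TermAncestorProfile(term, s)

    def ancestor_profile(self, term: str) -> TermAncestorProfile:
        """S-values of ``term`` and every ancestor, plus their sum SV."""
        return self._profile(term)

    def term_similarity(self, a: str, b: str) -> float:
        """Wang similarity between two terms, in [0, 1]."""
        pa, pb = self.ancestor_profile(a), self.ancestor_profile(b)
        common = pa.s_values.keys() & pb.s_values.keys()
        if not common:
            return 0.0
        shared = sum(pa.s_values[t] + pb.s_values[t] for t in common)
        return shared / (pa.sv + pb.sv)


class AnnotationMap:
    """Gene -> set of ontology term ids, validated against a DAG."""

    def __init__(self, mapping: Mapping[str, Iterable[str]], dag: GoDag) -> None:
        self._map: dict[str, frozenset[str]] = {}
        self.unannotated: set[str] = set()
        for gene, terms in mapping.items():
            ts = frozenset(terms)
            for t in ts:
                if t not in dag:
                    raise KeyError(f"annotation of {gene!r} uses unknown term {t!r}")
            if ts:
                self._map[gene] = ts
            else:
                self.unannotated.add(gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __len__(self) -> int:
        return len(self._map)

    def terms_of(self, gene: str) -> frozenset[str]:
        try:
            return self._map[gene]
        except KeyError:
            raise UndefinedSimilarity(f"gene {gene!r} has no annotation") from None

    def items(self):
        return self._map.items()

    def genes(self) -> list[str]:
        return list(self._map)


def ancestor_profile(dag: GoDag, term: str) -> TermAncestorProfile:
    return dag.ancestor_profile(term)


def term_similarity(dag: GoDag, a: str, b: str) -> float:
    return dag.term_similarity(a, b)


def gene_similarity(annot: AnnotationMap, dag: GoDag, g1: str, g2: str) -> float:
    """Best-match-average similarity between two genes' term sets.

    For every term of ``g1`` take the best similarity against ``g2``'s terms
    and vice versa; the result is the mean of the two directional averages.
    Raises :class:`UndefinedSimilarity` if either gene is unannotated.
    """
    t1, t2 = annot.terms_of(g1), annot.terms_of(g2)
    table = {(a, b): dag.term_similarity(a, b) for a in t1 for b in t2}
    fwd = sum(max(table[a, b] for b in t2) for a in t1) / len(t1)
    rev = sum(max(table[a, b] for a in t1) for b in t2) / len(t2)
    return 0.5 * (fwd + rev)
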