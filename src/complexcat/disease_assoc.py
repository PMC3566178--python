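"""Disease–complex association and drug-repositioning candidates.

Per-study disease–gene p-values are combined with Fisher's method; the
resulting disease gene sets are tested for enrichment in each complex of
the catalogue with a hypergeometric upper tail.  Significant associations
induce disease-specific complex–drug subnetworks, and every drug adjacent
to a significant complex becomes a repositioning candidate for that
disease.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

from .catalogue_builder import ProteinComplex
from .drug_network import DrugComplexNetwork

__all__ = [
    "DiseaseComplexAssociation",
    "RepositioningCandidate",
    "fisher_meta",
    "combine_evidence",
    "hypergeom_upper_tail",
    "disease_complex_enrichment",
    "significant_associations",
    "disease_subnetwork",
    "repositioning_candidates",
    "bh_adjust",
]

log = logging.getLogger(__name__)


def fisher_meta(pvals: Sequence[float]) -> float:
    """Fisher's method: −2Σln p against chi-square with 2k degrees of freedom.

    A single p-value is returned unchanged (the chi-square transform with
    two degrees of freedom is the identity).
    """
    if len(pvals) == 0:
        raise ValueError("need at least one p-value")
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0,1]")
    x2 = -2.0 * sum(math.log(p) for p in pvals)
    return float(stats.chi2.sf(x2, 2 * len(pvals)))


def combine_evidence(
    evidence: Iterable[tuple[str, str, float]],
    cutoff: float = 1e-5,
) -> dict[str, set[str]]:
    """Collapse (disease, gene, p) study records into disease gene sets.

    P-values of repeated (disease, gene) associations are combined with
    Fisher's method; only associations with combined p below ``cutoff``
    are kept.  The cutoff is a required, logged screening parameter.
    """
    per_pair: dict[tuple[str, str], list[float]] = {}
    for disease, gene, p in evidence:
        per_pair.setdefault((disease, gene), []).append(p)
    out: dict[str, set[str]] = {}
    kept = dropped = 0
    for (disease, gene), ps in per_pair.items():
        if fisher_meta(ps) < cutoff:
            out.setdefault(disease, set()).add(gene)
            kept += 1
        else:
            dropped += 1
    log.info("disease-gene screen at p<%g: kept %d, dropped %d", cutoff, kept, dropped)
    return out


@dataclass(frozen=True)
class DiseaseComplexAssociation:
    disease: str
    complex_id: str
    N: int  # universe size
    K: int  # disease proteins in universe
    n: int  # complex size
    t: int  # overlap
    p_value: float

    @property
    def significant_at(self) -> float:  # convenience echo of the conventional cut
        return 0.05


def hypergeom_upper_tail(N: int, K: int, n: int, t: int) -> float:
    """P(X >= t) for X ~ Hypergeom(N, K, n), including the observed overlap."""
    if t <= 0:
        return 1.0
    return float(stats.hypergeom.sf(t - 1, N, K, n))


def disease_complex_enrichment(
    catalogue: Sequence[ProteinComplex],
    disease_genes: set[str],
    universe: set[str] | None = None,
    disease: str = "",
) -> list[DiseaseComplexAssociation]:
    """Hypergeometric association of one disease gene set with every complex.

    The universe defaults to the set of all proteins in the catalogue;
    disease genes outside it are dropped with a warning.  Associations are
    returned sorted by ascending p-value.  The conventional significance
    rule is a raw p < 0.05 (see :func:`significant_associations`);
    :func:`bh_adjust` offers an optional multiple-testing correction.
    """
    if universe is None:
        universe = {m for c in catalogue for m in c.members}
    inside = disease_genes & universe
    outside = len(disease_genes) - len(inside)
    if outside:
        log.warning("%d disease gene(s) outside the universe dropped", outside)
    N, K = len(universe), len(inside)
    assocs = []
    for c in catalogue:
        members = c.members & universe
        t = len(members & inside)
        assocs.append(
            DiseaseComplexAssociation(
                disease=disease, complex_id=c.id, N=N, K=K, n=len(members), t=t,
                p_value=hypergeom_upper_tail(N, K, len(members), t),
            )
        )
    assocs.sort(key=lambda a: (a.p_value, a.complex_id))
    return assocs


def significant_associations(
    assocs: Sequence[DiseaseComplexAssociation], alpha: float = 0.05
) -> list[DiseaseComplexAssociation]:
    """Associations passing the raw p < alpha rule."""
    return [a for a in assocs if a.p_value < alpha]


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (optional; raw cut is the default)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(pvals), method="fdr_bh")[1])


def disease_subnetwork(
    disease: str,
    significant: Iterable[DiseaseComplexAssociation],
    net: DrugComplexNetwork,
) -> nx.Graph:
    """Induced complex–drug subgraph for one disease.

    Contains the disease node, every significantly associated complex
    (kept even if no drug reaches it) and every drug adjacent to one of
    those complexes.  Node attribute ``kind`` is one of ``disease``,
    ``complex``, ``drug``.
    """
    g = nx.Graph()
    g.add_node(disease, kind="disease")
    sig_ids = [a.complex_id for a in significant]
    drug_edges = {}
    for (drug, cid), support in net.edges.items():
        drug_edges.setdefault(cid, []).append((drug, support))
    for cid in sig_ids:
        g.add_node(cid, kind="complex")
        g.add_edge(disease, cid)
        for drug, support in drug_edges.get(cid, []):
            g.add_node(drug, kind="drug")
            g.add_edge(cid, drug, support=sorted(support))
    return g


@dataclass(frozen=True)
class RepositioningCandidate:
    disease: str
    drug: str
    supporting_complexes: tuple[str, ...]


def repositioning_candidates(
    subnetworks: Mapping[str, nx.Graph],
) -> list[RepositioningCandidate]:
    """One de-duplicated candidate per (disease, drug) adjacency.

    A drug in a disease-specific subnetwork is adjacent to at least one
    complex significantly associated with that disease; all such complexes
    are listed as support.
    """
    out: list[RepositioningCandidate] = []
    for disease, g in sorted(subnetworks.items()):
        drugs = [v for v, d in g.nodes(data=True) if d.get("kind") == "drug"]
        for drug in sorted(drugs):
            support = tuple(
                sorted(
                    c for c in g.neighbors(drug)
                    if g.nodes[c].get("kind") == "complex"
                )
            )
            if support:
                out.append(RepositioningCandidate(disease, drug, support))
    return out
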