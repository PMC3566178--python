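"""Seeded generators for every input of the catalogue pipeline.

Real inputs (complex databases, the GO biological-process DAG, PPI
networks, drug–target tables, GWAS disease genes) cannot be bundled, so
this module fabricates statistically analogous stand-ins with *planted*
structure: redundant perturbed copies of ground-truth complexes spread
over pseudo-source databases, gene annotations drawn from shared term
modules so that true complexes score high, a PPI network enriched for
co-complex edges, a heavy-tailed drug–target table, drug–drug interactions
enriched among co-complex drug pairs, and disease gene sets planted inside
chosen complexes.  Every planted answer is recorded in a manifest so
downstream assertions never have to re-derive ground truth.

All randomness flows from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np

from .catalogue_builder import ProteinComplex
from .cocomplex_ppi import Pair, cocomplex_pairs
from .drug_network import DrugComplexNetwork, build_network, cocomplex_drug_pairs
from .go_semantics import AnnotationMap, GoDag

__all__ = ["SyntheticConfig", "SyntheticBundle", "make_bundle",
           "make_go_dag", "make_true_complexes", "make_redundant_catalogue",
           "make_ppi", "make_pharmacology"]

_SOURCES = ("DBA", "DBB", "DBC")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults define the study conditions.

    The DAG/annotation block controls how strongly genes of one true
    complex share terms (hence how well significance separates real units
    from noise); the redundancy block mirrors the observed situation that
    complex databases contain many near-duplicate records; the
    pharmacology block plants drug–drug interactions among co-complex drug
    pairs at ``ddi_enrichment``-fold odds and one disease inside one
    complex each.
    """

    seed: int = 0
    # ontology / annotation
    n_terms: int = 150
    extra_edge_prob: float = 0.3
    part_of_prob: float = 0.25
    module_terms: int = 4
    terms_per_gene: int = 3
    stray_term_prob: float = 0.2
    # gene universe and true complexes
    n_genes: int = 800
    n_true_complexes: int = 100
    size_min: int = 5
    size_max: int = 9
    shared_member_prob: float = 0.15
    # redundancy
    redundancy_rate: float = 0.5
    max_copies: int = 3
    perturb_prob: float = 0.6
    jaccard_floor: float = 0.7
    # PPI
    ppi_p_in: float = 0.5
    ppi_p_bg: float = 0.01
    # pharmacology
    n_drugs: int = 150
    target_exponent: float = 2.5
    max_targets: int = 10
    n_ddis: int = 200
    ddi_enrichment: float = 4.0
    # disease
    n_diseases: int = 3
    leak_rate: float = 0.1
    disease_extra_genes: int = 10
    study_p_max: float = 1e-6

    def __post_init__(self) -> None:
        if self.size_min < 2 or self.size_max < self.size_min:
            raise ValueError("complex size range must be >= 2 and ordered")
        if not 0.0 <= self.redundancy_rate <= 1.0:
            raise ValueError("redundancy_rate must lie in [0,1]")
        if self.ppi_p_in <= self.ppi_p_bg:
            raise ValueError("co-complex PPI probability must exceed background")
        if self.ddi_enrichment < 1.0:
            raise ValueError("ddi_enrichment must be >= 1")


@dataclass
class SyntheticBundle:
    """All generated inputs plus the manifest of planted answers."""

    config: SyntheticConfig
    dag: GoDag
    annotations: AnnotationMap
    true_complexes: list[ProteinComplex]
    raw_catalogue: list[ProteinComplex]
    provenance: dict[str, str]  # raw complex id -> true complex id
    ppi: set[Pair]
    drug_targets: dict[str, frozenset[str]]
    ddis: set[Pair]
    disease_evidence: list[tuple[str, str, float]]
    disease_genes: dict[str, set[str]]
    planted_disease_complex: dict[str, str]  # disease -> true complex id
    manifest: dict = field(default_factory=dict)


def _gene(i: int) -> str:
    return f"G{i:04d}"


def _term(i: int) -> str:
    return f"T{i:04d}"


def make_go_dag(cfg: SyntheticConfig, rng: np.random.Generator) -> GoDag:
    """Rooted random DAG: a tree plus extra typed edges toward lower indices.

    Edges always point from a higher-index term to a lower one, which
    preserves acyclicity by construction.
    """
    if cfg.n_terms < 1:
        raise ValueError("need at least one term")
    edges: list[tuple[str, str, str]] = []
    for i in range(1, cfg.n_terms):
        parent = int(rng.integers(0, i))
        edges.append((_term(i), _term(parent), "is_a"))
        if i > 1 and rng.random() < cfg.extra_edge_prob:
            extra = int(rng.integers(0, i))
            if extra != parent:
                rel = "part_of" if rng.random() < cfg.part_of_prob else "is_a"
                edges.append((_term(i), _term(extra), rel))
    return GoDag(edges, terms=[_term(0)])


def make_true_complexes(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[ProteinComplex]:
    """Mostly disjoint ground-truth complexes carved out of the gene pool.

    A ``shared_member_prob`` chance per complex of adopting one member of
    another complex creates overlapping proteins without creating
    redundant pairs (the Jaccard overlap stays far below any threshold).
    """
    order = rng.permutation(cfg.n_genes)
    sizes = rng.integers(cfg.size_min, cfg.size_max + 1, size=cfg.n_true_complexes)
    if int(sizes.sum()) > cfg.n_genes:
        raise ValueError("gene pool too small for the requested complexes")
    out: list[ProteinComplex] = []
    pos = 0
    for k, size in enumerate(sizes):
        members = {_gene(int(g)) for g in order[pos : pos + int(size)]}
        pos += int(size)
        out.append(ProteinComplex(f"TRUE{k:03d}", "truth", frozenset(members)))
    # adopt shared members to create overlapping proteins
    final: list[ProteinComplex] = []
    for c in out:
        members = set(c.members)
        if len(out) > 1 and rng.random() < cfg.shared_member_prob:
            other = out[int(rng.integers(0, len(out)))]
            if other.id != c.id:
                members.add(sorted(other.members)[int(rng.integers(0, other.size))])
        final.append(ProteinComplex(c.id, c.source, frozenset(members)))
    return final


def make_annotations(
    cfg: SyntheticConfig,
    dag: GoDag,
    true_complexes: list[ProteinComplex],
    rng: np.random.Generator,
) -> AnnotationMap:
    """Annotate genes so that members of one complex share a term module."""
    terms = sorted(dag.terms)
    mapping: dict[str, set[str]] = {_gene(i): set() for i in range(cfg.n_genes)}
    for c in true_complexes:
        module = rng.choice(len(terms), size=min(cfg.module_terms, len(terms)),
                            replace=False)
        module_terms = [terms[int(i)] for i in module]
        for g in sorted(c.members):
            take = rng.choice(len(module_terms),
                              size=min(cfg.terms_per_gene, len(module_terms)),
                              replace=False)
            mapping[g].update(module_terms[int(i)] for i in take)
            if rng.random() < cfg.stray_term_prob:
                mapping[g].add(terms[int(rng.integers(0, len(terms)))])
    for g, ts in mapping.items():
        if not ts:  # background gene: random annotation
            take = rng.choice(len(terms), size=min(cfg.terms_per_gene, len(terms)),
                              replace=False)
            ts.update(terms[int(i)] for i in take)
    return AnnotationMap(mapping, dag)


def make_redundant_catalogue(
    cfg: SyntheticConfig,
    true_complexes: list[ProteinComplex],
    rng: np.random.Generator,
) -> tuple[list[ProteinComplex], dict[str, str]]:
    """Raw catalogue: one primary record per true complex plus perturbed copies.

    A fraction ``redundancy_rate`` of complexes emits 1–``max_copies``
    extra copies under pseudo-source names; each copy is perturbed by at
    most one member (add or remove, probability ``perturb_prob``), and a
    perturbation that would drop the copy's Jaccard to its original below
    ``jaccard_floor`` is rejected in favour of an exact copy.
    """
    raw: list[ProteinComplex] = []
    provenance: dict[str, str] = {}
    counter = itertools.count()
    all_genes = [_gene(i) for i in range(cfg.n_genes)]
    for c in true_complexes:
        rid = f"RAW{next(counter):04d}"
        raw.append(ProteinComplex(rid, _SOURCES[0], c.members))
        provenance[rid] = c.id
        if rng.random() >= cfg.redundancy_rate:
            continue
        for _ in range(int(rng.integers(1, cfg.max_copies + 1))):
            members = set(c.members)
            if rng.random() < cfg.perturb_prob:
                if rng.random() < 0.5 and len(members) > 2:
                    members.discard(sorted(members)[int(rng.integers(0, len(members)))])
                else:
                    members.add(all_genes[int(rng.integers(0, len(all_genes)))])
                inter = len(members & c.members)
                union = len(members | c.members)
                if inter / union < cfg.jaccard_floor:
                    members = set(c.members)
            rid = f"RAW{next(counter):04d}"
            src = _SOURCES[int(rng.integers(1, len(_SOURCES)))]
            raw.append(ProteinComplex(rid, src, frozenset(members)))
            provenance[rid] = c.id
    return raw, provenance


def _decode_pairs(codes: np.ndarray, names: list[str], n: int) -> set[Pair]:
    out = set()
    for code in codes:
        i, j = divmod(int(code), n)
        a, b = names[i], names[j]
        out.add((a, b) if a < b else (b, a))
    return out


def make_ppi(
    cfg: SyntheticConfig,
    true_complexes: list[ProteinComplex],
    rng: np.random.Generator,
) -> set[Pair]:
    """PPI pair set: co-complex pairs at ``ppi_p_in``, background at ``ppi_p_bg``."""
    cc = sorted(cocomplex_pairs(true_complexes))
    keep = rng.random(len(cc)) < cfg.ppi_p_in
    ppi = {p for p, k in zip(cc, keep) if k}
    genes = [_gene(i) for i in range(cfg.n_genes)]
    n = len(genes)
    total = n * (n - 1) // 2
    n_bg = int(rng.binomial(total, cfg.ppi_p_bg))
    ii, jj = np.triu_indices(n, k=1)
    sel = rng.choice(total, size=min(n_bg, total), replace=False)
    codes = ii[sel].astype(np.int64) * n + jj[sel]
    cc_set = set(cc)
    ppi |= {p for p in _decode_pairs(codes, genes, n) if p not in cc_set}
    return ppi


def make_pharmacology(
    cfg: SyntheticConfig,
    catalogue: list[ProteinComplex],
    rng: np.random.Generator,
) -> tuple[dict[str, frozenset[str]], set[Pair], DrugComplexNetwork]:
    """Heavy-tailed drug–target table and enriched drug–drug interactions.

    Target counts per drug follow a zeta law truncated at ``max_targets``
    (drug–complex networks are near scale-free); interactions are sampled
    without replacement with ``ddi_enrichment``-fold weight on co-complex
    drug pairs.
    """
    proteins = sorted({m for c in catalogue for m in c.members})
    targets: dict[str, frozenset[str]] = {}
    for d in range(cfg.n_drugs):
        k = min(int(rng.zipf(cfg.target_exponent)), cfg.max_targets, len(proteins))
        picks = rng.choice(len(proteins), size=k, replace=False)
        targets[f"DRUG{d:03d}"] = frozenset(proteins[int(i)] for i in picks)
    net = build_network(catalogue, targets)
    pool = sorted(net.drugs)
    n = len(pool)
    total = n * (n - 1) // 2
    if total < cfg.n_ddis:
        raise ValueError("too few connected drugs to draw the requested interactions")
    cc = cocomplex_drug_pairs(net)
    ii, jj = np.triu_indices(n, k=1)
    weights = np.ones(total)
    idx = {d: i for i, d in enumerate(pool)}
    cc_codes = {idx[a] * n + idx[b] for a, b in cc}
    codes = ii.astype(np.int64) * n + jj
    weights[np.fromiter((c in cc_codes for c in codes), bool, total)] = cfg.ddi_enrichment
    # Gumbel top-k = weighted sampling without replacement
    keys = np.log(weights) + rng.gumbel(size=total)
    top = np.argpartition(-keys, cfg.n_ddis)[: cfg.n_ddis]
    ddis = _decode_pairs(codes[top], pool, n)
    return targets, ddis, net


def make_diseases(
    cfg: SyntheticConfig,
    true_complexes: list[ProteinComplex],
    rng: np.random.Generator,
) -> tuple[dict[str, set[str]], dict[str, str], list[tuple[str, str, float]]]:
    """Disease gene sets planted inside chosen complexes, with study p-values."""
    picks = rng.choice(len(true_complexes), size=cfg.n_diseases, replace=False)
    genes_all = [_gene(i) for i in range(cfg.n_genes)]
    disease_genes: dict[str, set[str]] = {}
    planted: dict[str, str] = {}
    evidence: list[tuple[str, str, float]] = []
    for d, ci in enumerate(picks):
        disease = f"DIS{d:02d}"
        cpx = true_complexes[int(ci)]
        planted[disease] = cpx.id
        gset = {g for g in sorted(cpx.members) if rng.random() >= cfg.leak_rate}
        extra = rng.choice(cfg.n_genes, size=cfg.disease_extra_genes, replace=False)
        gset |= {genes_all[int(i)] for i in extra}
        disease_genes[disease] = gset
        for g in sorted(gset):
            for _ in range(int(rng.integers(1, 3))):
                evidence.append(
                    (disease, g, float(cfg.study_p_max * rng.random())))
    return disease_genes, planted, evidence


def make_bundle(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate the complete input bundle for one seed."""
    if cfg is None:
        cfg = SyntheticConfig(**overrides)
    elif overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    dag = make_go_dag(cfg, rng)
    truth = make_true_complexes(cfg, rng)
    annot = make_annotations(cfg, dag, truth, rng)
    raw, provenance = make_redundant_catalogue(cfg, truth, rng)
    ppi = make_ppi(cfg, truth, rng)
    targets, ddis, _net = make_pharmacology(cfg, truth, rng)
    disease_genes, planted, evidence = make_diseases(cfg, truth, rng)
    manifest = {
        "seed": cfg.seed,
        "true_complexes": {c.id: sorted(c.members) for c in truth},
        "provenance": provenance,
        "planted_disease_complex": planted,
        "n_raw_complexes": len(raw),
        "n_ppi_pairs": len(ppi),
        "n_drugs": len(targets),
        "n_ddis": len(ddis),
    }
    return SyntheticBundle(
        config=cfg,
        dag=dag,
        annotations=annot,
        true_complexes=truth,
        raw_catalogue=raw,
        provenance=provenance,
        ppi=ppi,
        drug_targets=targets,
        ddis=ddis,
        disease_evidence=evidence,
        disease_genes=disease_genes,
        planted_disease_complex=planted,
        manifest=manifest,
    )
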