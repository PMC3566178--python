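"""Bipartite drug–complex networks and drug-related statistics.

A drug is linked to every complex containing at least one of its targets;
each edge carries the supporting target proteins.  On top of this network
the module computes hub/degree tables with and without repeat removal,
co-complex drug pairs, a permutation test asking whether known drug–drug
interactions concentrate among co-complex drug pairs, and a binomial test
for the druggability of overlapping proteins.

Repeat removal addresses over-counting: if three complexes share one
protein targeted by a drug, the raw tables count the drug three times
(three edges) and the target three times; de-duplicated tables count each
(drug, target) relationship once, regardless of how many complexes carry
it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue_builder import ProteinComplex
from .cocomplex_ppi import Pair, canonical_pair

__all__ = [
    "DrugComplexNetwork",
    "DruggabilityReport",
    "DdiPermutationResult",
    "build_network",
    "degree_report",
    "cocomplex_drug_pairs",
    "ddi_permutation_test",
    "druggability_test",
    "binomial_druggability",
]


@dataclass(frozen=True)
class DrugComplexNetwork:
    """Drug and complex node sets plus edges annotated with supporting targets."""

    drugs: frozenset[str]
    complexes: frozenset[str]
    edges: Mapping[tuple[str, str], frozenset[str]]  # (drug, complex_id) -> targets
    complex_members: Mapping[str, frozenset[str]]
    drug_targets: Mapping[str, frozenset[str]]  # full target table, incl. isolated drugs

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(
    catalogue: Iterable[ProteinComplex], targets: Mapping[str, Iterable[str]]
) -> DrugComplexNetwork:
    """Link every drug to every complex containing at least one of its targets."""
    member_index: dict[str, frozenset[str]] = {}
    protein_to_complexes: dict[str, set[str]] = {}
    for c in catalogue:
        member_index[c.id] = c.members
        for m in c.members:
            protein_to_complexes.setdefault(m, set()).add(c.id)

    edges: dict[tuple[str, str], set[str]] = {}
    table: dict[str, frozenset[str]] = {}
    for drug, ts in targets.items():
        tset = frozenset(ts)
        if not tset:
            raise ValueError(f"drug {drug!r} has an empty target set")
        table[drug] = tset
        for t in tset:
            for cid in protein_to_complexes.get(t, ()):
                edges.setdefault((drug, cid), set()).add(t)

    drugs = frozenset(d for d, _ in edges)
    cids = frozenset(c for _, c in edges)
    return DrugComplexNetwork(
        drugs=drugs,
        complexes=cids,
        edges={k: frozenset(v) for k, v in edges.items()},
        complex_members=member_index,
        drug_targets=table,
    )


def degree_report(net: DrugComplexNetwork, dedup: bool = False) -> dict[str, pd.DataFrame]:
    """Ranked drug degrees, complex degrees and target usage counts.

    Raw mode counts edges: a drug's degree is its number of incident
    edges, and a target is "used" once per edge whose support contains it.
    De-duplicated mode counts relationships once: a drug's degree is its
    number of distinct targets found in at least one complex, and a
    target's usage is the number of distinct drugs that target it (among
    targets present in at least one complex).
    """
    drug_deg: dict[str, int] = {}
    cplx_deg: dict[str, int] = {}
    usage: dict[str, int] = {}
    if dedup:
        for drug in net.drugs:
            in_complex = {
                t for (d, _), sup in net.edges.items() if d == drug for t in sup
            }
            drug_deg[drug] = len(in_complex)
            for t in in_complex:
                usage[t] = usage.get(t, 0) + 1
    else:
        for (drug, cid), support in net.edges.items():
            drug_deg[drug] = drug_deg.get(drug, 0) + 1
            cplx_deg[cid] = cplx_deg.get(cid, 0) + 1
            for t in support:
                usage[t] = usage.get(t, 0) + 1

    def _frame(d: dict[str, int], key: str, value: str) -> pd.DataFrame:
        df = pd.DataFrame(sorted(d.items(), key=lambda kv: (-kv[1], kv[0])),
                          columns=[key, value])
        return df

    out = {
        "drugs": _frame(drug_deg, "drug", "degree"),
        "targets": _frame(usage, "target", "times_used"),
    }
    if not dedup:
        out["complexes"] = _frame(cplx_deg, "complex_id", "degree")
    return out


def cocomplex_drug_pairs(net: DrugComplexNetwork) -> set[Pair]:
    """Unordered pairs of distinct drugs adjacent to at least one common complex."""
    by_complex: dict[str, set[str]] = {}
    for (drug, cid) in net.edges:
        by_complex.setdefault(cid, set()).add(drug)
    pairs: set[Pair] = set()
    for drugs in by_complex.values():
        pairs.update(itertools.combinations(sorted(drugs), 2))
    return pairs


@dataclass(frozen=True)
class DdiPermutationResult:
    n_ddi_pairs: int
    observed_cocomplex: int
    replicates: np.ndarray
    null_mean: float
    p_value: float


def ddi_permutation_test(
    net: DrugComplexNetwork,
    ddis: set[Pair],
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    universe: str = "network",
) -> DdiPermutationResult:
    """Permutation test: do known drug–drug interactions share complexes?

    The observed statistic is the number of interaction pairs that are
    co-complex drug pairs.  Each replicate draws the same number of
    distinct unordered drug pairs uniformly from the universe (by default
    drugs with at least one network edge; ``universe="all"`` uses every
    drug in the target table) and counts co-complex pairs among them.
    Interaction pairs whose drugs fall outside the universe are excluded.
    The empirical p-value is (1 + #{replicate ≥ observed}) / (reps + 1).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pool = sorted(net.drugs if universe == "network" else net.drug_targets)
    in_pool = set(pool)
    kept = {p for p in ddis if p[0] in in_pool and p[1] in in_pool}
    cc = cocomplex_drug_pairs(net)
    observed = len(kept & cc)
    m = len(kept)
    if m == 0:
        return DdiPermutationResult(0, 0, np.zeros(reps, dtype=int), 0.0, 1.0)
    n = len(pool)
    total = n * (n - 1) // 2
    if total < m:
        raise ValueError(f"universe of {n} drugs cannot yield {m} distinct pairs")

    idx = {d: i for i, d in enumerate(pool)}
    ii, jj = np.triu_indices(n, k=1)
    codes = ii.astype(np.int64) * n + jj
    cc_codes = np.sort(
        np.array(
            [idx[a] * n + idx[b] for a, b in cc if a in idx and b in idx],
            dtype=np.int64,
        )
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        sel = rng.choice(total, size=m, replace=False)
        counts[r] = np.isin(codes[sel], cc_codes, assume_unique=False).sum()
    p = (1 + int((counts >= observed).sum())) / (reps + 1)
    return DdiPermutationResult(m, observed, counts, float(counts.mean()), p)


@dataclass(frozen=True)
class DruggabilityReport:
    n_targets: int
    n_potential_targets: int
    n_druggable: int
    n_overlapping_nodes: int
    ratio: float
    p0: float
    p_value: float


def binomial_druggability(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial probability P(X >= k | n, p0)."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("baseline probability p0 must lie in (0,1)")
    return float(stats.binom.sf(k - 1, n, p0))


def druggability_test(
    catalogue: Iterable[ProteinComplex],
    established_targets: set[str],
    potential_targets: set[str] = frozenset(),
    p0: float = 2500 / 20500,
) -> DruggabilityReport:
    """Druggability enrichment of overlapping proteins.

    Overlapping proteins belong to two or more complexes; the druggable set
    is the union of established drug targets and potential druggable-family
    members.  The one-sided binomial test compares the observed druggable
    fraction against the genome-wide baseline ``p0`` (default 2500/20500,
    roughly 2000–3000 druggable proteins over ~20500 protein-coding genes).
    """
    occurrence: dict[str, int] = {}
    for c in catalogue:
        for m in c.members:
            occurrence[m] = occurrence.get(m, 0) + 1
    overlapping = {g for g, cnt in occurrence.items() if cnt >= 2}
    if not overlapping:
        raise ValueError("catalogue has no overlapping proteins; ratio undefined")
    druggable = (set(established_targets) | set(potential_targets)) & overlapping
    n, k = len(overlapping), len(druggable)
    return DruggabilityReport(
        n_targets=len(set(established_targets) & overlapping),
        n_potential_targets=len(set(potential_targets) & overlapping - set(established_targets)),
        n_druggable=k,
        n_overlapping_nodes=n,
        ratio=k / n,
        p0=p0,
        p_value=binomial_druggability(k, n, p0),
    )
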