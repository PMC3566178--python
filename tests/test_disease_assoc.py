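"""Fisher's method, hypergeometric enrichment and repositioning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexcat import (
    ProteinComplex,
    build_network,
    disease_complex_enrichment,
    disease_subnetwork,
    fisher_meta,
    hypergeom_upper_tail,
    repositioning_candidates,
    significant_associations,
)
from complexcat.disease_assoc import combine_evidence


def cx(cid, members):
    return ProteinComplex(cid, "db", frozenset(members))


def fisher_series_oracle(pvals):
    """Closed-form Fisher combination: q·Σ_{i<k}(−ln q)^i / i!, q = Πp."""
    q = math.prod(pvals)
    if q == 0:
        return 0.0
    lnq = -math.log(q)
    return q * sum(lnq**i / math.factorial(i) for i in range(len(pvals)))


class TestFisherMeta:
    def test_single_value_is_identity(self):
        assert fisher_meta([0.03]) == pytest.approx(0.03, rel=1e-12)

    def test_all_ones_combine_to_one(self):
        assert fisher_meta([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_moderate_values(self):
        got = fisher_meta([0.05, 0.05])
        assert got == pytest.approx(fisher_series_oracle([0.05, 0.05]), rel=1e-10)
        assert got == pytest.approx(0.0175, abs=5e-4)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            fisher_meta([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_meta([])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_series_oracle_and_is_permutation_invariant(self, ps):
        got = fisher_meta(ps)
        assert got == pytest.approx(fisher_series_oracle(ps), rel=1e-9, abs=1e-12)
        assert fisher_meta(list(reversed(ps))) == pytest.approx(got, rel=1e-12)

    @given(st.lists(st.floats(1e-4, 1.0), min_size=2, max_size=5), st.integers(0, 4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_input(self, ps, i):
        i = i % len(ps)
        lowered = list(ps)
        lowered[i] = ps[i] / 2
        assert fisher_meta(lowered) <= fisher_meta(ps) + 1e-12


class TestCombineEvidence:
    def test_repeated_associations_are_combined(self):
        ev = [("d", "g", 1e-4), ("d", "g", 1e-4), ("d", "h", 1e-9)]
        # combined p for g: Fisher of two 1e-4 values, well below 1e-5
        sets = combine_evidence(ev, cutoff=1e-5)
        assert sets == {"d": {"g", "h"}}

    def test_cutoff_screens_weak_associations(self):
        sets = combine_evidence([("d", "g", 1e-3)], cutoff=1e-5)
        assert sets == {}


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(10, 3, 4, 0) == 1.0

    def test_small_case_full_enumeration_value(self):
        # N=10, K=3, n=4: [C(3,2)C(7,2)+C(3,3)C(7,1)]/C(10,4) = 70/210
        assert hypergeom_upper_tail(10, 3, 4, 2) == pytest.approx(1 / 3, rel=1e-12)

    def test_complex_fully_inside_disease_genes(self):
        # K = n = t: p = 1/C(N,n)
        assert hypergeom_upper_tail(8, 3, 3, 3) == pytest.approx(
            1 / math.comb(8, 3), rel=1e-12
        )

    @pytest.mark.parametrize("N,K,n", [(9, 4, 3), (12, 5, 6), (11, 2, 7)])
    def test_matches_subset_enumeration(self, N, K, n):
        universe = range(N)
        disease = set(range(K))
        total = math.comb(N, n)
        for t in range(0, min(K, n) + 1):
            count = sum(
                1 for s in itertools.combinations(universe, n)
                if len(disease & set(s)) >= t
            )
            assert hypergeom_upper_tail(N, K, n, t) == pytest.approx(
                count / total, rel=1e-9
            )

    def test_monotone_non_increasing_in_t(self):
        vals = [hypergeom_upper_tail(20, 8, 6, t) for t in range(7)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestEnrichment:
    def test_genes_outside_universe_dropped(self, caplog):
        cat = [cx("c1", {"A", "B"}), cx("c2", {"C", "D"})]
        with caplog.at_level("WARNING"):
            assocs = disease_complex_enrichment(cat, {"A", "Z"})
        assert "outside the universe" in caplog.text
        assert all(a.K == 1 for a in assocs)

    def test_sorted_by_p_value_and_counts_consistent(self):
        cat = [cx("c1", {"A", "B", "C"}), cx("c2", {"D", "E", "F"})]
        assocs = disease_complex_enrichment(cat, {"A", "B"})
        assert assocs[0].complex_id == "c1"
        a = assocs[0]
        assert (a.N, a.K, a.n, a.t) == (6, 2, 3, 2)
        assert a.p_value == pytest.approx(
            hypergeom_upper_tail(6, 2, 3, 2), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_complex_ranks_first(self, seed):
        """A complex carrying 8 of 30 disease genes in a 1000-protein
        universe separates decisively from random complexes."""
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(1000)]
        disease = set(rng.choice(genes, size=30, replace=False))
        planted_members = set(rng.choice(sorted(disease), size=8, replace=False))
        planted_members |= set(rng.choice(genes, size=2, replace=False))
        cat = [cx("planted", planted_members)]
        for i in range(49):
            cat.append(cx(f"r{i}", set(rng.choice(genes, size=10, replace=False))))
        assocs = disease_complex_enrichment(cat, disease, universe=set(genes))
        assert assocs[0].complex_id == "planted"


class TestSubnetworksAndRepositioning:
    def _net(self):
        cat = [cx("c1", {"A"}), cx("c2", {"B"}), cx("c3", {"Z"})]
        targets = {"d1": {"A"}, "d2": {"A", "B"}, "d3": {"Q"}}
        return cat, build_network(cat, targets)

    def _assoc(self, cid, p=1e-4):
        from complexcat.disease_assoc import DiseaseComplexAssociation

        return DiseaseComplexAssociation("dis", cid, 100, 10, 5, 4, p)

    def test_no_significant_complexes_leaves_lone_disease_node(self):
        _, net = self._net()
        g = disease_subnetwork("dis", [], net)
        assert set(g.nodes) == {"dis"}

    def test_star_of_drugs_around_one_complex(self):
        cat = [cx("hub", {"A"})]
        targets = {f"d{i}": {"A"} for i in range(11)}
        net = build_network(cat, targets)
        g = disease_subnetwork("dis", [self._assoc("hub")], net)
        drugs = [v for v, d in g.nodes(data=True) if d["kind"] == "drug"]
        assert len(drugs) == 11
        assert all(g.has_edge("hub", d) for d in drugs)

    def test_shared_drug_connects_two_complexes(self):
        _, net = self._net()
        g = disease_subnetwork("dis", [self._assoc("c1"), self._assoc("c2")], net)
        import networkx as nx

        h = g.subgraph(n for n in g if n != "dis")
        comp = nx.node_connected_component(h, "d2")
        assert {"c1", "c2", "d2"} <= comp  # the shared drug bridges both complexes

    def test_complex_without_drugs_kept_isolated(self):
        _, net = self._net()
        g = disease_subnetwork("dis", [self._assoc("c3")], net)
        assert "c3" in g and g.degree("c3") == 1  # only the disease edge

    def test_candidates_deduplicated_with_all_supports(self):
        _, net = self._net()
        g = disease_subnetwork("dis", [self._assoc("c1"), self._assoc("c2")], net)
        cands = repositioning_candidates({"dis": g})
        by_drug = {c.drug: c for c in cands}
        assert by_drug["d2"].supporting_complexes == ("c1", "c2")
        assert by_drug["d1"].supporting_complexes == ("c1",)
        assert "d3" not in by_drug

    def test_empty_subnetwork_gives_no_candidates(self):
        _, net = self._net()
        g = disease_subnetwork("dis", [], net)
        assert repositioning_candidates({"dis": g}) == []

    def test_candidates_match_brute_force_scan(self, small_bundle):
        b = small_bundle
        net = build_network(b.true_complexes, b.drug_targets)
        subnets = {}
        expected = set()
        for disease, genes in b.disease_genes.items():
            assocs = disease_complex_enrichment(b.true_complexes, genes)
            sig = significant_associations(assocs, 0.05)
            subnets[disease] = disease_subnetwork(disease, sig, net)
            sig_ids = {a.complex_id for a in sig}
            for (drug, cid) in net.edges:
                if cid in sig_ids:
                    expected.add((disease, drug))
        got = {(c.disease, c.drug) for c in repositioning_candidates(subnets)}
        assert got == expected
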