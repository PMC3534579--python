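"""Generators: planted truth must be exact and seed-reproducible."""

import numpy as np
import pytest

from teflux.knockdown import KnockdownConfig, gene_impact
from teflux.sites import scan_target_sites
from teflux.synth import (
    exhaustive_insertions,
    make_disease_map,
    make_gene_sequences,
    make_insertions,
    make_toy_network,
)


class TestToyNetwork:
    def test_all_isozymes_means_no_effective_genes(self):
        _, truth = make_toy_network(2, 3, isozyme_fraction=1.0,
                                    complex_fraction=0.0, seed=1)
        assert truth.effective_genes == frozenset()
        assert truth.buffered_genes

    def test_single_sole_gene_chain_matches_hand_enumeration(self):
        model, truth = make_toy_network(1, 3, isozyme_fraction=0.0,
                                        complex_fraction=0.0, seed=0)
        # chain m1 -> m2 -> m3; gene on step j affects everything downstream
        assert truth.gene_affected == {
            "g0_0": frozenset({"m0x2", "m0x3"}),
            "g0_1": frozenset({"m0x3"}),
        }
        for g, want in truth.gene_affected.items():
            assert gene_impact(model, g, KnockdownConfig()).affected_keys == want

    def test_deterministic_under_seed(self):
        m1, t1 = make_toy_network(3, 4, 0.3, 0.3, seed=9)
        m2, t2 = make_toy_network(3, 4, 0.3, 0.3, seed=9)
        assert t1 == t2
        assert [r.id for r in m1.reactions] == [r.id for r in m2.reactions]
        assert [r.gpr.to_string() for r in m1.reactions] == \
            [r.gpr.to_string() for r in m2.reactions]

    def test_effective_and_buffered_disjoint(self):
        _, truth = make_toy_network(4, 5, 0.4, 0.3, seed=2)
        assert not truth.effective_genes & truth.buffered_genes

    def test_zero_chains_rejected(self):
        with pytest.raises(ValueError):
            make_toy_network(0, 3)


class TestGeneSequences:
    def test_zero_planting_scans_clean(self):
        seqs, planted = make_gene_sequences(["gA"], length=200,
                                            planted_sites_per_gene=0, seed=3)
        assert planted["gA"] == ()
        assert scan_target_sites(seqs["gA"]) == []

    def test_planted_sites_found_exactly(self):
        seqs, planted = make_gene_sequences(["gA"], length=200,
                                            planted_sites_per_gene=3, seed=4)
        found = {(s.position, s.strand) for s in scan_target_sites(seqs["gA"])}
        want = {(s.position, s.strand) for s in planted["gA"]}
        assert found == want and len(want) == 3

    def test_reverse_strand_plants_found_as_minus(self):
        rng_hit = False
        for seed in range(6):
            seqs, planted = make_gene_sequences(["g"], length=120,
                                                planted_sites_per_gene=2,
                                                seed=seed)
            minus = [s for s in planted["g"] if s.strand == "-"]
            if minus:
                rng_hit = True
                found = scan_target_sites(seqs["g"])
                for s in minus:
                    assert any(f.position == s.position and f.strand == "-"
                               for f in found)
        assert rng_hit  # at least one seed planted a reverse-strand site

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError):
            make_gene_sequences(["g"], length=30, planted_sites_per_gene=4)

    def test_deterministic_under_seed(self):
        a, _ = make_gene_sequences(["x", "y"], seed=8)
        b, _ = make_gene_sequences(["x", "y"], seed=8)
        assert a == b


class TestInsertions:
    def _truth(self):
        _, truth = make_toy_network(4, 4, isozyme_fraction=0.5,
                                    complex_fraction=0.0, seed=5)
        return truth

    def test_bias_one_hits_effective_only(self):
        truth = self._truth()
        records = make_insertions(truth, insertions_per_donor=50,
                                  effective_bias=1.0, seed=1)
        assert {r.gene for r in records} <= truth.effective_genes

    def test_bias_zero_is_uniform_within_sampling_error(self):
        truth = self._truth()
        n = 30_000
        records = make_insertions(truth, donors=("A",),
                                  insertions_per_donor=n,
                                  effective_bias=0.0, seed=2)
        counts = {}
        for r in records:
            counts[r.gene] = counts.get(r.gene, 0) + 1
        k = len(truth.genes)
        se = (1 / k * (1 - 1 / k) / n) ** 0.5
        for g in truth.genes:
            assert abs(counts.get(g, 0) / n - 1 / k) < 4 * se

    def test_three_donors_disjoint_pools_no_overlap(self):
        # donors built on disjoint gene pools -> disjoint metabolite impacts
        model, truth = make_toy_network(3, 3, isozyme_fraction=0.0,
                                        complex_fraction=0.0, seed=7)
        by_chain = {d: [g for g in truth.genes if g.startswith(f"g{i}_")]
                    for i, d in enumerate("ABC")}
        affected = {
            d: frozenset().union(*(truth.gene_affected[g] for g in genes))
            for d, genes in by_chain.items()
        }
        assert not (affected["A"] & affected["B"] & affected["C"])

    def test_exhaustive_insertions_cover_every_gene(self):
        truth = self._truth()
        records = exhaustive_insertions(truth)
        assert {r.gene for r in records} == set(truth.genes)


class TestDiseaseMap:
    def test_planted_set_drawn_from_affected_pool(self):
        _, truth = make_toy_network(3, 4, 0.0, 0.0, seed=6)
        dmap, truth2 = make_disease_map(truth.metabolite_keys, n_diseases=2,
                                        set_size=4, truth=truth, plant=True,
                                        seed=3)
        assert truth2.planted_disease == "planted_disease"
        assert dmap["planted_disease"] <= truth.affected_pool

    def test_empty_pool_rejected(self):
        _, truth = make_toy_network(2, 3, isozyme_fraction=1.0,
                                    complex_fraction=0.0, seed=1)
        with pytest.raises(ValueError, match="pool"):
            make_disease_map(truth.metabolite_keys, n_diseases=1, set_size=2,
                             truth=truth, plant=True, seed=1)

    def test_set_size_validated(self):
        with pytest.raises(ValueError):
            make_disease_map(("a", "b"), n_diseases=1, set_size=5, seed=1)

    def test_deterministic_under_seed(self):
        keys = tuple(f"k{i}" for i in range(20))
        a, _ = make_disease_map(keys, 3, 5, seed=4)
        b, _ = make_disease_map(keys, 3, 5, seed=4)
        assert a == b
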