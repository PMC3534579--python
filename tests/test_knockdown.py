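"""Isozyme classification, partial knockdown, and the insertion screen."""

import numpy as np
import pytest

from teflux.fluxcore import fba, fva, max_production
from teflux.knockdown import (
    InsertionRecord,
    KnockdownConfig,
    apply_knockdown,
    classify_gene,
    gene_impact,
    scan_insertions,
)
from teflux.model import MetabolicModel, Metabolite, make_reaction
from teflux.sbml_io import add_production_objective

from .oracles import classify_by_truth_table, random_rule


class TestClassifyGene:
    def test_isozyme_or_pair_is_buffered(self, chain_model):
        assert classify_gene(chain_model, "giso1") == ("buffered", [])

    def test_sole_gene_is_effective(self, chain_model):
        assert classify_gene(chain_model, "gmid") == ("effective", ["R_BC"])

    def test_unknown_gene_rejected(self, chain_model):
        with pytest.raises(KeyError):
            classify_gene(chain_model, "nope")

    def test_matches_truth_table_oracle_on_random_rules(self):
        """50 random GPR fixtures classified identically by brute force."""
        genes = [f"g{i}" for i in range(5)]
        rng = np.random.default_rng(123)
        for _ in range(50):
            rules = {f"r{k}": random_rule(rng, genes) for k in range(4)}
            mets = [Metabolite("A_c", compartment="c")]
            rxns = [make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0)] + [
                make_reaction(rid, {"A_c": -1.0}, 0.0, 10.0, gpr=rule)
                for rid, rule in rules.items()
            ]
            model = MetabolicModel(mets, rxns)
            for g in sorted(model.genes):
                want = classify_by_truth_table(rules, g, genes)
                got = classify_gene(model, g)
                assert got[0] == want[0], (g, rules)
                assert sorted(got[1]) == sorted(want[1])


class TestApplyKnockdown:
    def test_identity_at_fold_one(self, chain_model):
        env = fva(chain_model, "EC")
        kd = apply_knockdown(chain_model, "gmid", env,
                             KnockdownConfig(fold_reduction=1.0))
        assert max_production(kd, "C_c") == pytest.approx(
            max_production(chain_model, "C_c")
        )

    def test_seventyfold_chain(self, chain_model):
        with_obj, rid = add_production_objective(chain_model, "C_c")
        env = fva(with_obj, rid, reactions=["R_BC"])
        kd = apply_knockdown(with_obj, "gmid", env, KnockdownConfig())
        lo, hi = (kd.reaction("R_BC").lower_bound,
                  kd.reaction("R_BC").upper_bound)
        assert (lo, hi) == pytest.approx((0.0, 10.0 / 70.0))
        assert fba(kd, rid).objective_value == pytest.approx(10.0 / 70.0)

    def test_buffered_gene_leaves_bounds_alone(self, chain_model):
        env = fva(chain_model, "EC")
        kd = apply_knockdown(chain_model, "giso1", env, KnockdownConfig())
        for r in chain_model.reactions:
            r2 = kd.reaction(r.id)
            assert (r2.lower_bound, r2.upper_bound) == (r.lower_bound,
                                                        r.upper_bound)

    def test_missing_envelope_entry_is_an_error(self, chain_model):
        env = fva(chain_model, "EC", reactions=["EA"])
        with pytest.raises(KeyError, match="R_BC"):
            apply_knockdown(chain_model, "gmid", env, KnockdownConfig())

    def test_reversible_reaction_shrinks_both_sides(self):
        mets = [Metabolite("A_c", compartment="c"),
                Metabolite("B_c", compartment="c")]
        rxns = [
            make_reaction("EA", {"A_c": 1.0}, -10.0, 10.0),
            make_reaction("AB", {"A_c": -1.0, "B_c": 1.0}, -10.0, 10.0,
                          gpr="g"),
            make_reaction("EB", {"B_c": -1.0}, -10.0, 10.0),
        ]
        model = MetabolicModel(mets, rxns)
        from teflux.fluxcore import FluxEnvelope
        env = FluxEnvelope(ranges={"AB": (-10.0, 10.0)},
                           objective_reaction="EB", objective_value=10.0)
        kd = apply_knockdown(model, "g", env, KnockdownConfig(fold_reduction=10))
        r = kd.reaction("AB")
        assert (r.lower_bound, r.upper_bound) == pytest.approx((-1.0, 1.0))
        # under the production objective itself the attainable reverse flux
        # is zero, so the envelope cap keeps the lower bound at zero
        kd2 = apply_knockdown(model, "g", fva(model, "EB"),
                              KnockdownConfig(fold_reduction=10))
        r2 = kd2.reaction("AB")
        assert (r2.lower_bound, r2.upper_bound) == pytest.approx((0.0, 1.0))


class TestGeneImpact:
    def test_buffered_gene_has_no_impact(self, chain_model):
        assert not gene_impact(chain_model, "giso1").has_impact

    def test_chain_gene_affects_downstream_only(self, chain_model):
        gi = gene_impact(chain_model, "gmid")
        affected = {m: (b, p) for m, _, b, p in gi.affected}
        assert set(affected) == {"C_c"}
        assert affected["C_c"] == pytest.approx((10.0, 10.0 / 70.0))

    def test_network_compensation_yields_no_impact(self, compensated_model):
        assert not gene_impact(compensated_model, "gk").has_impact

    def test_perturbed_at_least_baseline_over_fold(self, chain_model):
        gi = gene_impact(chain_model, "gmid")
        for _, _, base, pert in gi.affected:
            assert pert >= base / 70.0 - 1e-9

    @pytest.mark.parametrize("model_name, gene",
                             [("chain_model", "gmid"),
                              ("compensated_model", "gk")])
    def test_affected_set_monotone_in_fold(self, model_name, gene, request):
        """Growing the fold factor never shrinks the affected set."""
        model = request.getfixturevalue(model_name)
        sets = [
            gene_impact(model, gene,
                        KnockdownConfig(fold_reduction=f)).affected_keys
            for f in (1.0, 2.0, 10.0, 70.0)
        ]
        for small, big in zip(sets, sets[1:]):
            assert small <= big


class TestScanInsertions:
    def _records(self, genes, donor="A"):
        return [InsertionRecord(donor, g) for g in genes]

    def test_partition_identities(self, chain_model):
        records = self._records(["giso1", "giso2", "gmid"])
        scan = scan_insertions(chain_model, records)
        s = scan.summary
        assert s["n_genes_hit"] == s["n_buffered"] + s["n_effective"]
        assert s["n_effective"] == s["n_impact"] + s["n_no_impact"]

    def test_unmapped_genes_counted_not_fatal(self, chain_model):
        scan = scan_insertions(
            chain_model, self._records(["gmid", "not_a_gene"])
        )
        assert scan.unmapped_genes == ("not_a_gene",)
        assert scan.summary["n_insertions_mapped"] == 1

    def test_empty_table_is_an_error(self, chain_model):
        with pytest.raises(ValueError):
            scan_insertions(chain_model, [])

    def test_identical_donors_have_identical_overlap(self, chain_model):
        records = self._records(["gmid"], "A") + self._records(["gmid"], "B")
        scan = scan_insertions(chain_model, records)
        na = scan.per_donor["A"]["n_affected_metabolites"]
        assert scan.summary["overlaps"]["A&B"] == na
        assert na == scan.per_donor["B"]["n_affected_metabolites"]

    def test_overlaps_bounded_by_donor_counts(self, chain_model):
        records = (self._records(["gmid"], "A")
                   + self._records(["giso1"], "B")
                   + self._records(["gmid", "giso2"], "C"))
        scan = scan_insertions(chain_model, records)
        for pair, v in scan.summary["overlaps"].items():
            for d in pair.split("&"):
                assert v <= scan.per_donor[d]["n_affected_metabolites"]
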