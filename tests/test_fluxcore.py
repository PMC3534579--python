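"""FBA/FVA against hand LPs and a vertex-enumeration oracle."""

import numpy as np
import pytest

from teflux.fluxcore import (
    ASSERT_TOL,
    InfeasibleError,
    UnboundedError,
    fba,
    fva,
    max_production,
    stoichiometric_matrix,
)
from teflux.model import MetabolicModel, Metabolite, Reaction, make_reaction

from .oracles import brute_force_max_flux, random_toy_lp


def _model_from_matrix(S, bounds):
    mets = [Metabolite(f"x{i}_c", compartment="c") for i in range(S.shape[0])]
    rxns = []
    for j in range(S.shape[1]):
        stoich = {f"x{i}_c": float(S[i, j]) for i in range(S.shape[0])
                  if S[i, j] != 0}
        rxns.append(Reaction(f"r{j}", stoich, bounds[j][0], bounds[j][1]))
    return MetabolicModel(mets, rxns)


class TestFBA:
    def test_capacity_limited_chain(self, chain_model):
        assert fba(chain_model, "EC").objective_value == pytest.approx(10.0)

    def test_export_without_source_is_zero(self):
        mets = [Metabolite("A_c", compartment="c")]
        rxns = [make_reaction("EA", {"A_c": -1.0}, 0.0, 1000.0)]
        m = MetabolicModel(mets, rxns)
        assert fba(m, "EA").objective_value == pytest.approx(0.0)

    def test_steady_state_residual_within_tolerance(self, chain_model):
        sol = fba(chain_model, "EC")
        S, _, rxn_ids = stoichiometric_matrix(chain_model)
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) <= ASSERT_TOL

    def test_infeasible_forced_flux(self):
        # a reaction must run at >=5 but its product has no consumer
        mets = [Metabolite("A_c", compartment="c")]
        rxns = [make_reaction("src", {"A_c": 1.0}, 5.0, 10.0)]
        with pytest.raises(InfeasibleError):
            fba(MetabolicModel(mets, rxns), "src")

    def test_unbounded_objective_is_reported(self):
        mets = [Metabolite("A_c", compartment="c")]
        rxns = [
            make_reaction("in", {"A_c": 1.0}, 0.0, float("inf")),
            make_reaction("out", {"A_c": -1.0}, 0.0, float("inf")),
        ]
        with pytest.raises(UnboundedError):
            fba(MetabolicModel(mets, rxns), "out")

    def test_matches_vertex_enumeration_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            S, bounds = random_toy_lp(rng)
            model = _model_from_matrix(S, bounds)
            j = int(rng.integers(S.shape[1]))
            got = fba(model, f"r{j}").objective_value
            want = brute_force_max_flux(S, bounds, j)
            assert got == pytest.approx(want, abs=1e-6)


class TestFVA:
    def test_unique_pathway_is_pinned(self, chain_model):
        env = fva(chain_model, "EC", optimality_fraction=1.0)
        for rid in ("EA", "R_AB", "R_BC", "EC"):
            lo, hi = env[rid]
            assert (lo, hi) == pytest.approx((10.0, 10.0))

    def test_blocked_reaction_is_zero(self):
        mets = [Metabolite(m, compartment="c") for m in ("A_c", "B_c", "C_c")]
        rxns = [
            make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0),
            make_reaction("AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 10.0),
            make_reaction("EB", {"B_c": -1.0}, 0.0, 1000.0),
            # C is unproducible, so consuming it is blocked
            make_reaction("CB", {"C_c": -1.0, "B_c": 1.0}, 0.0, 10.0),
        ]
        env = fva(MetabolicModel(mets, rxns), "EB", optimality_fraction=0.0)
        assert env["CB"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_parallel_branches_split_freely(self, parallel_model):
        env = fva(parallel_model, "EC", optimality_fraction=1.0)
        assert env["EC"] == pytest.approx((10.0, 10.0))
        for rid in ("B1a", "B1b", "B2a", "B2b"):
            assert env[rid] == pytest.approx((0.0, 10.0), abs=1e-7)

    def test_fba_optimum_lies_inside_envelope(self, parallel_model):
        env = fva(parallel_model, "EC", optimality_fraction=1.0)
        sol = fba(parallel_model, "EC")
        for rid, (lo, hi) in env.ranges.items():
            assert lo - ASSERT_TOL <= sol.fluxes[rid] <= hi + ASSERT_TOL

    def test_reaction_subset_restriction(self, chain_model):
        env = fva(chain_model, "EC", reactions=["R_BC"])
        assert set(env.ranges) == {"R_BC"}


class TestMaxProduction:
    def test_chain_metabolite(self, chain_model):
        assert max_production(chain_model, "C_c") == pytest.approx(10.0)

    def test_orphan_metabolite_is_zero(self):
        mets = [Metabolite("A_c", compartment="c"),
                Metabolite("orphan_c", compartment="c")]
        rxns = [make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0)]
        assert max_production(MetabolicModel(mets, rxns), "orphan_c") == 0.0

    def test_matches_oracle_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            S, bounds = random_toy_lp(rng, n_reactions=5, n_metabolites=3)
            model = _model_from_matrix(S, bounds)
            for i in range(S.shape[0]):
                got = max_production(model, f"x{i}_c")
                # oracle: add the demand column to S and enumerate
                S2 = np.hstack([S, np.zeros((S.shape[0], 1))])
                S2[i, -1] = -1.0
                want = brute_force_max_flux(S2, bounds + [(0.0, 1000.0)],
                                            S.shape[1])
                assert got == pytest.approx(max(want, 0.0), abs=1e-6)

    def test_monotone_under_bound_tightening(self, parallel_model):
        base = max_production(parallel_model, "C_c")
        rng = np.random.default_rng(3)
        for _ in range(10):
            rid = parallel_model.reactions[
                rng.integers(len(parallel_model.reactions))].id
            rxn = parallel_model.reaction(rid)
            tightened = parallel_model.replace_bounds(
                {rid: (rxn.lower_bound, rxn.upper_bound * rng.random())}
            )
            assert max_production(tightened, "C_c") <= base + ASSERT_TOL

    def test_homogeneity_under_bound_scaling(self, chain_model):
        lam = 3.5
        scaled = chain_model.replace_bounds({
            r.id: (r.lower_bound * lam, r.upper_bound * lam)
            for r in chain_model.reactions
        })
        assert max_production(scaled, "C_c") == pytest.approx(
            lam * max_production(chain_model, "C_c")
        )
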