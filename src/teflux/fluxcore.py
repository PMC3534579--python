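"""Linear-programming engine: FBA, FVA and maximal-production queries.

All problems are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`, which is deterministic for a fixed model.
The steady-state constraint ``S·v = 0`` is imposed only on non-boundary
metabolites; boundary species represent the environment and may accumulate
freely.

Only objective *values* are meaningful downstream: individual flux vectors
at degenerate optima are non-unique and are never compared between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model import MetabolicModel
from .sbml_io import add_production_objective

FEASIBILITY_TOL = 1e-9   # solver-level
ASSERT_TOL = 1e-6        # downstream assertion tolerance

__all__ = [
    "FluxAssignment",
    "FluxEnvelope",
    "InfeasibleError",
    "UnboundedError",
    "fba",
    "fva",
    "max_production",
    "stoichiometric_matrix",
    "FEASIBILITY_TOL",
    "ASSERT_TOL",
]


class InfeasibleError(RuntimeError):
    """The LP has no steady-state solution within bounds."""


class UnboundedError(RuntimeError):
    """The objective can grow without limit."""


@dataclass(frozen=True)
class FluxAssignment:
    fluxes: dict[str, float]
    objective_value: float
    objective_reaction: str


@dataclass(frozen=True)
class FluxEnvelope:
    """Per-reaction attainable [v_min, v_max] flux range under a fixed
    production objective (the FVA output)."""

    ranges: dict[str, tuple[float, float]]
    objective_reaction: str
    objective_value: float

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.ranges


def stoichiometric_matrix(model: MetabolicModel):
    """Sparse S over non-boundary metabolites; returns (S, met_ids, rxn_ids)."""
    mets = [m.id for m in model.non_boundary_metabolites]
    row_of = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            i = row_of.get(mid)
            if i is not None:
                rows.append(i)
                cols.append(j)
                vals.append(coef)
    S = csr_matrix((vals, (rows, cols)), shape=(len(mets), len(model.reactions)))
    return S, mets, [r.id for r in model.reactions]


class _LP:
    """Cached LP skeleton for one model (S, bounds, column index)."""

    def __init__(self, model: MetabolicModel) -> None:
        self.S, self.met_ids, self.rxn_ids = stoichiometric_matrix(model)
        self.col = {r: j for j, r in enumerate(self.rxn_ids)}
        self.bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        self.n = len(self.rxn_ids)

    def solve(self, c: np.ndarray, extra_ub=None):
        A_ub, b_ub = (None, None)
        if extra_ub is not None:
            A_ub, b_ub = extra_ub
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=self.bounds,
            method="highs",
            options={"presolve": True, "primal_feasibility_tolerance": FEASIBILITY_TOL,
                     "dual_feasibility_tolerance": FEASIBILITY_TOL},
        )
        return res


def _check_status(res, what: str) -> None:
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible while {what}")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded while {what}")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure while {what}: {res.message}")


def fba(
    model: MetabolicModel,
    objective_reaction: str,
    sense: str = "max",
    _lp: "_LP | None" = None,
) -> FluxAssignment:
    """Flux balance analysis: optimize one reaction's flux subject to
    ``S·v = 0`` on internal metabolites and the reaction bounds."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    lp = _lp if _lp is not None else _LP(model)
    if objective_reaction not in lp.col:
        raise KeyError(f"unknown objective reaction {objective_reaction!r}")
    c = np.zeros(lp.n)
    c[lp.col[objective_reaction]] = -1.0 if sense == "max" else 1.0
    res = lp.solve(c)
    _check_status(res, f"optimizing {objective_reaction!r} ({sense})")
    obj = float(res.x[lp.col[objective_reaction]])
    return FluxAssignment(
        fluxes=dict(zip(lp.rxn_ids, (float(v) for v in res.x))),
        objective_value=obj,
        objective_reaction=objective_reaction,
    )


def fva(
    model: MetabolicModel,
    objective_reaction: str,
    optimality_fraction: float = 0.0,
    reactions: list[str] | None = None,
) -> FluxEnvelope:
    """Flux variability analysis under a production objective.

    For every reaction (or the subset *reactions*), the attainable flux
    minimum and maximum subject to steady state, bounds, and
    ``v_obj >= optimality_fraction * optimum``.  The default fraction 0
    constrains only non-negative objective flux, i.e. the envelope of the
    network while it is *able* to run the objective.
    """
    if not 0.0 <= optimality_fraction <= 1.0:
        raise ValueError("optimality_fraction must lie in [0, 1]")
    lp = _LP(model)
    opt = fba(model, objective_reaction, "max", _lp=lp).objective_value

    j_obj = lp.col[objective_reaction]
    row = np.zeros((1, lp.n))
    row[0, j_obj] = -1.0
    extra = (row, np.array([-optimality_fraction * opt]))

    targets = lp.rxn_ids if reactions is None else list(reactions)
    ranges: dict[str, tuple[float, float]] = {}
    c = np.zeros(lp.n)
    for rid in targets:
        j = lp.col[rid]  # KeyError on unknown reaction
        c[j] = 1.0
        lo_res = lp.solve(c, extra_ub=extra)
        _check_status(lo_res, f"FVA min of {rid!r}")
        c[j] = -1.0
        hi_res = lp.solve(c, extra_ub=extra)
        _check_status(hi_res, f"FVA max of {rid!r}")
        c[j] = 0.0
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        if lo > hi:  # numerical jitter on blocked/fixed reactions
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FluxEnvelope(ranges=ranges, objective_reaction=objective_reaction,
                        objective_value=opt)


def max_production(model: MetabolicModel, met_id: str) -> float:
    """Maximal steady-state biosynthesis rate of an internal metabolite:
    the FBA optimum of a unit demand reaction exporting it."""
    with_obj, rid = add_production_objective(model, met_id)
    value = fba(with_obj, rid, "max").objective_value
    return max(value, 0.0)
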