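"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites (species,
possibly flagged as *boundary*, i.e. exempt from the steady-state constraint),
reactions with flux bounds and a gene-protein-reaction (GPR) boolean rule, and
the set of genes appearing in those rules.

Metabolite identity follows the COBRA convention of a compartment-suffixed id
(``glc_c``, ``glc_m`` ...); :func:`strip_compartment` recovers the
compartment-free key used whenever "different metabolites" are counted across
organelles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .gpr import GPRExpression, parse_gpr

DEFAULT_BOUND = 1000.0

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "strip_compartment",
]


def strip_compartment(met_id: str, compartment: str | None = None) -> str:
    """Compartment-free metabolite key: the id minus a trailing ``_<token>``.

    If *compartment* is given, only that exact suffix is stripped; otherwise
    any single trailing underscore token of length <= 2 (the usual one- or
    two-letter organelle codes) is removed.
    """
    if compartment:
        suffix = "_" + compartment
        return met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id
    head, sep, tail = met_id.rpartition("_")
    if sep and head and 1 <= len(tail) <= 2:
        return head
    return met_id


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")

    @property
    def key(self) -> str:
        """Compartment-stripped identity used for cross-organelle counting."""
        return strip_compartment(self.id, self.compartment)


@dataclass(frozen=True)
class Reaction:
    """A reaction: signed stoichiometry, flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  ``gpr`` is the parsed boolean tree; an empty tree means the
    reaction has no gene requirement (spontaneous or exchange).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=GPRExpression.empty)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ValueError(f"reaction {self.id!r}: zero coefficient for {met!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class MetabolicModel:
    """An immutable-by-convention stoichiometric network.

    Invariants enforced at construction: unique metabolite and reaction ids,
    every stoichiometry entry references a declared metabolite, and the gene
    set is exactly the union of GPR leaves.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        model_id: str = "model",
    ) -> None:
        self.id = model_id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self._met_index = {m.id: m for m in self.metabolites}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            unknown = set(r.stoichiometry) - self._met_index.keys()
            if unknown:
                raise ValueError(
                    f"reaction {r.id!r} references undeclared species: {sorted(unknown)}"
                )
        self.genes: frozenset[str] = frozenset(
            g for r in self.reactions for g in r.gpr.genes()
        )

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def non_boundary_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    def reactions_of_gene(self, gene: str) -> list[Reaction]:
        """Reactions whose GPR mentions *gene* (i.e. catalyzed by it)."""
        return [r for r in self.reactions if gene in r.gpr.genes()]

    # -- functional updates -------------------------------------------------
    def with_reactions(self, reactions: list[Reaction]) -> "MetabolicModel":
        return MetabolicModel(self.metabolites, reactions, model_id=self.id)

    def replace_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """New model with the given reactions' bounds replaced."""
        new = [
            r.with_bounds(*bounds[r.id]) if r.id in bounds else r
            for r in self.reactions
        ]
        return self.with_reactions(new)

    def stats(self) -> dict[str, int]:
        return {
            "metabolites": len(self.metabolites),
            "non_boundary_metabolites": len(self.non_boundary_metabolites),
            "reactions": len(self.reactions),
            "genes": len(self.genes),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = self.stats()
        return (
            f"<MetabolicModel {self.id}: {s['metabolites']} metabolites "
            f"({s['non_boundary_metabolites']} internal), {s['reactions']} reactions, "
            f"{s['genes']} genes>"
        )


def make_reaction(
    rxn_id: str,
    stoichiometry: dict[str, float],
    lower_bound: float = -DEFAULT_BOUND,
    upper_bound: float = DEFAULT_BOUND,
    gpr: str | GPRExpression = "",
    name: str = "",
) -> Reaction:
    """Convenience constructor accepting a GPR rule string."""
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    return Reaction(rxn_id, stoichiometry, lower_bound, upper_bound, gpr, name)
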