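"""In-silico partial gene knockdown and the insertion-impact screen.

The procedure mirrors how a strong (default 70-fold) reduction in a gene's
expression propagates to metabolite biosynthesis in a metabolic network:

1.  *Isozyme screen* — a gene is **buffered** when every GPR rule it appears
    in remains satisfiable without it (an OR-branch isozyme covers it), and
    **effective** otherwise.  Only effective genes can have any phenotype;
    the reactions whose rules go false are the gene's *falsified* reactions.
2.  *Linear knockdown* — expression is coupled linearly to flux capacity:
    under a given production objective, each falsified reaction's attainable
    flux range (its FVA envelope) is shrunk by the fold factor and imposed
    as new bounds.
3.  *Impact* — a metabolite is affected when its maximal production rate
    drops by more than a relative threshold from a positive baseline.

One gene is perturbed at a time; combinations of insertions are out of
scope (at most a handful of new insertions arise per cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .fluxcore import fba, fva
from .model import MetabolicModel, strip_compartment
from .sbml_io import add_production_objective

log = logging.getLogger(__name__)

__all__ = [
    "KnockdownConfig",
    "GeneImpact",
    "InsertionRecord",
    "ScanResult",
    "classify_gene",
    "apply_knockdown",
    "gene_impact",
    "scan_insertions",
    "read_insertions",
]


@dataclass(frozen=True)
class KnockdownConfig:
    """Parameters of the knockdown screen.

    fold_reduction: factor by which falsified reactions' flux capacity is
        divided (>= 1).  The default 70 reflects the measured expression
        drop caused by sense-oriented intronic L1 insertions.
    relative_drop_threshold: minimal relative production decrease counted as
        an effect (LP noise floor).
    production_floor: minimal baseline production for a metabolite to be
        evaluated at all.
    optimality_fraction: objective fraction passed to FVA when building the
        envelope (0 = unconstrained-objective envelope).
    envelope_mode: "envelope" caps falsified reactions at envelope/f;
        "raw" caps at original bounds / f.
    """

    fold_reduction: float = 70.0
    relative_drop_threshold: float = 1e-6
    production_floor: float = 1e-9
    optimality_fraction: float = 0.0
    envelope_mode: str = "envelope"

    def __post_init__(self) -> None:
        if self.fold_reduction < 1:
            raise ValueError("fold_reduction must be >= 1")
        if self.relative_drop_threshold <= 0:
            raise ValueError("relative_drop_threshold must be > 0")
        if self.envelope_mode not in ("envelope", "raw"):
            raise ValueError("envelope_mode must be 'envelope' or 'raw'")


@dataclass(frozen=True)
class GeneImpact:
    """Metabolites whose maximal biosynthesis drops under one gene's
    knockdown: (metabolite id, compartment, baseline rate, perturbed rate)."""

    gene: str
    affected: tuple[tuple[str, str, float, float], ...] = ()

    @property
    def affected_keys(self) -> frozenset[str]:
        """Compartment-stripped identities of the affected metabolites."""
        return frozenset(strip_compartment(m, c) for m, c, _, _ in self.affected)

    @property
    def has_impact(self) -> bool:
        return bool(self.affected)


@dataclass(frozen=True)
class InsertionRecord:
    donor: str
    gene: str


@dataclass
class ScanResult:
    """Output of :func:`scan_insertions`: per-gene impacts, per-donor
    affected-metabolite sets, and the summary counts of the screen."""

    impacts: dict[str, GeneImpact]
    buffered_genes: frozenset[str]
    effective_genes: frozenset[str]
    unmapped_genes: tuple[str, ...]
    summary: dict
    per_donor: dict[str, dict]
    donor_affected: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def impact_genes(self) -> frozenset[str]:
        return frozenset(g for g, gi in self.impacts.items() if gi.has_impact)

    @property
    def affected_keys(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for gi in self.impacts.values():
            out |= gi.affected_keys
        return out


# ---------------------------------------------------------------------------

def classify_gene(model: MetabolicModel, gene: str) -> tuple[str, list[str]]:
    """Isozyme screen for one gene.

    Evaluates every reaction's GPR with this gene absent and all others
    present; reactions whose rule goes false are *falsified*.  Returns
    ``("buffered", [])`` when nothing is falsified, else
    ``("effective", falsified_ids)``.
    """
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model gene set")
    falsified = [
        r.id
        for r in model.reactions
        if gene in r.gpr.genes() and not r.gpr.satisfied_without(gene)
    ]
    return ("buffered" if not falsified else "effective"), falsified


def _capped_bounds(
    lb: float, ub: float, cap_lo: float, cap_hi: float, f: float
) -> tuple[float, float]:
    """Shrink a capacity interval by 1/f and intersect with [lb, ub]."""
    lo = max(lb, min(cap_lo / f, 0.0))
    hi = min(ub, max(cap_hi / f, 0.0))
    if lo > hi:  # forced-flux reaction vs cap; the cap wins
        lo = hi
    return lo, hi


def apply_knockdown(
    model: MetabolicModel,
    gene: str,
    envelope,
    config: KnockdownConfig = KnockdownConfig(),
) -> MetabolicModel:
    """New model in which the gene's falsified reactions are capped at
    (envelope range)/fold_reduction, intersected with their original bounds.

    Reversible falsified reactions shrink on both sides: reduced expression
    limits catalytic capacity in either direction.  Reactions kept true by
    an isozyme are untouched.  ``envelope`` must cover every falsified
    reaction (it is the FVA envelope of the production objective currently
    being evaluated).
    """
    _, falsified = classify_gene(model, gene)
    if not falsified:
        return model
    f = config.fold_reduction
    new_bounds: dict[str, tuple[float, float]] = {}
    for rid in falsified:
        rxn = model.reaction(rid)
        if config.envelope_mode == "raw":
            cap_lo, cap_hi = rxn.lower_bound, rxn.upper_bound
        else:
            if rid not in envelope:
                raise KeyError(
                    f"envelope for objective {envelope.objective_reaction!r} "
                    f"is missing falsified reaction {rid!r}"
                )
            cap_lo, cap_hi = envelope[rid]
        new_bounds[rid] = _capped_bounds(
            rxn.lower_bound, rxn.upper_bound, cap_lo, cap_hi, f
        )
    return model.replace_bounds(new_bounds)


def _perturbed_production(
    with_obj: MetabolicModel,
    obj_rxn: str,
    gene: str,
    falsified: list[str],
    envelope,
    config: KnockdownConfig,
) -> float:
    kd = apply_knockdown(with_obj, gene, envelope, config)
    return max(fba(kd, obj_rxn, "max").objective_value, 0.0)


def gene_impact(
    model: MetabolicModel,
    gene: str,
    config: KnockdownConfig = KnockdownConfig(),
) -> GeneImpact:
    """Which metabolites' maximal biosynthesis drops when *gene* is knocked
    down?  Every internal metabolite with baseline production above the
    floor is re-evaluated under the capped model; a relative drop above the
    threshold counts."""
    status, falsified = classify_gene(model, gene)
    if status == "buffered":
        return GeneImpact(gene)
    affected = []
    for met in model.non_boundary_metabolites:
        with_obj, obj_rxn = add_production_objective(model, met.id)
        try:
            baseline = max(fba(with_obj, obj_rxn, "max").objective_value, 0.0)
            if baseline <= config.production_floor:
                continue
            envelope = fva(
                with_obj, obj_rxn, config.optimality_fraction, reactions=falsified
            )
            perturbed = _perturbed_production(
                with_obj, obj_rxn, gene, falsified, envelope, config
            )
        except Exception as exc:
            raise RuntimeError(
                f"knockdown evaluation failed for gene {gene!r} at metabolite "
                f"{met.id!r}: {exc}"
            ) from exc
        perturbed = min(perturbed, baseline)
        if (baseline - perturbed) / baseline > config.relative_drop_threshold:
            affected.append((met.id, met.compartment, baseline, perturbed))
    return GeneImpact(gene, tuple(affected))


# ---------------------------------------------------------------------------
# insertion-table screen
# ---------------------------------------------------------------------------

def read_insertions(path: str) -> list[InsertionRecord]:
    """TSV with header ``donor<TAB>gene_id``."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["donor", "gene_id"]:
            raise ValueError(
                f"{path}: expected header 'donor\\tgene_id', got {header!r}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            donor, gene = line.split("\t")[:2]
            records.append(InsertionRecord(donor, gene))
    return records


def scan_insertions(
    model: MetabolicModel,
    insertions: list[InsertionRecord],
    config: KnockdownConfig = KnockdownConfig(),
) -> ScanResult:
    """Run the full insertion screen: classify every hit gene, compute each
    effective gene's metabolite impact, and tabulate pooled and per-donor
    counts and overlaps.

    Insertion genes absent from the model are logged and counted, not fatal.
    The per-metabolite FVA envelope is computed once (restricted to the
    union of falsified reactions) and shared across genes, since envelopes
    depend only on the model and the objective, not on the donor.
    """
    if not insertions:
        raise ValueError("empty insertion table")

    mapped = [r for r in insertions if r.gene in model.genes]
    unmapped = tuple(sorted({r.gene for r in insertions} - model.genes))
    if unmapped:
        log.warning("%d insertion genes not in model: %s%s", len(unmapped),
                    ", ".join(unmapped[:5]), "..." if len(unmapped) > 5 else "")
    if not mapped:
        raise ValueError("no insertion genes map to the model gene set")

    hit_genes = sorted({r.gene for r in mapped})
    falsified_of: dict[str, list[str]] = {}
    buffered, effective = set(), set()
    for g in hit_genes:
        status, fals = classify_gene(model, g)
        (buffered if status == "buffered" else effective).add(g)
        falsified_of[g] = fals
    union_falsified = sorted({rid for g in effective for rid in falsified_of[g]})

    reactions_hit = {r.id for g in hit_genes for r in model.reactions_of_gene(g)}

    # one baseline FBA + one restricted FVA per metabolite, one knockdown LP
    # per (effective gene, producible metabolite)
    affected_of: dict[str, list] = {g: [] for g in effective}
    ever_unblocked: set[str] = set()
    for met in model.non_boundary_metabolites:
        with_obj, obj_rxn = add_production_objective(model, met.id)
        baseline = max(fba(with_obj, obj_rxn, "max").objective_value, 0.0)
        if baseline <= config.production_floor:
            continue
        envelope = fva(
            with_obj, obj_rxn, config.optimality_fraction, reactions=union_falsified
        )
        for g in effective:
            if all(
                abs(envelope[rid][0]) <= config.production_floor
                and abs(envelope[rid][1]) <= config.production_floor
                for rid in falsified_of[g]
            ):
                continue  # gene's reactions carry no flux under this objective
            ever_unblocked.add(g)
            perturbed = _perturbed_production(
                with_obj, obj_rxn, g, falsified_of[g], envelope, config
            )
            perturbed = min(perturbed, baseline)
            if (baseline - perturbed) / baseline > config.relative_drop_threshold:
                affected_of[g].append((met.id, met.compartment, baseline, perturbed))

    impacts = {g: GeneImpact(g, tuple(affected_of.get(g, ()))) for g in hit_genes}
    impact_genes = {g for g in effective if impacts[g].has_impact}
    blocked = effective - ever_unblocked

    def donor_block(records: list[InsertionRecord]) -> tuple[dict, frozenset[str]]:
        genes = sorted({r.gene for r in records})
        keys: frozenset[str] = frozenset()
        for g in genes:
            keys |= impacts[g].affected_keys
        return (
            {
                "n_insertions": len(records),
                "n_genes_hit": len(genes),
                "n_impact_genes": len([g for g in genes if impacts[g].has_impact]),
                "n_affected_metabolites": len(keys),
            },
            keys,
        )

    donors = sorted({r.donor for r in mapped})
    per_donor, donor_affected = {}, {}
    for d in donors:
        per_donor[d], donor_affected[d] = donor_block(
            [r for r in mapped if r.donor == d]
        )

    overlaps: dict[str, int] = {}
    for a, b in combinations(donors, 2):
        overlaps[f"{a}&{b}"] = len(donor_affected[a] & donor_affected[b])
    if len(donors) >= 3:
        inter = donor_affected[donors[0]]
        for d in donors[1:]:
            inter = inter & donor_affected[d]
        overlaps["&".join(donors)] = len(inter)

    pooled_keys: frozenset[str] = frozenset()
    for g in hit_genes:
        pooled_keys |= impacts[g].affected_keys

    summary = {
        "n_insertions": len(insertions),
        "n_insertions_mapped": len(mapped),
        "n_unmapped_genes": len(unmapped),
        "n_genes_hit": len(hit_genes),
        "n_reactions_hit": len(reactions_hit),
        "n_buffered": len(buffered),
        "n_effective": len(effective),
        "n_impact": len(impact_genes),
        "n_no_impact": len(effective) - len(impact_genes),
        "n_effective_blocked": len(blocked),
        "n_affected_metabolites": len(pooled_keys),
        "overlaps": overlaps,
    }
    return ScanResult(
        impacts=impacts,
        buffered_genes=frozenset(buffered),
        effective_genes=frozenset(effective),
        unmapped_genes=unmapped,
        summary=summary,
        per_donor=per_donor,
        donor_affected=donor_affected,
    )
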