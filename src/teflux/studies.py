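"""Pre-registered synthetic study designs.

Three fixed designs exercise the pipeline end to end:

``toy``
    A small mixed network (sole-gene, isozyme and complex rules) whose
    planted effective-gene set and gene-to-metabolite impact map the full
    LP screen must recover exactly.

``calibration``
    A null study: insertions drawn uniformly over genes (bias 0), disease
    maps unrelated to the truth, equal planted target-site counts per gene
    so the site-weighted Monte Carlo null coincides with the insertion
    generator.  Enrichment p-values across replicates must be uniform.
    The network is 40 sole-gene chains of length 8 and the null statistic
    is scored against large (3/4 of the key universe) disease sets; both
    choices keep the count statistic well spread out, which is what makes a
    uniformity check on the inherently discrete empirical p meaningful.

``power``
    A planted-signal study: 80% of conversion steps are isozyme-buffered,
    insertions target effective genes only (bias 1), and one disease's
    metabolite set is drawn from the truly-affected pool.  The planted
    disease must come out significant in nearly every replicate.

The enrichment replicates score genes through the analytically known
impact map of the chain truth (identical to what the LP screen computes on
these networks, as the toy end-to-end test verifies); this keeps hundreds
of replicates desk-sized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import enrichment_test
from .sites import TargetSiteIndex, build_site_index
from .synth import (
    SyntheticTruth,
    make_disease_map,
    make_gene_sequences,
    make_insertions,
    make_toy_network,
)

__all__ = ["StudyDesign", "DESIGNS", "build_study", "replicate_pvalues"]

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class StudyDesign:
    name: str
    n_chains: int
    chain_length: int
    isozyme_fraction: float
    complex_fraction: float
    sites_per_gene: int
    sequence_length: int
    insertions_per_donor: int
    donors: tuple[str, ...]
    effective_bias: float
    n_diseases: int
    disease_set_size: int
    plant_disease: bool
    n_samples: int  # Monte Carlo samples per enrichment run


DESIGNS: dict[str, StudyDesign] = {
    "toy": StudyDesign(
        name="toy", n_chains=3, chain_length=4,
        isozyme_fraction=0.25, complex_fraction=0.25,
        sites_per_gene=2, sequence_length=120,
        insertions_per_donor=0, donors=("A", "B", "C"), effective_bias=0.0,
        n_diseases=3, disease_set_size=5, plant_disease=True, n_samples=2000,
    ),
    "calibration": StudyDesign(
        name="calibration", n_chains=40, chain_length=8,
        isozyme_fraction=0.0, complex_fraction=0.0,
        sites_per_gene=3, sequence_length=150,
        insertions_per_donor=80, donors=("A",), effective_bias=0.0,
        n_diseases=3, disease_set_size=240, plant_disease=False, n_samples=500,
    ),
    "power": StudyDesign(
        name="power", n_chains=40, chain_length=8,
        isozyme_fraction=0.8, complex_fraction=0.0,
        sites_per_gene=3, sequence_length=150,
        insertions_per_donor=80, donors=("A",), effective_bias=1.0,
        n_diseases=3, disease_set_size=40, plant_disease=True, n_samples=500,
    ),
}


@dataclass
class StudyBundle:
    design: StudyDesign
    model: object
    truth: SyntheticTruth
    sequences: dict[str, str]
    index: TargetSiteIndex
    dmap: dict[str, frozenset[str]]


def build_study(name: str, seed: int) -> StudyBundle:
    """Instantiate a design: network + truth, motif-planted sequences, the
    target-site index and the disease map.  Insertions are drawn per
    replicate, not here."""
    design = DESIGNS[name]
    rng = np.random.default_rng(seed)
    s_model, s_seq, s_map = rng.integers(0, _SEED_CAP, size=3)
    model, truth = make_toy_network(
        design.n_chains, design.chain_length,
        design.isozyme_fraction, design.complex_fraction, seed=int(s_model),
    )
    sequences, _ = make_gene_sequences(
        truth.genes, length=design.sequence_length,
        planted_sites_per_gene=design.sites_per_gene, seed=int(s_seq),
    )
    index = build_site_index(sequences, model.genes)
    dmap, truth2 = make_disease_map(
        truth.metabolite_keys, n_diseases=design.n_diseases,
        set_size=design.disease_set_size,
        truth=truth, plant=design.plant_disease, seed=int(s_map),
    )
    if truth2 is not None:
        truth = truth2
    return StudyBundle(design, model, truth, sequences, index, dmap)


def default_insertions(bundle: StudyBundle, seed: int):
    """The design's insertion table: random biased draws, or (when the
    design sets insertions_per_donor to 0) exhaustive one-per-gene coverage
    so a screen visits every planted gene."""
    from .synth import exhaustive_insertions, make_insertions

    design = bundle.design
    if design.insertions_per_donor:
        return make_insertions(
            bundle.truth, donors=design.donors,
            insertions_per_donor=design.insertions_per_donor,
            effective_bias=design.effective_bias, seed=seed,
        )
    return exhaustive_insertions(bundle.truth, design.donors)


def write_study_bundle(bundle: StudyBundle, outdir, seed: int) -> dict[str, str]:
    """Write the study's inputs (SBML model, FASTA, insertion TSV, disease
    map TSV) to *outdir*; returns the paths."""
    from pathlib import Path

    from .disease import write_disease_map
    from .sbml_io import write_sbml
    from .sites import write_fasta
    from .synth import write_insertions

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": str(out / "model.xml"),
        "fasta": str(out / "genes.fasta"),
        "insertions": str(out / "insertions.tsv"),
        "disease_map": str(out / "disease_map.tsv"),
    }
    write_sbml(bundle.model, paths["model"])
    write_fasta(bundle.sequences, paths["fasta"])
    write_insertions(default_insertions(bundle, seed), paths["insertions"])
    write_disease_map(bundle.dmap, paths["disease_map"])
    return paths


def replicate_pvalues(
    name: str,
    n_replicates: int,
    seed: int,
    disease: str | None = None,
) -> np.ndarray:
    """Run the enrichment test over independently re-drawn insertion sets
    and fresh Monte Carlo nulls; return one p-value per replicate for the
    tracked disease (the planted one if the design plants, else the first).
    """
    bundle = build_study(name, seed)
    design = bundle.design
    if disease is None:
        disease = bundle.truth.planted_disease or sorted(bundle.dmap)[0]
    rng = np.random.default_rng(seed + 1)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        s_ins, s_mc = (int(v) for v in rng.integers(0, _SEED_CAP, size=2))
        records = make_insertions(
            bundle.truth, donors=design.donors,
            insertions_per_donor=design.insertions_per_donor,
            effective_bias=design.effective_bias, seed=s_ins,
        )
        observed = [rec.gene for rec in records]
        results = enrichment_test(
            observed, dict(bundle.truth.gene_affected), bundle.dmap,
            bundle.index, n_samples=design.n_samples, seed=s_mc,
        )
        pvals[r] = next(res.p for res in results if res.disease == disease)
    return pvals
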