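"""End-to-end orchestration: model -> knockdown screen -> enrichment.

``run_all`` chains the stages of the analysis and writes TSV reports with
``#``-prefixed metadata headers: the gene-impact long table, the summary
counts (pooled, per donor, and donor overlaps), the disease-enrichment
table, and a YAML run-metadata file.  Every payload is a pure function of
(inputs, parameters, seed); timestamps and runtimes appear only in the
metadata file so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .disease import DiseaseMap, load_disease_map, load_synonyms
from .enrichment import enrichment_test, write_enrichment_tsv
from .knockdown import (
    KnockdownConfig,
    ScanResult,
    read_insertions,
    scan_insertions,
)
from .model import MetabolicModel
from .sbml_io import load_sbml
from .sites import build_site_index, read_fasta

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "write_impact_tsv", "write_summary_tsv"]


@dataclass
class RunConfig:
    model_path: str
    insertions_path: str
    output_dir: str
    fasta_path: str | None = None
    disease_map_path: str | None = None
    synonyms_path: str | None = None
    fold_reduction: float = 70.0
    max_mismatch: int = 1
    n_samples: int = 100_000
    seed: int = 0
    optimality_fraction: float = 0.0
    per_donor_enrichment: bool = False

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def knockdown_config(self) -> KnockdownConfig:
        return KnockdownConfig(
            fold_reduction=self.fold_reduction,
            optimality_fraction=self.optimality_fraction,
        )

    def header(self) -> list[str]:
        return [
            f"teflux {__version__}",
            f"seed={self.seed} fold_reduction={self.fold_reduction} "
            f"max_mismatch={self.max_mismatch} n_samples={self.n_samples} "
            f"optimality_fraction={self.optimality_fraction}",
            f"model={self.model_path}",
        ]


def write_impact_tsv(scan: ScanResult, path: str, header: list[str]) -> None:
    """Gene x metabolite impact matrix in long form."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tmetabolite_id\tcompartment\tbaseline\tperturbed\t"
                 "relative_drop\n")
        for gene in sorted(scan.impacts):
            for met, comp, base, pert in scan.impacts[gene].affected:
                fh.write(f"{gene}\t{met}\t{comp}\t{base:.6g}\t{pert:.6g}\t"
                         f"{(base - pert) / base:.6g}\n")


def write_summary_tsv(scan: ScanResult, path: str, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("scope\tstatistic\tvalue\n")
        for k, v in scan.summary.items():
            if k == "overlaps":
                continue
            fh.write(f"pooled\t{k}\t{v}\n")
        for donor in sorted(scan.per_donor):
            for k, v in scan.per_donor[donor].items():
                fh.write(f"donor:{donor}\t{k}\t{v}\n")
        for pair, v in scan.summary["overlaps"].items():
            fh.write(f"overlap:{pair}\taffected_metabolites\t{v}\n")


def _stage(name: str, fn, timings: dict):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    return out


def run_all(config: RunConfig) -> dict:
    """Run the complete analysis; returns a dict with in-memory results and
    the paths of every report written.

    The enrichment stage is skipped with an explicit notice when the FASTA
    or the disease map is not supplied; earlier outputs are still produced.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()
    timings: dict[str, float] = {}
    notices: list[str] = []
    paths: dict[str, str] = {}

    model: MetabolicModel = _stage(
        "load_model", lambda: load_sbml(config.model_path), timings
    )
    insertions = _stage(
        "load_insertions", lambda: read_insertions(config.insertions_path), timings
    )
    scan = _stage(
        "knockdown_scan",
        lambda: scan_insertions(model, insertions, config.knockdown_config()),
        timings,
    )
    paths["impact"] = str(outdir / "gene_impact.tsv")
    write_impact_tsv(scan, paths["impact"], header)
    paths["summary"] = str(outdir / "summary.tsv")
    write_summary_tsv(scan, paths["summary"], header)

    enrichment = None
    if config.fasta_path and config.disease_map_path:
        sequences = _stage(
            "load_fasta", lambda: read_fasta(config.fasta_path), timings
        )
        index = _stage(
            "site_index",
            lambda: build_site_index(sequences, model.genes, config.max_mismatch),
            timings,
        )
        dmap: DiseaseMap = _stage(
            "load_disease_map",
            lambda: load_disease_map(config.disease_map_path), timings,
        )
        synonyms = (
            load_synonyms(config.synonyms_path) if config.synonyms_path else None
        )
        impact_lookup = {
            g: gi.affected_keys for g, gi in scan.impacts.items()
        }
        observed = [r.gene for r in insertions if r.gene in model.genes]
        enrichment = _stage(
            "enrichment",
            lambda: enrichment_test(
                observed, impact_lookup, dmap, index,
                n_samples=config.n_samples, seed=config.seed, synonyms=synonyms,
            ),
            timings,
        )
        paths["enrichment"] = str(outdir / "enrichment.tsv")
        write_enrichment_tsv(enrichment, paths["enrichment"], header)
    else:
        notices.append(
            "enrichment stage skipped: fasta_path and/or disease_map_path "
            "not supplied"
        )
        log.warning(notices[-1])

    metadata = {
        "teflux_version": __version__,
        "config": asdict(config),
        "model_stats": model.stats(),
        "stage_runtimes_s": timings,
        "notices": notices,
    }
    paths["metadata"] = str(outdir / "run_metadata.yaml")
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)

    return {
        "model": model,
        "scan": scan,
        "enrichment": enrichment,
        "paths": paths,
        "notices": notices,
    }
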