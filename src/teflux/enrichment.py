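"""Monte Carlo enrichment test for disease-linked affected metabolites.

The observed statistic for a disease is the number of its metabolites found
in the union of affected-metabolite sets over the genes actually hit by
insertions.  The null redistributes the same number of insertions uniformly
across all endonuclease target sites (genes weighted by site count), scores
every random sample identically, and reports the empirical one-sided
p-value

    p = (n + 1) / (N + 1)

with *n* the number of random samples whose statistic is at least the
observed one and *N* the total number of samples.  All diseases are scored
on the same shared sample stream, and a gene hit several times in one
sample contributes its affected set once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .disease import DiseaseMap, normalize_key
from .sites import TargetSiteIndex, sample_insertion_sets

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_test", "write_enrichment_tsv"]


@dataclass(frozen=True)
class EnrichmentResult:
    disease: str
    observed: int
    expected: float   # null mean
    sd: float         # null SD
    n: int            # samples with statistic >= observed
    n_samples: int    # N
    p: float          # (n+1)/(N+1)
    metabolites: tuple[str, ...] = ()  # the observed disease-linked keys

    def __post_init__(self) -> None:
        assert self.n <= self.n_samples
        assert 0 < self.p <= 1


def _build_masks(
    impact_lookup: dict[str, frozenset[str]],
    dmap: DiseaseMap,
    synonyms: dict[str, str] | None,
):
    """Integer-bitmask encoding of affected-key sets and disease sets over a
    shared key universe (exact, just fast set algebra)."""

    def norm(keys):
        out = {normalize_key(k) for k in keys}
        if synonyms:
            out = {synonyms.get(k, k) for k in out}
        return out

    gene_keys = {g: norm(keys) for g, keys in impact_lookup.items()}
    dmap = {d: {normalize_key(k) for k in keys} for d, keys in dmap.items()}
    universe = sorted(set().union(*gene_keys.values(), *dmap.values())
                      if gene_keys or dmap else set())
    bit = {k: 1 << i for i, k in enumerate(universe)}
    gene_mask = {}
    for g, keys in gene_keys.items():
        m = 0
        for k in keys:
            m |= bit[k]
        gene_mask[g] = m
    disease_mask = {}
    for d, keys in dmap.items():
        m = 0
        for k in keys:
            m |= bit[k]
        disease_mask[d] = m
    return gene_mask, disease_mask, bit


def enrichment_test(
    observed_genes: list[str],
    impact_lookup: dict[str, frozenset[str]],
    dmap: DiseaseMap,
    index: TargetSiteIndex,
    m: int | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    synonyms: dict[str, str] | None = None,
    replace: bool = True,
    return_null: bool = False,
):
    """Per-disease enrichment of affected metabolites against the
    target-site null.

    observed_genes: the genes hit by real insertions (a multiset; a gene
        listed twice still contributes its affected set once).
    impact_lookup: gene -> affected compartment-free metabolite keys, as
        computed by the knockdown screen; genes absent from it contribute
        nothing.
    m: insertions per random sample; defaults to ``len(observed_genes)``.

    Returns a list of :class:`EnrichmentResult` sorted by disease name (and
    the per-disease null statistic arrays when *return_null* is set).
    """
    if not dmap:
        raise ValueError("empty disease map")
    empty = [d for d, keys in dmap.items() if not keys]
    if empty:
        log.warning("diseases with no metabolites excluded: %s", empty)
        dmap = {d: k for d, k in dmap.items() if k}
    if m is None:
        m = len(observed_genes)

    gene_mask, disease_mask, bit = _build_masks(impact_lookup, dmap, synonyms)
    inv_bit = {v: k for k, v in bit.items()}

    def union_mask(genes) -> int:
        u = 0
        for g in set(genes):
            u |= gene_mask.get(g, 0)
        return u

    observed_mask = union_mask(observed_genes)
    diseases = sorted(dmap)
    observed_stat = {d: (observed_mask & disease_mask[d]).bit_count()
                     for d in diseases}

    null_stats = {d: np.empty(n_samples, dtype=np.int32) for d in diseases}
    for i, sample in enumerate(
        sample_insertion_sets(index, m, n_samples, seed, replace=replace)
    ):
        u = union_mask(sample)
        for d in diseases:
            null_stats[d][i] = (u & disease_mask[d]).bit_count()

    results = []
    for d in diseases:
        stats = null_stats[d]
        obs = observed_stat[d]
        n_ge = int((stats >= obs).sum())
        mean = float(stats.mean())
        sd = float(stats.std(ddof=0))
        hit_mask = observed_mask & disease_mask[d]
        mets = tuple(sorted(
            inv_bit[1 << i] for i in range(hit_mask.bit_length())
            if hit_mask >> i & 1
        ))
        results.append(EnrichmentResult(
            disease=d, observed=obs, expected=mean, sd=sd,
            n=n_ge, n_samples=n_samples, p=(n_ge + 1) / (n_samples + 1),
            metabolites=mets,
        ))
    if return_null:
        return results, null_stats
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str,
                         header_lines: list[str] | None = None) -> None:
    """Disease-by-disease table in the Expected / SD / Observed / P layout."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("disease\texpected\tsd\tobserved\tp\tmetabolites\n")
        for r in results:
            fh.write(
                f"{r.disease}\t{r.expected:.3f}\t{r.sd:.3f}\t{r.observed}\t"
                f"{r.p:.6g}\t{','.join(r.metabolites)}\n"
            )
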