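"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: toy stoichiometric
networks (independent linear chains with isozyme / complex / sole-gene
rules, unit stoichiometry, capacity 10 — all optima hand-computable), gene
sequences with exactly-planted endonuclease target sites on a motif-free
background, multi-donor insertion tables with a tunable bias toward
effective genes, and disease maps with an optionally planted enriched
disease.  Each generator is a pure function of its seed, and the recorded
:class:`SyntheticTruth` is what the end-to-end tests recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .knockdown import InsertionRecord
from .model import MetabolicModel, Metabolite, make_reaction
from .sites import MOTIF, MOTIF_RC, Site, scan_target_sites

CAPACITY = 10.0
EXPORT_CAP = 1000.0

__all__ = [
    "SyntheticTruth",
    "make_toy_network",
    "make_gene_sequences",
    "make_insertions",
    "make_disease_map",
    "write_insertions",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    genes: tuple[str, ...] = ()
    effective_genes: frozenset[str] = frozenset()
    buffered_genes: frozenset[str] = frozenset()
    gene_affected: dict[str, frozenset[str]] = field(default_factory=dict)
    metabolite_keys: tuple[str, ...] = ()
    planted_sites: dict[str, tuple[Site, ...]] = field(default_factory=dict)
    planted_disease: str | None = None

    def __post_init__(self) -> None:
        assert not (self.effective_genes & self.buffered_genes)

    @property
    def affected_pool(self) -> frozenset[str]:
        """All metabolite keys truly affected by some effective gene."""
        pool: frozenset[str] = frozenset()
        for g in self.effective_genes:
            pool |= self.gene_affected.get(g, frozenset())
        return pool


# ---------------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------------

def make_toy_network(
    n_chains: int = 3,
    chain_length: int = 4,
    isozyme_fraction: float = 0.25,
    complex_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Independent linear chains ``-> m1 -> m2 -> ... -> mL ->`` with unit
    stoichiometry and capacity 10.

    Each internal conversion gets a GPR drawn from {sole gene, OR-pair
    (isozymes, both buffered), AND-pair (complex, both effective)} with the
    given fractions.  Truth: an effective gene on step j affects exactly the
    metabolites downstream of it (positions j+1 .. L), each with baseline
    production 10.
    """
    if n_chains < 1 or chain_length < 2:
        raise ValueError("need at least one chain of length >= 2")
    if isozyme_fraction + complex_fraction > 1:
        raise ValueError("isozyme_fraction + complex_fraction must be <= 1")
    rng = np.random.default_rng(seed)

    metabolites, reactions = [], []
    genes: list[str] = []
    effective, buffered = set(), set()
    gene_affected: dict[str, frozenset[str]] = {}
    keys: list[str] = []

    for ci in range(n_chains):
        met_ids = [f"m{ci}x{j}_c" for j in range(1, chain_length + 1)]
        chain_keys = [f"m{ci}x{j}" for j in range(1, chain_length + 1)]
        keys.extend(chain_keys)
        for mid in met_ids:
            metabolites.append(Metabolite(mid, compartment="c"))
        reactions.append(
            make_reaction(f"U{ci}", {met_ids[0]: 1.0}, 0.0, CAPACITY)
        )
        reactions.append(
            make_reaction(f"X{ci}", {met_ids[-1]: -1.0}, 0.0, EXPORT_CAP)
        )
        for j in range(chain_length - 1):
            downstream = frozenset(chain_keys[j + 1 :])
            u = rng.random()
            base = f"g{ci}_{j}"
            if u < complex_fraction:
                ga, gb = base + "a", base + "b"
                rule = f"({ga} and {gb})"
                for g in (ga, gb):
                    effective.add(g)
                    gene_affected[g] = downstream
                genes += [ga, gb]
            elif u < complex_fraction + isozyme_fraction:
                ga, gb = base + "a", base + "b"
                rule = f"({ga} or {gb})"
                buffered.update((ga, gb))
                genes += [ga, gb]
            else:
                rule = base
                effective.add(base)
                gene_affected[base] = downstream
                genes.append(base)
            reactions.append(
                make_reaction(
                    f"R{ci}_{j}",
                    {met_ids[j]: -1.0, met_ids[j + 1]: 1.0},
                    0.0,
                    CAPACITY,
                    gpr=rule,
                )
            )

    model = MetabolicModel(metabolites, reactions, model_id=f"toy_s{seed}")
    truth = SyntheticTruth(
        genes=tuple(genes),
        effective_genes=frozenset(effective),
        buffered_genes=frozenset(buffered),
        gene_affected=gene_affected,
        metabolite_keys=tuple(keys),
    )
    return model, truth


# ---------------------------------------------------------------------------
# sequences with planted target sites
# ---------------------------------------------------------------------------

_GC = np.frombuffer(b"GC", dtype=np.uint8)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_GAP = 16  # planted hexamers this far apart share no 6-mer window


def _scrub(arr: np.ndarray, planted: list[Site], rng,
           max_mismatch: int, max_iter: int = 200) -> None:
    """Mutate background bases (never inside a planted hexamer) until the
    scanner finds exactly the planted sites (in place)."""
    prot = np.zeros(len(arr), dtype=bool)
    for s in planted:
        prot[s.position : s.position + 6] = True
    planted_pairs = {(s.position, s.strand) for s in planted}
    for _ in range(max_iter):
        hits = scan_target_sites(arr.tobytes().decode("ascii"), max_mismatch)
        spurious = [s for s in hits if (s.position, s.strand) not in planted_pairs]
        if not spurious:
            return
        for s in spurious:
            window = np.arange(s.position, s.position + 6)
            free = window[~prot[window]]
            if len(free) == 0:  # distinct positions always leave a free base
                raise RuntimeError("unscrubbable spurious site inside plant")
            arr[free] = rng.choice(_GC, size=len(free))
    raise RuntimeError("failed to scrub background of spurious target sites")


def make_gene_sequences(
    genes: list[str] | tuple[str, ...],
    length: int = 150,
    planted_sites_per_gene: int | dict[str, int] = 2,
    gc_content: float = 0.5,
    seed: int = 0,
    max_mismatch: int = 1,
) -> tuple[dict[str, str], dict[str, tuple[Site, ...]]]:
    """Per-gene sequences whose only target sites are the planted ones.

    The background is rejection-scrubbed to contain no window within
    *max_mismatch* of the motif on either strand, then exact TTAAAA (+) or
    TTTTAA (−) hexamers are planted at recorded, well-separated positions.
    Scanning the output finds exactly the planted sites.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    counts = (
        planted_sites_per_gene
        if isinstance(planted_sites_per_gene, dict)
        else {g: int(planted_sites_per_gene) for g in genes}
    )
    seqs: dict[str, str] = {}
    planted: dict[str, tuple[Site, ...]] = {}
    for g in genes:
        k = counts.get(g, 0)
        if length < 6 * (k + 1):
            raise ValueError(
                f"gene {g!r}: length {length} too short for {k} planted sites"
            )
        n_slots = (length - 6) // _MIN_GAP + 1
        if k > n_slots:
            raise ValueError(
                f"gene {g!r}: cannot place {k} non-overlapping sites in "
                f"length {length}"
            )
        arr = rng.choice(_BASES, size=length, p=p)
        slot_ids = rng.choice(n_slots, size=k, replace=False)
        positions = sorted(int(s) * _MIN_GAP for s in slot_ids)
        sites = []
        for pos in positions:
            strand = "+" if rng.random() < 0.5 else "-"
            hexamer = MOTIF if strand == "+" else MOTIF_RC
            arr[pos : pos + 6] = np.frombuffer(hexamer.encode(), dtype=np.uint8)
            sites.append(Site(pos, strand, 0))
        _scrub(arr, sites, rng, max_mismatch)
        seq = arr.tobytes().decode("ascii")
        found = scan_target_sites(seq, max_mismatch)
        if {(s.position, s.strand) for s in found} != {
            (s.position, s.strand) for s in sites
        }:
            raise RuntimeError(f"gene {g!r}: planted-site verification failed")
        seqs[g] = seq
        planted[g] = tuple(sites)
    return seqs, planted


# ---------------------------------------------------------------------------
# insertion tables and disease maps
# ---------------------------------------------------------------------------

def make_insertions(
    truth: SyntheticTruth,
    donors: tuple[str, ...] = ("A", "B", "C"),
    insertions_per_donor: int = 10,
    effective_bias: float = 0.0,
    seed: int = 0,
) -> list[InsertionRecord]:
    """Random insertion records per donor.

    ``effective_bias`` tilts the per-gene probability toward effective
    genes: 0 is the uniform null over all genes, 1 draws only effective
    genes (uniformly among them).
    """
    if not 0.0 <= effective_bias <= 1.0:
        raise ValueError("effective_bias must lie in [0, 1]")
    genes = list(truth.genes)
    if not genes:
        raise ValueError("truth has no genes")
    eff = [g in truth.effective_genes for g in genes]
    n_eff = sum(eff)
    if effective_bias > 0 and n_eff == 0:
        raise ValueError("no effective genes to bias toward")
    w = np.full(len(genes), (1 - effective_bias) / len(genes))
    if n_eff:
        w += effective_bias * np.array(eff, dtype=float) / n_eff
    w /= w.sum()
    rng = np.random.default_rng(seed)
    records = []
    for d in donors:
        picks = rng.choice(len(genes), size=insertions_per_donor, p=w)
        records += [InsertionRecord(d, genes[i]) for i in picks]
    return records


def exhaustive_insertions(
    truth: SyntheticTruth, donors: tuple[str, ...] = ("A", "B", "C")
) -> list[InsertionRecord]:
    """One insertion per gene, donors assigned round-robin — the coverage
    pattern used when a screen must visit every planted gene."""
    return [
        InsertionRecord(donors[i % len(donors)], g)
        for i, g in enumerate(sorted(truth.genes))
    ]


def write_insertions(records: list[InsertionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("donor\tgene_id\n")
        for r in records:
            fh.write(f"{r.donor}\t{r.gene}\n")


def make_disease_map(
    metabolite_keys: list[str] | tuple[str, ...],
    n_diseases: int = 5,
    set_size: int = 10,
    truth: SyntheticTruth | None = None,
    plant: bool = False,
    seed: int = 0,
) -> tuple[dict[str, frozenset[str]], SyntheticTruth | None]:
    """Random disease -> metabolite-set map.

    With ``plant=True`` one extra disease's set is drawn from the
    truly-affected metabolite pool of *truth*, so the enrichment test should
    flag it when insertions favour effective genes.  Returns the map and the
    updated truth (or None when no truth was given).
    """
    if set_size > len(metabolite_keys):
        raise ValueError("set_size exceeds the number of metabolite keys")
    rng = np.random.default_rng(seed)
    keys = np.array(sorted(metabolite_keys), dtype=object)
    dmap: dict[str, frozenset[str]] = {}
    for i in range(n_diseases):
        picks = rng.choice(len(keys), size=set_size, replace=False)
        dmap[f"disease_{i:02d}"] = frozenset(keys[picks])
    if plant:
        if truth is None:
            raise ValueError("planting requires a SyntheticTruth")
        pool = sorted(truth.affected_pool)
        if not pool:
            raise ValueError("cannot plant a disease: affected pool is empty")
        size = min(set_size, len(pool))
        picks = rng.choice(len(pool), size=size, replace=False)
        dmap["planted_disease"] = frozenset(pool[i] for i in picks)
        truth = replace(truth, planted_disease="planted_disease")
    return dmap, truth
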