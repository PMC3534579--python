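"""L1 endonuclease target-site scanning and random insertion sampling.

The L1 endonuclease preferentially nicks DNA at the TT|AAAA hexamer; the
scanner reports every position where a 6-mer window matches TTAAAA within a
Hamming distance (default 1) on either strand.  A reverse-strand hit is a
window whose reverse complement matches TTAAAA, i.e. a forward match to
TTTTAA.  ``N`` bases match nothing and count as mismatches.

The site index over a gene set is the substrate for the Monte Carlo null:
insertions are redistributed uniformly across all target sites, which weights
genes by their site counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Site",
    "TargetSiteIndex",
    "MOTIF",
    "scan_target_sites",
    "build_site_index",
    "sample_insertion_sets",
    "read_fasta",
    "write_fasta",
]

MOTIF = "TTAAAA"
MOTIF_RC = "TTTTAA"  # reverse complement of MOTIF read on the forward strand
ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Site:
    position: int     # 0-based offset of the 6-mer window
    strand: str       # "+" or "-"
    mismatches: int


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid nucleotide {sequence[pos]!r} at position {pos}"
        )
    return arr


def _window_mismatches(arr: np.ndarray, motif: str) -> np.ndarray:
    """Hamming distance of every 6-mer window to *motif* (N never matches)."""
    k = len(motif)
    n_win = len(arr) - k + 1
    mism = np.zeros(n_win, dtype=np.int8)
    pattern = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    for off in range(k):
        col = arr[off : off + n_win]
        mism += (col != pattern[off]) | (col == ord("N"))
    return mism


def scan_target_sites(sequence: str, max_mismatch: int = 1) -> list[Site]:
    """All endonuclease target sites in *sequence*, both strands, within
    ``max_mismatch`` of the TTAAAA hexamer.  Overlapping sites are all
    reported; a window may hit on both strands."""
    if len(sequence) < 6:
        return []
    arr = _encode(sequence)
    out: list[Site] = []
    fwd = _window_mismatches(arr, MOTIF)
    rev = _window_mismatches(arr, MOTIF_RC)
    for pos in range(len(fwd)):
        if fwd[pos] <= max_mismatch:
            out.append(Site(pos, "+", int(fwd[pos])))
        if rev[pos] <= max_mismatch:
            out.append(Site(pos, "-", int(rev[pos])))
    return out


@dataclass(frozen=True)
class TargetSiteIndex:
    """Per-gene endonuclease target sites; genes with zero sites are kept."""

    sites: dict[str, tuple[Site, ...]]
    max_mismatch: int

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def site_counts(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.sites.items()}


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reader returning id -> sequence (first token of the
    header line is the id)."""
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_site_index(
    sequences: dict[str, str],
    model_genes: set[str] | frozenset[str],
    max_mismatch: int = 1,
) -> TargetSiteIndex:
    """Scan the gene sequences that are present in the model.

    Sequences whose id is not a model gene are excluded with a warning;
    model genes lacking a sequence are logged as coverage gaps but simply
    absent from the index.
    """
    if not sequences:
        raise ValueError("empty FASTA: no sequences to scan")
    extra = sorted(set(sequences) - set(model_genes))
    if extra:
        log.warning("%d FASTA sequences not in model gene set (excluded): %s%s",
                    len(extra), ", ".join(extra[:5]), "..." if len(extra) > 5 else "")
    missing = sorted(set(model_genes) - set(sequences))
    if missing:
        log.info("%d model genes lack sequences (no target sites indexed)",
                 len(missing))
    sites = {
        g: tuple(scan_target_sites(seq, max_mismatch))
        for g, seq in sequences.items()
        if g in model_genes
    }
    return TargetSiteIndex(sites=sites, max_mismatch=max_mismatch)


def sample_insertion_sets(
    index: TargetSiteIndex,
    m: int,
    n_samples: int,
    seed: int,
    replace: bool = True,
):
    """Yield ``n_samples`` random insertion samples: each draws *m* target
    sites uniformly (with replacement by default) over all indexed sites and
    returns the multiset of hit genes as a tuple.

    The stream is a pure function of the seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    genes = sorted(g for g, v in index.sites.items() if v)
    counts = np.array([len(index.sites[g]) for g in genes], dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("index contains no target sites")
    if not replace and m > total:
        raise ValueError(f"cannot draw {m} sites without replacement from {total}")
    gene_of_site = np.repeat(np.arange(len(genes)), counts)
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes, dtype=object)
    for _ in range(n_samples):
        picks = rng.choice(total, size=m, replace=replace)
        yield tuple(gene_arr[gene_of_site[picks]])
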