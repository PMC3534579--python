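"""Metabolite-disease association tables.

A disease map links disease names to sets of metabolite keys (case-folded,
compartment-free), emulating the metabolite-disease associations of
metabolome databases.  An optional synonym table translates model metabolite
keys to map keys, since naming conventions differ between reconstructions
and databases.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

from .model import strip_compartment

log = logging.getLogger(__name__)

__all__ = ["DiseaseMap", "load_disease_map", "load_synonyms", "count_linked",
           "normalize_key", "write_disease_map"]

DiseaseMap = dict[str, frozenset[str]]


def normalize_key(key: str) -> str:
    """Case-folded, compartment-stripped metabolite key."""
    return strip_compartment(key.strip()).casefold()


def load_disease_map(path: str) -> DiseaseMap:
    """Read a TSV with header ``disease<TAB>metabolite_key``; duplicate rows
    collapse, keys are normalized."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["disease", "metabolite_key"]:
            raise ValueError(
                f"{path}: expected header 'disease\\tmetabolite_key', got {header!r}"
            )
        n_rows = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed row {line!r}")
            pairs.add((fields[0].strip(), normalize_key(fields[1])))
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: disease map has no rows")
    dmap: dict[str, set[str]] = {}
    for disease, key in pairs:
        dmap.setdefault(disease, set()).add(key)
    log.info("disease map: %d rows, %d diseases, %d distinct pairs",
             n_rows, len(dmap), len(pairs))
    return {d: frozenset(s) for d, s in dmap.items()}


def write_disease_map(dmap: DiseaseMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("disease\tmetabolite_key\n")
        for disease in sorted(dmap):
            for key in sorted(dmap[disease]):
                fh.write(f"{disease}\t{key}\n")


def load_synonyms(path: str) -> dict[str, str]:
    """Optional model-key -> map-key translation TSV with header
    ``model_key<TAB>map_key``."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["model_key", "map_key"]:
            raise ValueError(
                f"{path}: expected header 'model_key\\tmap_key', got {header!r}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            out[normalize_key(a)] = normalize_key(b)
    return out


def count_linked(
    affected: Iterable[str],
    dmap: DiseaseMap,
    synonyms: dict[str, str] | None = None,
) -> dict[str, int]:
    """Per disease, how many of its metabolites are in the affected set.

    Input keys are normalized (and translated through *synonyms* if given),
    so compartment decoration on the affected keys does not matter.
    Diseases with no overlap are reported with 0.
    """
    keys = {normalize_key(k) for k in affected}
    if synonyms:
        keys = {synonyms.get(k, k) for k in keys}
    return {disease: len(keys & mets) for disease, mets in dmap.items()}
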