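"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible solutions with plain numpy linear algebra, the
GPR oracle evaluates rule strings with Python's own boolean operators, and
the motif oracle compares every window (and its reverse complement) to the
hexamer directly.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# LP: vertex enumeration over {S v = 0, lb <= v <= ub}
# ---------------------------------------------------------------------------

def enumerate_vertices(S: np.ndarray, bounds: list[tuple[float, float]],
                       tol: float = 1e-7) -> list[np.ndarray]:
    """All vertices of the (bounded) steady-state polytope: points where
    n - rank(S) coordinates sit at a bound and the rest solve S v = 0."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if S.size else 0
    verts = []
    for basis in combinations(range(n), r):
        SB = S[:, basis]
        if r and np.linalg.matrix_rank(SB) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for assignment in product(*[bounds[j] for j in nonbasic]):
            v = np.zeros(n)
            for j, val in zip(nonbasic, assignment):
                v[j] = val
            rhs = -S[:, nonbasic] @ np.array(assignment) if nonbasic else np.zeros(m)
            if r:
                xB, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
                if np.max(np.abs(SB @ xB - rhs), initial=0.0) > tol:
                    continue
                for j, val in zip(basis, xB):
                    v[j] = val
            elif np.max(np.abs(rhs), initial=0.0) > tol:
                continue
            if all(bounds[j][0] - tol <= v[j] <= bounds[j][1] + tol
                   for j in range(n)):
                verts.append(v)
    return verts


def brute_force_max_flux(S: np.ndarray, bounds, j_obj: int) -> float:
    """LP maximum of v[j_obj] over the steady-state polytope by enumerating
    its vertices (valid because all bounds are finite)."""
    verts = enumerate_vertices(S, bounds)
    if not verts:
        raise RuntimeError("no feasible vertex found")
    return max(v[j_obj] for v in verts)


def random_toy_lp(rng: np.random.Generator, n_reactions: int = 6,
                  n_metabolites: int = 3):
    """A random bounded network in which v = 0 is always feasible."""
    while True:
        S = rng.integers(-2, 3, size=(n_metabolites, n_reactions)).astype(float)
        mask = rng.random(S.shape) < 0.45
        S = S * mask
        if np.any(np.abs(S).sum(axis=0) > 0):
            break
    bounds = []
    for _ in range(n_reactions):
        lb = -10.0 if rng.random() < 0.5 else 0.0
        bounds.append((lb, 10.0))
    return S, bounds


# ---------------------------------------------------------------------------
# GPR: truth-table evaluation through Python's eval
# ---------------------------------------------------------------------------

def eval_rule_python(rule: str, present: set[str], genes: list[str]) -> bool:
    """Evaluate a GPR rule string with Python's boolean operators."""
    expr = rule
    for g in sorted(genes, key=len, reverse=True):
        expr = expr.replace(g, "True" if g in present else "False")
    return bool(eval(expr))  # noqa: S307 - trusted test fixture strings


def random_rule(rng: np.random.Generator, genes: list[str], depth: int = 0) -> str:
    """Random boolean rule over the given gene names."""
    if depth >= 3 or rng.random() < 0.35:
        return genes[rng.integers(len(genes))]
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    parts = [random_rule(rng, genes, depth + 1) for _ in range(k)]
    return "(" + op.join(parts) + ")"


def classify_by_truth_table(rules: dict[str, str], gene: str,
                            genes: list[str]) -> tuple[str, list[str]]:
    """Brute-force isozyme classification: evaluate every rule with all
    genes present except *gene*."""
    present = set(genes) - {gene}
    falsified = [
        rid for rid, rule in rules.items()
        if gene in rule.replace("(", " ").replace(")", " ").split()
        and not eval_rule_python(rule, present, genes)
    ]
    return ("buffered" if not falsified else "effective"), falsified


# ---------------------------------------------------------------------------
# motif scan: direct window comparison on both strands
# ---------------------------------------------------------------------------

def brute_force_sites(sequence: str, max_mismatch: int = 1) -> set[tuple]:
    """Every (position, strand, mismatches) where a 6-mer window matches
    TTAAAA within the distance on the forward strand or on its reverse
    complement; N matches nothing."""
    motif = "TTAAAA"
    seq = sequence.upper()
    out = set()
    for i in range(len(seq) - 5):
        window = seq[i : i + 6]
        d_fwd = sum(a != b or a == "N" for a, b in zip(window, motif))
        rc = window.translate(_COMPLEMENT)[::-1]
        d_rev = sum(a != b or a == "N" for a, b in zip(rc, motif))
        if d_fwd <= max_mismatch:
            out.add((i, "+", d_fwd))
        if d_rev <= max_mismatch:
            out.add((i, "-", d_rev))
    return out
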