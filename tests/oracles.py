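"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP path: linear programs are solved
by exhaustive vertex enumeration of the polytope {S v = 0, l <= v <= u}
(every LP optimum over a bounded polytope is attained at a vertex), and GPR
rules are evaluated by substituting truth values into the rule text and
handing it to Python's own boolean evaluator.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, List

import numpy as np


def enumerate_vertices(S: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                       tol: float = 1e-8) -> np.ndarray:
    """All vertices of {v : S v = 0, lower <= v <= upper} (n small).

    A vertex has n active constraints: r = rank(S) equalities plus n - r
    variables at a bound.  Enumerate every choice of fixed variables and
    bound sides, solve for the free ones, keep solutions that satisfy all
    constraints.
    """
    S = np.atleast_2d(np.asarray(S, float))
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    vertices = []
    for free in itertools.combinations(range(n), r):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < r:
            continue
        for sides in itertools.product((0, 1), repeat=len(fixed)):
            v = np.empty(n)
            for j, side in zip(fixed, sides):
                v[j] = upper[j] if side else lower[j]
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lower - tol) or np.any(v > upper + tol):
                continue
            vertices.append(np.clip(v, lower, upper))
    if not vertices:
        return np.empty((0, n))
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def lp_max(S, lower, upper, c) -> float:
    """Brute-force LP maximum of c.v over the steady-state box polytope."""
    V = enumerate_vertices(S, np.asarray(lower, float), np.asarray(upper, float))
    if V.shape[0] == 0:
        raise ValueError("infeasible polytope in oracle")
    return float(np.max(V @ np.asarray(c, float)))


def fva_ranges(S, lower, upper, floor_index=None, floor=None):
    """Coordinate-wise min/max over the polytope, optionally with an
    objective floor imposed as a tightened lower bound."""
    lower = np.asarray(lower, float).copy()
    upper = np.asarray(upper, float).copy()
    if floor_index is not None:
        lower[floor_index] = max(lower[floor_index], floor)
    V = enumerate_vertices(S, lower, upper)
    if V.shape[0] == 0:
        raise ValueError("infeasible polytope in oracle")
    return V.min(axis=0), V.max(axis=0)


def problem_matrices(problem):
    """Extract (S, lower, upper, reaction_ids) from a SteadyStateProblem."""
    return (
        problem.S.toarray(),
        problem.lower.copy(),
        problem.upper.copy(),
        list(problem.reaction_ids),
    )


_WORD_RE = re.compile(r"[^\s()]+")


def eval_gpr_text(text: str, knocked: Iterable[str]) -> bool:
    """Evaluate a GPR string by truth-value substitution + Python eval."""
    knocked = set(knocked)

    def sub(m):
        word = m.group(0)
        low = word.lower()
        if low in ("and", "or"):
            return low
        if low in ("unknown", "unknown_gene"):
            return "True"
        return "False" if word in knocked else "True"

    return bool(eval(_WORD_RE.sub(sub, text)))  # noqa: S307 - test oracle


def all_knockout_sets(genes: List[str], max_size=None):
    max_size = len(genes) if max_size is None else max_size
    for k in range(max_size + 1):
        yield from (set(c) for c in itertools.combinations(genes, k))
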