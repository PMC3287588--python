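"""Independent oracles used by the test suite.

The vertex-enumeration oracle solves small FBA problems (n <= 8 reactions)
by brute force: every vertex of {S v = 0, lb <= v <= ub} has a set of
variables tight at bounds whose complement is uniquely determined by the
mass-balance rows, so enumerating all lb/ub/free assignments visits every
vertex.  The oracle shares no code path with the HiGHS-based solver.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np

from phycoflux.core import CompartmentalizedModel, build_stoichiometric_matrix


def enumerate_vertex_optimum(
    model: CompartmentalizedModel, objective: str, sense: str = "max"
) -> Optional[float]:
    """Exhaustive vertex enumeration; returns the optimal objective or None
    when the polytope is empty."""
    S, met_ids, rxn_ids = build_stoichiometric_matrix(model)
    n = len(rxn_ids)
    assert n <= 8, "oracle is for small networks only"
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    obj = rxn_ids.index(objective)
    best: Optional[float] = None
    better = max if sense == "max" else min
    for assignment in itertools.product((0, 1, 2), repeat=n):
        v = np.where(np.array(assignment) == 0, lb, ub).astype(float)
        free = [j for j, a in enumerate(assignment) if a == 2]
        v[free] = 0.0
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A) < len(free):
                continue  # not a vertex: undetermined free block
            rhs = -S @ v
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = sol
        if np.max(np.abs(S @ v)) > 1e-9 if S.size else False:
            continue
        if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
            continue
        cand = float(v[obj])
        best = cand if best is None else better(best, cand)
    return best


def per_species_net_coefficients(stoichiometries, synonyms) -> dict:
    """Sum signed coefficients per canonical species — the oracle for
    synonym-merge coefficient accumulation."""
    out: dict = {}
    for mid, coeff in stoichiometries.items():
        canon = synonyms.get(mid, mid)
        out[canon] = out.get(canon, 0.0) + coeff
    return {k: v for k, v in out.items() if v != 0.0}
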