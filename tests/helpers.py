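"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they are checking: the
least-cost oracle enumerates simple paths by depth-first search (with a
cost bound for pruning, which does not affect exactness), and the circuit
oracles are series/parallel closed forms.
"""

from __future__ import annotations

import numpy as np


def brute_force_min_cost(cost_matrix, src: int, dst: int) -> float:
    """Exhaustive simple-path minimum cost between two nodes.

    ``cost_matrix`` is a symmetric scipy sparse matrix of edge costs.
    Returns inf when no path exists.
    """
    n = cost_matrix.shape[0]
    indptr, indices, data = cost_matrix.indptr, cost_matrix.indices, cost_matrix.data
    best = [np.inf]
    visited = np.zeros(n, dtype=bool)

    def dfs(v: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if v == dst:
            best[0] = acc
            return
        visited[v] = True
        for u, w in zip(indices[indptr[v]:indptr[v + 1]], data[indptr[v]:indptr[v + 1]]):
            if not visited[u]:
                dfs(int(u), acc + w)
        visited[v] = False

    dfs(src, 0.0)
    return best[0]


def chain_effective_resistance(potentials: np.ndarray, injection: float) -> float:
    """R_eff = V(source) / I for a ground fixed at 0."""
    return float(potentials[0] / injection)
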