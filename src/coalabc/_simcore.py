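"""Event-driven structured-coalescent core.

The hot loop lives here, jitted with numba: competing exponential clocks for
within-deme coalescence (rate k(k-1)/2 divided by the deme size in gene
copies) and per-lineage backward migration, interrupted by epoch boundaries
at which rate matrices switch and demes merge. Everything above this module
is plain numpy/Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_tree(
    seed: int,
    k_init: np.ndarray,  # (3,) int64 sampled gene copies per deme
    sizes: np.ndarray,  # (3,) float64 deme sizes in gene copies
    bounds: np.ndarray,  # (E,) float64 ascending epoch ends, last = inf
    migration: np.ndarray,  # (E, 3, 3) float64 backward per-lineage rates
    merge_from: np.ndarray,  # (E,) int64 deme folded at the epoch end (-1 none)
    merge_to: np.ndarray,  # (E,) int64 receiving deme
):
    """Simulate one gene genealogy; returns (parent, node_time, pop_counts).

    Nodes 0..n-1 are the sampled copies (deme-major order: all of deme 0,
    then 1, then 2); internal nodes are appended in coalescence-time order,
    so parent[v] > v for every non-root v. pop_counts[v, d] is the number of
    sampled copies from deme d below node v.
    """
    np.random.seed(seed)
    n = int(k_init[0] + k_init[1] + k_init[2])
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    pop_counts = np.zeros((n_nodes, 3), dtype=np.int64)

    act = np.empty((3, n), dtype=np.int64)
    k = np.zeros(3, dtype=np.int64)
    idx = 0
    for d in range(3):
        for _ in range(k_init[d]):
            act[d, k[d]] = idx
            pop_counts[idx, d] = 1
            k[d] += 1
            idx += 1

    next_node = n
    total = n
    t = 0.0
    e = 0

    while total > 1:
        crate = 0.0
        mrate = 0.0
        for d in range(3):
            kd = k[d]
            if kd > 1:
                crate += kd * (kd - 1) / 2.0 / sizes[d]
            if kd > 0:
                row = 0.0
                for j in range(3):
                    row += migration[e, d, j]
                mrate += kd * row
        tot = crate + mrate

        advance = True
        if tot > 0.0:
            dt = np.random.exponential(1.0 / tot)
            if t + dt < bounds[e]:
                advance = False
                t += dt
        if advance:
            # jump to the epoch boundary, fold demes, switch rate matrix
            t = bounds[e]
            f = merge_from[e]
            if f >= 0:
                to = merge_to[e]
                for i in range(k[f]):
                    act[to, k[to]] = act[f, i]
                    k[to] += 1
                k[f] = 0
            e += 1
            continue

        u = np.random.random() * tot
        acc = 0.0
        handled = False
        for d in range(3):
            kd = k[d]
            if kd > 1:
                acc += kd * (kd - 1) / 2.0 / sizes[d]
                if u < acc:
                    i = np.random.randint(0, kd)
                    j = np.random.randint(0, kd - 1)
                    if j >= i:
                        j += 1
                    a = act[d, i]
                    b = act[d, j]
                    parent[a] = next_node
                    parent[b] = next_node
                    node_time[next_node] = t
                    for dd in range(3):
                        pop_counts[next_node, dd] = (
                            pop_counts[a, dd] + pop_counts[b, dd]
                        )
                    lo = min(i, j)
                    hi = max(i, j)
                    act[d, hi] = act[d, kd - 1]
                    act[d, lo] = next_node
                    k[d] -= 1
                    next_node += 1
                    total -= 1
                    handled = True
                    break
        if handled:
            continue
        for d in range(3):
            kd = k[d]
            if kd == 0:
                continue
            for j2 in range(3):
                r = kd * migration[e, d, j2]
                if r <= 0.0:
                    continue
                acc += r
                if u < acc:
                    i = np.random.randint(0, kd)
                    node = act[d, i]
                    act[d, i] = act[d, kd - 1]
                    k[d] -= 1
                    act[j2, k[j2]] = node
                    k[j2] += 1
                    handled = True
                    break
            if handled:
                break
        # floating-point edge (u ~ tot): no event this round, loop again

    return parent, node_time, pop_counts
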