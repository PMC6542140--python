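"""Compiled Kingman sampler for the three-deme introduction scenario.

Backward in time: demes 0 (large native cluster), 1 (second native
cluster) and 2 (introduced).  Deme 2 has size ``n_i`` on (0, t_ib), the
founder size ``n_f`` on (t_ib, t_i), and merges into deme 0 at ``t_i``;
deme 1 merges into deme 0 at ``t_d``.  Pairs within a deme of size N
coalesce at rate 1/(2N) per pair per generation (diploid scale, matching
msprime ploidy=2).  Per locus, one mutation is placed on a branch chosen
proportional to branch length and the derived leaves become the alternate
allele — identical to the SNP scheme of the msprime engine, against which
this sampler is cross-validated distributionally in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _one_locus(calls, locus, n1, n2, ni, sizes, t_ib, t_i, t_d):
    n_ind = n1 + n2 + ni
    n_leaves = 2 * n_ind
    n_nodes = 2 * n_leaves - 1
    time = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    parent = np.full(n_nodes, -1, dtype=np.int64)

    # active lineages
    act = np.arange(n_leaves)
    deme = np.empty(n_leaves, dtype=np.int64)
    for i in range(n_leaves):
        ind = i // 2
        if ind < n1:
            deme[i] = 0
        elif ind < n1 + n2:
            deme[i] = 1
        else:
            deme[i] = 2
    k = n_leaves
    nxt = n_leaves
    t = 0.0
    epoch = 0  # 0: before t_ib, 1: bottleneck, 2: after t_i, 3: after t_d
    bounds = np.array([t_ib, t_i, t_d, np.inf])

    while k > 1:
        # per-deme lineage counts
        k0 = 0
        k1 = 0
        k2 = 0
        for i in range(k):
            d = deme[i]
            if d == 0:
                k0 += 1
            elif d == 1:
                k1 += 1
            else:
                k2 += 1
        size2 = sizes[2] if epoch == 0 else sizes[3]  # n_i then n_f
        r0 = 0.5 * k0 * (k0 - 1) / (2.0 * sizes[0])
        r1 = 0.5 * k1 * (k1 - 1) / (2.0 * sizes[1])
        r2 = 0.5 * k2 * (k2 - 1) / (2.0 * size2)
        rate = r0 + r1 + r2
        if rate > 0.0:
            dt = np.random.exponential(1.0 / rate)
        else:
            dt = np.inf
        if epoch < 3 and t + dt >= bounds[epoch]:
            t = bounds[epoch]
            if epoch == 1:  # t_i: introduced merges into deme 0
                for i in range(k):
                    if deme[i] == 2:
                        deme[i] = 0
            elif epoch == 2:  # t_d: second native merges into deme 0
                for i in range(k):
                    if deme[i] == 1:
                        deme[i] = 0
            epoch += 1
            continue
        t += dt
        # choose deme proportional to rate, then a uniform pair within it
        u = np.random.random() * rate
        if u < r0:
            dsel = 0
        elif u < r0 + r1:
            dsel = 1
        else:
            dsel = 2
        # reservoir-free pair pick: find the deme's lineage positions
        kd = k0 if dsel == 0 else (k1 if dsel == 1 else k2)
        a = np.random.randint(0, kd)
        b = np.random.randint(0, kd - 1)
        if b >= a:
            b += 1
        ia = -1
        ib = -1
        seen = 0
        for i in range(k):
            if deme[i] == dsel:
                if seen == a:
                    ia = i
                if seen == b:
                    ib = i
                seen += 1
        na, nb = act[ia], act[ib]
        time[nxt] = t
        left[nxt] = na
        right[nxt] = nb
        parent[na] = nxt
        parent[nb] = nxt
        act[ia] = nxt
        # remove ib by swapping in the last active lineage
        act[ib] = act[k - 1]
        deme[ib] = deme[k - 1]
        nxt += 1
        k -= 1

    # branch lengths; root is node n_nodes - 1
    total = 0.0
    for v in range(n_nodes - 1):
        total += time[parent[v]] - time[v]
    x = np.random.random() * total
    acc = 0.0
    chosen = n_nodes - 2
    for v in range(n_nodes - 1):
        acc += time[parent[v]] - time[v]
        if acc >= x:
            chosen = v
            break
    # leaves under the chosen node
    stack = np.empty(n_nodes, dtype=np.int64)
    top = 0
    stack[top] = chosen
    top += 1
    while top > 0:
        top -= 1
        v = stack[top]
        if v < n_leaves:
            calls[v // 2, locus] += 1
        else:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1


@njit(cache=True)
def simulate_scenario_calls(
    n1, n2, ni, size_n1, size_n2, size_i, size_f, t_ib, t_i, t_d, n_loci, seed
):
    np.random.seed(seed)
    sizes = np.array([size_n1, size_n2, size_i, size_f])
    calls = np.zeros((n1 + n2 + ni, n_loci), dtype=np.int8)
    for locus in range(n_loci):
        _one_locus(calls, locus, n1, n2, ni, sizes, t_ib, t_i, t_d)
    return calls
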