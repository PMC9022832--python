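"""Compiled kernels for the heavy combinatorics.

The dodecahedron has 5,184,000 labeled spanning trees; enumerating and
classifying them is the one genuinely heavy step in the package, so the
inner loops are JIT-compiled.  Edge subsets are 30-bit masks (uint32) with
bit *i* for the *i*-th edge in the graph's lexicographic edge order.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def enumerate_spanning_tree_masks(eu, ev, nv, ne, adj, out):
    """Enumerate all spanning trees of a graph as edge bitmasks.

    Depth-first include/exclude search over edges in index order.  An edge is
    included only if it joins two union-find components (no cycle); it is
    excluded only if the graph of included plus still-undecided edges stays
    connected (so every branch leads to at least one spanning tree and each
    tree is emitted exactly once).

    Parameters are plain arrays so the kernel stays allocation-free:
    ``eu``/``ev`` endpoint arrays, ``adj`` per-vertex neighbour bitmasks of
    the full graph (modified in place and restored), ``out`` a preallocated
    uint32 array.  Returns the number of trees written.
    """
    parent = np.arange(nv, dtype=np.int64)
    size = np.ones(nv, dtype=np.int64)
    cap = ne + 2
    st_i = np.zeros(cap, dtype=np.int64)
    st_k = np.zeros(cap, dtype=np.int64)
    st_mask = np.zeros(cap, dtype=np.uint32)
    st_stage = np.zeros(cap, dtype=np.int64)
    st_ru = np.zeros(cap, dtype=np.int64)
    st_rv = np.zeros(cap, dtype=np.int64)
    full = (np.int64(1) << np.int64(nv)) - 1
    pos = 0
    sp = 1
    while sp > 0:
        t = sp - 1
        stage = st_stage[t]
        i = st_i[t]
        if stage == 0:
            st_stage[t] = 1
            if st_k[t] == nv - 1:
                out[pos] = st_mask[t]
                pos += 1
                sp -= 1
                continue
            if i == ne:
                sp -= 1
                continue
            u, v = eu[i], ev[i]
            ru = u
            while parent[ru] != ru:
                ru = parent[ru]
            rv = v
            while parent[rv] != rv:
                rv = parent[rv]
            if ru != rv:
                # include edge i: union by size (undone at stage 1)
                if size[ru] < size[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                size[ru] += size[rv]
                st_ru[t], st_rv[t] = ru, rv
                st_i[sp], st_k[sp] = i + 1, st_k[t] + 1
                st_mask[sp] = st_mask[t] | (np.uint32(1) << np.uint32(i))
                st_stage[sp] = 0
                sp += 1
                continue
            st_ru[t] = -1
        elif stage == 1:
            st_stage[t] = 2
            if st_ru[t] >= 0:
                parent[st_rv[t]] = st_rv[t]
                size[st_ru[t]] -= size[st_rv[t]]
            # exclude edge i: bitmask BFS connectivity of what remains
            u, v = eu[i], ev[i]
            adj[u] &= ~(np.int64(1) << np.int64(v))
            adj[v] &= ~(np.int64(1) << np.int64(u))
            reach = np.int64(1)
            frontier = np.int64(1)
            while frontier != 0:
                newf = np.int64(0)
                f = frontier
                w = 0
                while f != 0:
                    if f & 1:
                        newf |= adj[w]
                    f >>= 1
                    w += 1
                frontier = newf & ~reach
                reach |= frontier
            if reach == full:
                st_i[sp], st_k[sp] = i + 1, st_k[t]
                st_mask[sp] = st_mask[t]
                st_stage[sp] = 0
                sp += 1
            else:
                adj[u] |= np.int64(1) << np.int64(v)
                adj[v] |= np.int64(1) << np.int64(u)
                sp -= 1
        else:
            u, v = eu[i], ev[i]
            adj[u] |= np.int64(1) << np.int64(v)
            adj[v] |= np.int64(1) << np.int64(u)
            sp -= 1
    return pos


@njit(cache=False)
def tree_stats(masks, eu, ev, nv, ne, face_edge, nf):
    """Per-tree MLD (tree diameter, via double BFS) and wrapping number
    (faces whose boundary carries exactly four tree links)."""
    n = masks.shape[0]
    mld = np.zeros(n, dtype=np.int64)
    wrap = np.zeros(n, dtype=np.int64)
    adj = np.zeros((nv, 3), dtype=np.int64)
    deg = np.zeros(nv, dtype=np.int64)
    dist = np.zeros(nv, dtype=np.int64)
    queue = np.zeros(nv, dtype=np.int64)
    for t in range(n):
        m = np.int64(masks[t])
        deg[:] = 0
        for e in range(ne):
            if (m >> np.int64(e)) & 1:
                u, v = eu[e], ev[e]
                adj[u, deg[u]] = v
                deg[u] += 1
                adj[v, deg[v]] = u
                deg[v] += 1
        src = 0
        fard = 0
        for _ in range(2):
            dist[:] = -1
            dist[src] = 0
            queue[0] = src
            qh, qt = 0, 1
            far, fard = src, 0
            while qh < qt:
                x = queue[qh]
                qh += 1
                for j in range(deg[x]):
                    y = adj[x, j]
                    if dist[y] < 0:
                        dist[y] = dist[x] + 1
                        if dist[y] > fard:
                            fard = dist[y]
                            far = y
                        queue[qt] = y
                        qt += 1
            src = far
        mld[t] = fard
        w = 0
        for f in range(nf):
            c = 0
            for j in range(face_edge.shape[1]):
                e = face_edge[f, j]
                if e >= 0 and (m >> np.int64(e)) & 1:
                    c += 1
            if c == 4:
                w += 1
        wrap[t] = w
    return mld, wrap


@njit(cache=False)
def count_hamiltonian_paths_directed(adj, nv):
    """Number of directed Hamiltonian paths by exhaustive DFS over all start
    vertices; each undirected edge-subset path is counted twice."""
    full = (np.int64(1) << np.int64(nv)) - 1
    total = 0
    st_v = np.zeros(nv + 1, dtype=np.int64)
    st_visited = np.zeros(nv + 1, dtype=np.int64)
    st_avail = np.zeros(nv + 1, dtype=np.int64)
    for s in range(nv):
        sp = 1
        st_v[0] = s
        st_visited[0] = np.int64(1) << np.int64(s)
        st_avail[0] = adj[s]
        while sp > 0:
            t = sp - 1
            if st_visited[t] == full:
                total += 1
                sp -= 1
                continue
            av = st_avail[t] & ~st_visited[t]
            if av == 0:
                sp -= 1
                continue
            nxt = av & (-av)  # lowest set bit
            st_avail[t] &= ~nxt
            v = 0
            b = nxt
            while b > 1:
                b >>= 1
                v += 1
            st_v[sp] = v
            st_visited[sp] = st_visited[t] | nxt
            st_avail[sp] = adj[v]
            sp += 1
    return total
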