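"""Minimum-energy assembly networks and activation profiles.

For a fixed spanning tree, the assembly intermediates at pentamer count *n*
are the face subsets that achieve the level minimum dE_min(n), found by
exhaustive search over all C(F, n) subsets (at most 924 per level on the
dodecahedron).  Intermediates related by a symmetry of the dodecahedron
that preserves the tree (the tree's stabilizer subgroup) are physically
identical and are merged.  Nodes at consecutive levels are adjacent when
they differ by the addition of one pentamer; the master-equation kinetics
runs on this layered network.

The activation barrier max_n dE_min(n) is the nucleation bottleneck; its
dependence on the tree's wrapping number and MLD is what makes packaging
selective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .energetics import EnergyParams, level_energies
from .polyhedra import PolyhedronGraph

__all__ = [
    "EnergyProfile",
    "AssemblyNetwork",
    "min_energy_profile",
    "build_network",
    "equilibrium_distribution",
]

_TOL = 1e-9


@dataclass(frozen=True)
class EnergyProfile:
    """Per-level minimum assembly energies dE_min(n), n = 0..F (E0 units)."""

    e_min: tuple[float, ...]
    n_barrier: int
    n_min: int

    @property
    def barrier(self) -> float:
        """Activation barrier: the maximum of the minimum-energy profile."""
        return self.e_min[self.n_barrier]

    @property
    def minimum(self) -> float:
        return self.e_min[self.n_min]


def _tree_mask(tree, graph: PolyhedronGraph) -> int:
    if isinstance(tree, (int, np.integer)):
        return int(tree)
    if hasattr(tree, "representative"):  # SpanningTreeClass
        return int(tree.representative)
    return graph.edges_to_mask(tree)


def _level_minima(tree: int, graph: PolyhedronGraph, params: EnergyParams):
    """Exhaustive per-level minimization.  Returns (e_min, min-config lists)."""
    F = graph.n_faces
    e_min = np.zeros(F + 1)
    min_cfgs: list[list[tuple[int, ...]]] = []
    for n in range(F + 1):
        subs = list(combinations(range(F), n))
        occ = np.zeros((len(subs), F), dtype=np.int64)
        for i, s in enumerate(subs):
            occ[i, list(s)] = 1
        E = level_energies(tree, graph, params, occ)
        e_min[n] = E.min()
        keep = np.nonzero(E <= e_min[n] + _TOL)[0]
        min_cfgs.append([subs[i] for i in keep])
    return e_min, min_cfgs


def min_energy_profile(
    tree, graph: PolyhedronGraph, params: EnergyParams
) -> EnergyProfile:
    """Exact minimum-energy assembly profile for one spanning tree."""
    mask = _tree_mask(tree, graph)
    e_min, _ = _level_minima(mask, graph, params)
    return EnergyProfile(
        e_min=tuple(float(x) for x in e_min),
        n_barrier=int(np.argmax(e_min)),
        n_min=int(np.argmin(e_min)),
    )


def tree_stabilizer(tree: int, graph: PolyhedronGraph) -> list[int]:
    """Indices of group elements that map the tree's edge set to itself."""
    return [
        g
        for g in range(len(graph.symmetry_group))
        if graph.apply_to_mask(g, tree) == tree
    ]


@dataclass
class AssemblyNetwork:
    """Layered network of minimum-energy assembly intermediates.

    levels[n] holds the canonical face tuples of the m_n distinct
    intermediates with n pentamers; adjacency[n][i] lists the level-(n+1)
    node indices reachable from node (n, i) by adding one pentamer.
    ``e_min`` carries the (shared) level energies in E0 units.
    """

    graph: PolyhedronGraph
    tree: int
    params: EnergyParams
    e_min: np.ndarray
    levels: list[list[tuple[int, ...]]]
    adjacency: list[list[list[int]]]
    stabilizer: list[int] = field(default_factory=list)

    @property
    def multiplicities(self) -> list[int]:
        return [len(lv) for lv in self.levels]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_nodes(self) -> int:
        return sum(self.multiplicities)

    @property
    def profile(self) -> EnergyProfile:
        return EnergyProfile(
            e_min=tuple(float(x) for x in self.e_min),
            n_barrier=int(np.argmax(self.e_min)),
            n_min=int(np.argmin(self.e_min)),
        )

    @property
    def level_sizes(self) -> list[int]:
        return self.multiplicities

    def node_levels(self) -> np.ndarray:
        """Level (pentamer count) of every node, in block order."""
        return np.concatenate(
            [np.full(m, n) for n, m in enumerate(self.multiplicities)]
        )

    def adjacency_matrix(self, n: int) -> np.ndarray:
        """Binary A_n with A[i, j] = 1 iff (n, i) links to (n+1, j)."""
        A = np.zeros((len(self.levels[n]), len(self.levels[n + 1])), dtype=np.int64)
        for i, row in enumerate(self.adjacency[n]):
            A[i, row] = 1
        return A

    def monotone_path_count(self) -> int:
        """Number of strictly-growing assembly paths from n=0 to n=F."""
        cnt = np.ones(len(self.levels[0]), dtype=object)
        for n in range(self.n_levels - 1):
            nxt = np.zeros(len(self.levels[n + 1]), dtype=object)
            for i, row in enumerate(self.adjacency[n]):
                for j in row:
                    nxt[j] += cnt[i]
            cnt = nxt
        return int(cnt.sum())

    def connectivity_report(self) -> dict:
        """Reachability diagnostics.

        ``source_to_sink`` — whether the complete capsid is reachable from
        the empty state (required for assembly; an error is raised at build
        time if it fails).  ``stranded`` — nodes not lying on any monotone
        0 -> F path.  Such nodes are kept: the master equation also flows
        downward, so they act as metastable side states.
        """
        L = self.n_levels
        fwd = [set() for _ in range(L)]
        fwd[0] = set(range(len(self.levels[0])))
        for n in range(L - 1):
            for i in fwd[n]:
                fwd[n + 1].update(self.adjacency[n][i])
        bwd = [set() for _ in range(L)]
        bwd[L - 1] = set(range(len(self.levels[L - 1])))
        for n in range(L - 2, -1, -1):
            bwd[n] = {
                i
                for i in range(len(self.levels[n]))
                if any(j in bwd[n + 1] for j in self.adjacency[n][i])
            }
        stranded = [
            (n, i)
            for n in range(L)
            for i in range(len(self.levels[n]))
            if i not in (fwd[n] & bwd[n])
        ]
        return {
            "source_to_sink": bool(fwd[L - 1]),
            "stranded": stranded,
        }

    def to_dict(self) -> dict:
        return {
            "tree": int(self.tree),
            "params": {
                "e0": self.params.e0,
                "eps1": self.params.eps1,
                "mu0": self.params.mu0,
            },
            "e_min": [float(x) for x in self.e_min],
            "levels": [
                {"n": n, "m": len(lv), "configs": [list(c) for c in lv]}
                for n, lv in enumerate(self.levels)
            ],
            "adjacency": [[list(r) for r in rows] for rows in self.adjacency],
        }


def _canon_faces(
    faces: tuple[int, ...], graph: PolyhedronGraph, stab: list[int]
) -> tuple[int, ...]:
    return min(
        tuple(sorted(int(graph.face_perms[g][f]) for f in faces)) for g in stab
    )


def build_network(
    tree, graph: PolyhedronGraph, params: EnergyParams
) -> AssemblyNetwork:
    """Build the minimum-energy assembly network of one spanning tree.

    Each level keeps exactly the configurations achieving dE_min(n),
    deduplicated under the tree's stabilizer subgroup.  Raises if the
    complete capsid is unreachable from the empty state.
    """
    mask = _tree_mask(tree, graph)
    e_min, min_cfgs = _level_minima(mask, graph, params)
    stab = tree_stabilizer(mask, graph)
    levels: list[list[tuple[int, ...]]] = []
    for cfgs in min_cfgs:
        seen: dict[tuple[int, ...], None] = {}
        for s in cfgs:
            seen.setdefault(_canon_faces(s, graph, stab), None)
        levels.append(sorted(seen))
    adjacency: list[list[list[int]]] = []
    F = graph.n_faces
    for n in range(F):
        index = {c: j for j, c in enumerate(levels[n + 1])}
        rows = []
        for c in levels[n]:
            cs = set(c)
            row = set()
            for f in range(F):
                if f in cs:
                    continue
                cc = _canon_faces(tuple(sorted(cs | {f})), graph, stab)
                if cc in index:
                    row.add(index[cc])
            rows.append(sorted(row))
        adjacency.append(rows)
    net = AssemblyNetwork(
        graph=graph,
        tree=mask,
        params=params,
        e_min=e_min,
        levels=levels,
        adjacency=adjacency,
        stabilizer=stab,
    )
    report = net.connectivity_report()
    if not report["source_to_sink"]:
        # find the first level with no incoming links to name it
        for n in range(F):
            if all(not r for r in net.adjacency[n]):
                raise RuntimeError(
                    f"assembly network disconnected: no single-pentamer step "
                    f"links level {n} to level {n + 1}"
                )
        raise RuntimeError("assembly network: complete capsid unreachable")
    return net


def equilibrium_distribution(
    network: AssemblyNetwork | object, params: EnergyParams, c_f: float
) -> np.ndarray:
    """Boltzmann equilibrium probability of every network node.

    P_eq(n) is proportional to exp(-e0*dE(n) + n*ln c_f); all nodes of a
    level share it.  Normalized so the m_n-weighted sum over all levels
    n = 0..F equals one (the empty state is included: it is the source
    state of the assembly network).
    """
    if c_f <= 0:
        raise ValueError("c_f must be positive")
    e_min = np.asarray(network.e_min, dtype=float)
    m = np.array([len(lv) for lv in network.levels])
    n = np.arange(len(e_min))
    logw = -params.e0 * e_min + n * np.log(c_f)
    logw -= logw.max()  # overflow guard
    w = np.exp(logw)
    z = (m * w).sum()
    return np.concatenate([np.full(m[k], w[k] / z) for k in range(len(e_min))])
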