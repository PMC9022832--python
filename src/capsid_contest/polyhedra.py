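"""Polyhedral scaffold graphs and their symmetry groups.

The capsid is modelled as twelve pentamers on the faces of a dodecahedron;
the condensed RNA secondary structure (the psi sequence of packaging
signals) lives on the dodecahedron's edges.  This module builds the
dodecahedral graph — vertices, edges, faces and the full symmetry group of
120 rotations and reflections — plus two small fixture polyhedra
(tetrahedron, cube) used as exhaustively checkable test scaffolds.

Symmetry groups are obtained as graph automorphism groups.  For 3-connected
planar graphs (all convex polyhedra) the combinatorial automorphism group
coincides with the geometric symmetry group of the solid, so no coordinates
are needed.
"""

from __future__ import annotations

import json
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher

__all__ = [
    "PolyhedronGraph",
    "build_dodecahedron",
    "build_fixture",
    "canonical_form",
    "orbit",
]

Edge = tuple[int, int]

_EXPECTED = {
    # name: (V, E, F, |G|)
    "dodecahedron": (20, 30, 12, 120),
    "cube": (8, 12, 6, 48),
    "tetrahedron": (4, 6, 4, 24),
}


def _planar_faces(G: nx.Graph) -> list[tuple[int, ...]]:
    """All faces of a planar embedding, each as a minimal-rotation cycle."""
    ok, emb = nx.check_planarity(G)
    if not ok:  # pragma: no cover - all built-in scaffolds are planar
        raise ValueError("graph is not planar")
    seen: set[tuple[int, int]] = set()
    faces = []
    for u in emb:
        for v in emb[u]:
            if (u, v) in seen:
                continue
            cycle = emb.traverse_face(u, v, mark_half_edges=seen)
            faces.append(_canonical_cycle(cycle))
    return sorted(faces)


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle so it starts at its minimum vertex and runs
    toward the smaller neighbour.  Deterministic face serialization."""
    n = len(cycle)
    k = min(range(n), key=lambda i: cycle[i])
    fwd = tuple(cycle[(k + i) % n] for i in range(n))
    rev = tuple(cycle[(k - i) % n] for i in range(n))
    return min(fwd, rev)


def _automorphisms(G: nx.Graph) -> np.ndarray:
    gm = GraphMatcher(G, G)
    V = G.number_of_nodes()
    perms = sorted(tuple(m[i] for i in range(V)) for m in gm.isomorphisms_iter())
    return np.array(perms, dtype=np.int64)


class PolyhedronGraph:
    """A polyhedral scaffold: vertices, edges, faces and symmetry group.

    Parameters
    ----------
    name : str
        Identifier ("dodecahedron", "cube", "tetrahedron").
    graph : networkx.Graph
        3-connected planar graph with integer vertex labels 0..V-1.

    Attributes
    ----------
    edges : tuple of (u, v)
        Sorted vertex pairs, in lexicographic order; the edge index used by
        all bitmask representations follows this order.
    faces : tuple of vertex cycles
        Minimal-rotation face cycles; every edge borders exactly two faces.
    symmetry_group : (|G|, V) int array
        Vertex permutations (rotations and reflections).
    edge_perms, face_perms : (|G|, E) and (|G|, F) int arrays
        The induced action of each group element on edges and faces.
    """

    def __init__(self, name: str, graph: nx.Graph):
        self.name = name
        self.n_vertices = graph.number_of_nodes()
        self.edges: tuple[Edge, ...] = tuple(
            sorted(tuple(sorted(e)) for e in graph.edges())
        )
        self.n_edges = len(self.edges)
        self.edge_index = {e: i for i, e in enumerate(self.edges)}
        self.faces = tuple(_planar_faces(graph))
        self.n_faces = len(self.faces)
        self.symmetry_group = _automorphisms(graph)
        self._finalize()
        self._validate()

    # -- derived structure -------------------------------------------------

    def _finalize(self) -> None:
        eidx = self.edge_index
        # face -> edge indices, edge -> face pair
        self.face_edge_indices: tuple[tuple[int, ...], ...] = tuple(
            tuple(
                eidx[tuple(sorted((f[i], f[(i + 1) % len(f)])))]
                for i in range(len(f))
            )
            for f in self.faces
        )
        e2f: dict[Edge, list[int]] = {e: [] for e in self.edges}
        for fi, fedges in enumerate(self.face_edge_indices):
            for ei in fedges:
                e2f[self.edges[ei]].append(fi)
        self.edge_to_faces = {e: tuple(fs) for e, fs in e2f.items()}
        # edge/face permutation action of each group element
        G = self.symmetry_group
        self.edge_perms = np.array(
            [
                [eidx[tuple(sorted((g[u], g[v])))] for (u, v) in self.edges]
                for g in G
            ],
            dtype=np.int64,
        )
        fmap = {frozenset(f): i for i, f in enumerate(self.faces)}
        self.face_perms = np.array(
            [[fmap[frozenset(g[v] for v in f)] for f in self.faces] for g in G],
            dtype=np.int64,
        )
        # edge x face incidence (0/1), used by the energy model
        m = np.zeros((self.n_edges, self.n_faces), dtype=np.int64)
        for fi, fedges in enumerate(self.face_edge_indices):
            m[list(fedges), fi] = 1
        self.edge_face_matrix = m

    def _validate(self) -> None:
        V, E, F = self.n_vertices, self.n_edges, self.n_faces
        if V - E + F != 2:
            raise ValueError(f"Euler check failed: V-E+F = {V - E + F}")
        if not all(len(fs) == 2 for fs in self.edge_to_faces.values()):
            raise ValueError("every edge must border exactly two faces")
        if self.name in _EXPECTED:
            exp = _EXPECTED[self.name]
            got = (V, E, F, len(self.symmetry_group))
            if got != exp:
                raise ValueError(f"{self.name}: expected {exp}, got {got}")

    # -- bitmask helpers ---------------------------------------------------

    def edges_to_mask(self, edge_subset: Iterable[Edge]) -> int:
        mask = 0
        for e in edge_subset:
            e = tuple(sorted(e))
            if e not in self.edge_index:
                raise ValueError(f"edge {e} not in {self.name} graph")
            mask |= 1 << self.edge_index[e]
        return mask

    def mask_to_edges(self, mask: int) -> frozenset[Edge]:
        return frozenset(
            self.edges[i] for i in range(self.n_edges) if (int(mask) >> i) & 1
        )

    def apply_to_mask(self, g: int, mask: int) -> int:
        """Image of an edge-subset bitmask under group element ``g``."""
        out = 0
        perm = self.edge_perms[g]
        for i in range(self.n_edges):
            if (int(mask) >> i) & 1:
                out |= 1 << int(perm[i])
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "vertices": list(range(self.n_vertices)),
            "edges": [list(e) for e in self.edges],
            "faces": [list(f) for f in self.faces],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PolyhedronGraph({self.name!r}, V={self.n_vertices}, "
            f"E={self.n_edges}, F={self.n_faces}, |G|={len(self.symmetry_group)})"
        )


@lru_cache(maxsize=None)
def build_dodecahedron() -> PolyhedronGraph:
    """The dodecahedral capsid scaffold: 20 vertices, 30 edges, 12 pentagonal
    faces, symmetry group of order 120.  Vertex labelling follows
    ``networkx.dodecahedral_graph`` and is the canonical labelling on which
    all canonical forms in this package are defined."""
    return PolyhedronGraph("dodecahedron", nx.dodecahedral_graph())


@lru_cache(maxsize=None)
def build_fixture(name: str) -> PolyhedronGraph:
    """Small oracle-testable scaffolds: ``tetrahedron`` (V=4, |G|=24) or
    ``cube`` (V=8, |G|=48)."""
    if name == "tetrahedron":
        return PolyhedronGraph(name, nx.complete_graph(4))
    if name == "cube":
        g = nx.convert_node_labels_to_integers(
            nx.hypercube_graph(3), ordering="sorted"
        )
        return PolyhedronGraph(name, g)
    raise ValueError(f"unknown fixture {name!r}; use 'tetrahedron' or 'cube'")


def get_polyhedron(name: str) -> PolyhedronGraph:
    if name == "dodecahedron":
        return build_dodecahedron()
    return build_fixture(name)


def canonical_form(
    edge_subset: Iterable[Edge], graph: PolyhedronGraph
) -> frozenset[Edge]:
    """Canonical representative of an edge subset's symmetry orbit.

    The representative is the orbit member whose edge-index bitmask (edges
    indexed in lexicographic order) is numerically minimal.  Idempotent;
    equal for any two subsets in the same orbit.
    """
    mask = graph.edges_to_mask(edge_subset)
    return graph.mask_to_edges(canonical_mask(mask, graph))


def canonical_mask(mask: int, graph: PolyhedronGraph) -> int:
    """Bitmask version of :func:`canonical_form`: minimum of the orbit of
    ``mask`` under the group's induced edge permutations."""
    best = int(mask)
    for g in range(len(graph.symmetry_group)):
        img = graph.apply_to_mask(g, mask)
        if img < best:
            best = img
    return best


def orbit(edge_subset: Iterable[Edge], graph: PolyhedronGraph) -> set[frozenset[Edge]]:
    """The full symmetry orbit of an edge subset."""
    mask = graph.edges_to_mask(edge_subset)
    return {
        graph.mask_to_edges(graph.apply_to_mask(g, mask))
        for g in range(len(graph.symmetry_group))
    }
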