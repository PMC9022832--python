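"""Spanning-tree enumeration, symmetry reduction, and classification.

The psi sequence of packaging signals is modelled as a spanning tree of the
dodecahedral graph: nineteen links joining all twenty vertices.  This module
enumerates all labeled spanning trees, reduces them to symmetry-inequivalent
classes, and indexes each class by its two folding-geometry characteristics:

* **MLD** (maximum ladder distance) — the tree diameter in links; a
  topological compactness index of the secondary structure.  It is 19 for a
  Hamiltonian path (the linear chain) and 9 at minimum on the dodecahedron.
* **wrapping number** N_p — the number of faces whose boundary carries the
  maximum of four tree links, i.e. the number of pentamer sites with maximal
  specific affinity.  A face can never carry five links (that would close a
  cycle), so 4 is the maximum.

The enumerated count is always verified against the Kirchhoff matrix-tree
determinant, and the class count can be cross-checked with Burnside's lemma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from .polyhedra import Edge, PolyhedronGraph, build_dodecahedron

__all__ = [
    "SpanningTreeClass",
    "TreeLibrary",
    "enumerate_spanning_trees",
    "count_spanning_trees",
    "dedupe_by_symmetry",
    "burnside_class_count",
    "mld",
    "wrapping_number",
    "count_hamiltonian_paths",
    "build_library",
    "dodecahedron_library",
]


# --------------------------------------------------------------------------
# enumeration


def count_spanning_trees(graph: PolyhedronGraph) -> int:
    """Number of labeled spanning trees by the Kirchhoff matrix-tree
    theorem (determinant of a Laplacian cofactor)."""
    V = graph.n_vertices
    L = np.zeros((V, V))
    for u, v in graph.edges:
        L[u, u] += 1
        L[v, v] += 1
        L[u, v] -= 1
        L[v, u] -= 1
    return int(round(np.linalg.det(L[1:, 1:])))


def enumerate_spanning_trees(graph: PolyhedronGraph) -> np.ndarray:
    """All spanning trees of ``graph`` as a uint32 array of edge bitmasks.

    The count is verified against :func:`count_spanning_trees`; a mismatch
    raises, so a returned array is guaranteed complete and duplicate-free.
    """
    if graph.n_edges > 31:
        raise ValueError("edge bitmasks limited to 31 edges")
    expected = count_spanning_trees(graph)
    if expected == 0:
        raise ValueError("graph is disconnected; no spanning trees")
    eu = np.array([e[0] for e in graph.edges], dtype=np.int64)
    ev = np.array([e[1] for e in graph.edges], dtype=np.int64)
    adj = np.zeros(graph.n_vertices, dtype=np.int64)
    for u, v in graph.edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    out = np.zeros(expected, dtype=np.uint32)
    n = _kernels.enumerate_spanning_tree_masks(
        eu, ev, graph.n_vertices, graph.n_edges, adj, out
    )
    if n != expected:
        raise AssertionError(
            f"enumerated {n} trees but Kirchhoff determinant gives {expected}"
        )
    return out


# --------------------------------------------------------------------------
# canonicalization under the symmetry group (vectorized over all trees)


def _half_tables(graph: PolyhedronGraph) -> tuple[np.ndarray, np.ndarray, int]:
    """For each group element, lookup tables mapping the low/high half-words
    of an edge bitmask to the permuted full mask."""
    ne = graph.n_edges
    half = ne // 2
    nhi = ne - half
    bits_lo = ((np.arange(1 << half)[:, None] >> np.arange(half)) & 1).astype(
        np.uint32
    )
    bits_hi = ((np.arange(1 << nhi)[:, None] >> np.arange(nhi)) & 1).astype(
        np.uint32
    )
    weights = (np.uint32(1) << graph.edge_perms.astype(np.uint32))  # (|G|, E)
    lo_tab = bits_lo @ weights[:, :half].T  # (2**half, |G|)
    hi_tab = bits_hi @ weights[:, half:].T
    return lo_tab.T.copy(), hi_tab.T.copy(), half


def canonicalize_masks(masks: np.ndarray, graph: PolyhedronGraph) -> np.ndarray:
    """Canonical (orbit-minimal) form of each edge bitmask, vectorized."""
    lo_tab, hi_tab, half = _half_tables(graph)
    lo = masks & np.uint32((1 << half) - 1)
    hi = masks >> np.uint32(half)
    canon = masks.copy()
    for g in range(len(graph.symmetry_group)):
        np.minimum(canon, lo_tab[g][lo] | hi_tab[g][hi], out=canon)
    return canon


def burnside_class_count(masks: np.ndarray, graph: PolyhedronGraph) -> float:
    """Independent orbit count via Burnside's lemma: the average over group
    elements of the number of trees each element fixes."""
    lo_tab, hi_tab, half = _half_tables(graph)
    lo = masks & np.uint32((1 << half) - 1)
    hi = masks >> np.uint32(half)
    fixed = 0
    for g in range(len(graph.symmetry_group)):
        fixed += int((lo_tab[g][lo] | hi_tab[g][hi] == masks).sum())
    return fixed / len(graph.symmetry_group)


# --------------------------------------------------------------------------
# per-tree characteristics


def _as_mask(tree, graph: PolyhedronGraph) -> int:
    if isinstance(tree, (int, np.integer)):
        return int(tree)
    return graph.edges_to_mask(tree)


def _check_tree(mask: int, graph: PolyhedronGraph) -> None:
    if bin(mask).count("1") != graph.n_vertices - 1:
        raise ValueError("a spanning tree must have V-1 edges")


def mld(tree, graph: PolyhedronGraph) -> int:
    """Maximum ladder distance: the tree diameter in links (double BFS)."""
    mask = _as_mask(tree, graph)
    out = _stats_single(mask, graph)
    return int(out[0])


def wrapping_number(tree, graph: PolyhedronGraph) -> int:
    """Number of faces whose boundary carries exactly four tree links."""
    mask = _as_mask(tree, graph)
    return int(_stats_single(mask, graph)[1])


def _stats_single(mask: int, graph: PolyhedronGraph) -> tuple[int, int]:
    arr = np.array([mask], dtype=np.uint32)
    m, w = _tree_stats(arr, graph)
    return int(m[0]), int(w[0])


def _tree_stats(masks: np.ndarray, graph: PolyhedronGraph):
    maxlen = max(len(f) for f in graph.face_edge_indices)
    face_edge = np.full((graph.n_faces, maxlen), -1, dtype=np.int64)
    for fi, fedges in enumerate(graph.face_edge_indices):
        face_edge[fi, : len(fedges)] = fedges
    eu = np.array([e[0] for e in graph.edges], dtype=np.int64)
    ev = np.array([e[1] for e in graph.edges], dtype=np.int64)
    return _kernels.tree_stats(
        masks, eu, ev, graph.n_vertices, graph.n_edges, face_edge, graph.n_faces
    )


def count_hamiltonian_paths(graph) -> int:
    """Distinct edge subsets forming a simple path through all vertices.

    Exhaustive DFS over directed paths; each undirected path is found once
    per direction, so the directed count is halved.  Accepts a
    :class:`PolyhedronGraph` or any (n_vertices, edge list) pair.
    """
    if isinstance(graph, PolyhedronGraph):
        nv, edges = graph.n_vertices, graph.edges
    else:
        nv, edges = graph
    adj = np.zeros(nv, dtype=np.int64)
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    directed = _kernels.count_hamiltonian_paths_directed(adj, nv)
    assert directed % 2 == 0
    return directed // 2


# --------------------------------------------------------------------------
# classes and the library


@dataclass(frozen=True)
class SpanningTreeClass:
    """A symmetry-inequivalent spanning tree class.

    ``representative`` is the canonical (orbit-minimal) edge bitmask;
    ``orbit_size`` the number of labeled trees in the orbit (divides the
    group order); ``mld`` and ``wrapping_number`` are orbit invariants.
    """

    class_id: int
    representative: int
    mld: int
    wrapping_number: int
    orbit_size: int
    is_hamiltonian_path: bool

    def edges(self, graph: PolyhedronGraph) -> frozenset[Edge]:
        return graph.mask_to_edges(self.representative)

    def to_record(self, graph: PolyhedronGraph) -> dict:
        return {
            "class_id": self.class_id,
            "edges": sorted(list(e) for e in self.edges(graph)),
            "mld": self.mld,
            "np": self.wrapping_number,
            "orbit_size": self.orbit_size,
            "hamiltonian": self.is_hamiltonian_path,
        }


class TreeLibrary:
    """All spanning-tree classes of a polyhedron, indexed by (MLD, N_p)."""

    def __init__(self, graph: PolyhedronGraph, classes: list[SpanningTreeClass]):
        self.graph = graph
        self.classes = classes
        self.by_mld_np: dict[tuple[int, int], list[SpanningTreeClass]] = {}
        for c in classes:
            self.by_mld_np.setdefault((c.mld, c.wrapping_number), []).append(c)

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def total_labeled_trees(self) -> int:
        return sum(c.orbit_size for c in self.classes)

    def lookup(self, mld: int, np_: int) -> list[SpanningTreeClass]:
        """Classes with the given (MLD, N_p); empty list if the bucket is
        absent (reported as absent, never an exception)."""
        return list(self.by_mld_np.get((mld, np_), []))

    def select(
        self,
        mld: int,
        np_: int,
        rule: str = "barrier",
        class_id: int | None = None,
        energy_params=None,
    ) -> SpanningTreeClass:
        """Pick one class from a (MLD, N_p) bucket.

        ``class_id`` overrides everything.  rule="canonical" takes the
        canonical-form-minimal member.  rule="barrier" (default) takes the
        member whose min-energy assembly profile has the largest activation
        barrier, ties broken canonically — this is the member whose profile
        matches the published reference profiles for the (9,8)/(19,2)
        competition pair.  ``energy_params`` defaults to eps1=-0.5, mu0=-4.
        """
        bucket = self.lookup(mld, np_)
        if not bucket:
            raise KeyError(f"no spanning-tree class with MLD={mld}, N_p={np_}")
        if class_id is not None:
            for c in bucket:
                if c.class_id == class_id:
                    return c
            raise KeyError(f"class_id {class_id} not in bucket ({mld},{np_})")
        if rule == "canonical":
            return min(bucket, key=lambda c: c.representative)
        if rule == "barrier":
            from .energetics import EnergyParams
            from .network import min_energy_profile

            params = energy_params or EnergyParams(e0=4.0, eps1=-0.5, mu0=-4.0)
            return max(
                bucket,
                key=lambda c: (
                    min_energy_profile(c.representative, self.graph, params).barrier,
                    -c.representative,
                ),
            )
        raise ValueError(f"unknown selection rule {rule!r}")

    def to_jsonl(self) -> str:
        lines = [
            json.dumps(c.to_record(self.graph), sort_keys=True)
            for c in self.classes
        ]
        return "\n".join(lines) + "\n"


def dedupe_by_symmetry(masks: np.ndarray, graph: PolyhedronGraph) -> TreeLibrary:
    """Partition labeled spanning trees into symmetry orbits.

    Returns a :class:`TreeLibrary` with one canonical representative per
    orbit.  The sum of orbit sizes always equals the input count, and every
    orbit size divides the group order.
    """
    canon = canonicalize_masks(np.asarray(masks, dtype=np.uint32), graph)
    reps, counts = np.unique(canon, return_counts=True)
    order = len(graph.symmetry_group)
    if np.any(order % counts):
        raise AssertionError("orbit size does not divide group order")
    mlds, wraps = _tree_stats(reps.astype(np.uint32), graph)
    vmax = graph.n_vertices - 1
    classes = [
        SpanningTreeClass(
            class_id=i,
            representative=int(reps[i]),
            mld=int(mlds[i]),
            wrapping_number=int(wraps[i]),
            orbit_size=int(counts[i]),
            is_hamiltonian_path=bool(mlds[i] == vmax),
        )
        for i in range(len(reps))
    ]
    return TreeLibrary(graph, classes)


def build_library(graph: PolyhedronGraph) -> TreeLibrary:
    """Enumerate, deduplicate and classify all spanning trees of ``graph``."""
    return dedupe_by_symmetry(enumerate_spanning_trees(graph), graph)


@lru_cache(maxsize=1)
def dodecahedron_library() -> TreeLibrary:
    """The full dodecahedron library (cached; ~20 s to build)."""
    return build_library(build_dodecahedron())
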