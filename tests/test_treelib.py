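"""Spanning-tree enumeration, symmetry classes, MLD and wrapping numbers."""

import itertools

import numpy as np
import pytest

import capsid_contest as cc
from capsid_contest.polyhedra import get_polyhedron
from capsid_contest.treelib import burnside_class_count


def brute_force_orbits(masks, graph):
    """Oracle: partition edge-bitmask trees into orbits by explicit group
    action (no canonicalization machinery)."""
    remaining = set(int(m) for m in masks)
    orbits = []
    while remaining:
        seed = next(iter(remaining))
        orb = {
            graph.apply_to_mask(g, seed)
            for g in range(len(graph.symmetry_group))
        }
        assert orb <= remaining
        remaining -= orb
        orbits.append(orb)
    return orbits


def test_tetrahedron_cayley_count_and_two_classes(tetrahedron):
    """K4 has 4^2 = 16 labeled spanning trees in exactly two shapes
    (paths and stars), verified against a brute-force orbit partition."""
    trees = cc.enumerate_spanning_trees(tetrahedron)
    assert len(trees) == 16 == cc.count_spanning_trees(tetrahedron)
    assert len(set(map(int, trees))) == 16
    lib = cc.dedupe_by_symmetry(trees, tetrahedron)
    assert len(lib) == 2
    oracle = brute_force_orbits(trees, tetrahedron)
    assert sorted(len(o) for o in oracle) == sorted(
        c.orbit_size for c in lib.classes
    )
    assert lib.total_labeled_trees == 16
    # paths have diameter 3, stars diameter 2
    assert sorted(c.mld for c in lib.classes) == [2, 3]


def test_cube_kirchhoff_and_burnside(cube):
    trees = cc.enumerate_spanning_trees(cube)
    assert len(trees) == cc.count_spanning_trees(cube)
    lib = cc.dedupe_by_symmetry(trees, cube)
    assert lib.total_labeled_trees == len(trees)
    assert len(lib) == burnside_class_count(trees, cube)
    for c in lib.classes:
        assert len(cube.symmetry_group) % c.orbit_size == 0


def test_disconnected_input_rejected():
    import networkx as nx

    from capsid_contest.polyhedra import PolyhedronGraph

    # two disjoint squares are planar but not connected
    g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 0)])
    g.add_edges_from([(4, 5), (5, 6), (6, 7), (7, 4)])
    with pytest.raises(ValueError):
        poly = PolyhedronGraph("twosquares", g)


def test_mld_of_known_shapes(tetrahedron, library, dodecahedron):
    path = [(0, 1), (1, 2), (2, 3)]
    star = [(0, 1), (0, 2), (0, 3)]
    assert cc.mld(path, tetrahedron) == 3
    assert cc.mld(star, tetrahedron) == 2
    ham = library.lookup(19, 2)[0]
    assert cc.mld(ham.representative, dodecahedron) == 19


def test_wrapping_number_bounds_and_invariance(library, dodecahedron):
    """No face can carry five tree links (it would close a cycle), and both
    MLD and N_p are constant on symmetry orbits."""
    rng = np.random.default_rng(1)
    reps = [c.representative for c in library.classes]
    for rep in rng.choice(len(reps), size=40, replace=False):
        mask = reps[rep]
        for fedges in dodecahedron.face_edge_indices:
            links = sum((mask >> e) & 1 for e in fedges)
            assert links <= 4
        g = int(rng.integers(0, 120))
        image = dodecahedron.apply_to_mask(g, mask)
        assert cc.mld(image, dodecahedron) == cc.mld(mask, dodecahedron)
        assert cc.wrapping_number(image, dodecahedron) == cc.wrapping_number(
            mask, dodecahedron
        )


def test_hamiltonian_path_count_oracles(tetrahedron):
    """DFS count equals an independent permutation-based count on K4, and
    the degenerate 4-cycle has one path per omitted edge."""
    edge_sets = set()
    for order in itertools.permutations(range(4)):
        # K4: every ordering is a path
        edge_sets.add(
            frozenset(tuple(sorted(p)) for p in zip(order, order[1:]))
        )
    assert cc.count_hamiltonian_paths(tetrahedron) == len(edge_sets) == 12
    c4 = (4, [(0, 1), (1, 2), (2, 3), (0, 3)])
    assert cc.count_hamiltonian_paths(c4) == 4


def test_dodecahedron_library_structure(library):
    """Tens of thousands of classes; buckets partition the classes; the
    Hamiltonian classes are exactly the MLD=19 ones."""
    assert 10_000 < len(library) < 100_000
    assert sum(len(b) for b in library.by_mld_np.values()) == len(library)
    hams = [c for c in library.classes if c.is_hamiltonian_path]
    assert all(c.mld == 19 for c in hams)
    assert {c.wrapping_number for c in hams} <= {2, 3, 4}
    assert library.lookup(19, 5) == []  # absent bucket, not an exception
    with pytest.raises(KeyError):
        library.select(19, 5)


def test_selection_rules(library, ref_params):
    bucket = library.lookup(19, 2)
    assert len(bucket) == 5
    by_canonical = library.select(19, 2, rule="canonical")
    assert by_canonical.representative == min(c.representative for c in bucket)
    by_barrier = library.select(19, 2, rule="barrier", energy_params=ref_params)
    g = library.graph
    barriers = {
        c.class_id: cc.min_energy_profile(c.representative, g, ref_params).barrier
        for c in bucket
    }
    assert barriers[by_barrier.class_id] == max(barriers.values())
    pinned = library.select(19, 2, class_id=by_canonical.class_id)
    assert pinned == by_canonical


def test_library_jsonl_roundtrip(cube):
    import json

    lib = cc.build_library(cube)
    lines = lib.to_jsonl().strip().splitlines()
    assert len(lines) == len(lib)
    rec = json.loads(lines[0])
    assert set(rec) == {"class_id", "edges", "mld", "np", "orbit_size", "hamiltonian"}
    mask = cube.edges_to_mask(map(tuple, rec["edges"]))
    assert mask == lib.classes[0].representative
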