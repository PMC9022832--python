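"""Assembly networks: exhaustive minimization, multiplicities, profiles."""

import itertools

import numpy as np
import pytest

import capsid_contest as cc
from capsid_contest.network import build_network, tree_stabilizer


def naive_network_oracle(tree_mask, graph, params):
    """Independent reimplementation by full enumeration: per level, the
    minimum-energy face subsets, deduplicated by explicit stabilizer orbits."""
    stab = [
        g
        for g in range(len(graph.symmetry_group))
        if graph.apply_to_mask(g, tree_mask) == tree_mask
    ]
    F = graph.n_faces
    levels = []
    e_min = []
    for n in range(F + 1):
        best, cfgs = None, []
        for s in itertools.combinations(range(F), n):
            e = cc.assembly_energy(
                cc.AssemblyConfig(tree_mask, frozenset(s)), graph, params
            )
            if best is None or e < best - 1e-9:
                best, cfgs = e, [s]
            elif abs(e - best) <= 1e-9:
                cfgs.append(s)
        e_min.append(best)
        orbits = set()
        for s in cfgs:
            orbits.add(
                frozenset(
                    tuple(sorted(int(graph.face_perms[g][f]) for f in s))
                    for g in stab
                )
            )
        levels.append(orbits)
    return e_min, levels


def test_cube_network_matches_exhaustive_oracle(cube):
    params = cc.EnergyParams(e0=2.0, eps1=-0.5, mu0=-1.5)
    lib = cc.build_library(cube)
    for cls in lib.classes[::3]:
        net = build_network(cls.representative, cube, params)
        e_min, levels = naive_network_oracle(cls.representative, cube, params)
        assert np.allclose(net.e_min, e_min)
        assert net.multiplicities == [len(lv) for lv in levels]
        # each stored representative belongs to one oracle orbit
        for n, lv in enumerate(net.levels):
            oracle_members = {m for orb in levels[n] for m in orb}
            assert all(tuple(c) in oracle_members for c in lv)


def test_min_energy_profile_reference_barriers(
    class98, class192, dodecahedron, ref_params
):
    p98 = cc.min_energy_profile(class98, dodecahedron, ref_params)
    p192 = cc.min_energy_profile(class192, dodecahedron, ref_params)
    assert p98.barrier == pytest.approx(3.0)
    assert p192.barrier == pytest.approx(5.0)
    assert p98.e_min[0] == 0.0 and p192.e_min[0] == 0.0
    assert p98.barrier >= 0 and p192.barrier >= 0


def test_reference_multiplicities(net98):
    assert net98.multiplicities[0] == 1
    assert net98.multiplicities[12] == 1
    assert net98.multiplicities[5] == 4


def test_all_networks_have_unique_endpoints(net98, net192, cube_network):
    for net in (net98, net192, cube_network):
        assert net.multiplicities[0] == 1
        assert net.multiplicities[-1] == 1
        assert net.connectivity_report()["source_to_sink"]


def test_incomplete_particle_ground_state_at_strong_affinity(
    library, dodecahedron
):
    """At eps1 = -1.1 (near assembly equilibrium) the (9,8) classes have
    incomplete-particle ground states: the profile minimum sits at nine or
    ten pentamers depending on the class member, never at the full capsid."""
    params = cc.EnergyParams(
        e0=4.0, eps1=-1.1, mu0=cc.equilibrium_mu0(-1.1)
    )
    argmins = set()
    for cls in library.lookup(9, 8):
        prof = cc.min_energy_profile(cls, dodecahedron, params)
        argmins.add(prof.n_min)
        assert prof.n_min < 12
    assert 10 in argmins


def test_stabilizer_is_subgroup(class98, class192, dodecahedron):
    for cls in (class98, class192):
        stab = tree_stabilizer(cls.representative, dodecahedron)
        assert 120 % len(stab) == 0
        assert len(stab) * cls.orbit_size == 120


def test_equilibrium_distribution_normalization(net98, ref_params):
    rng = np.random.default_rng(5)
    for _ in range(5):
        cf = float(rng.uniform(0.05, 2.0))
        p = cc.equilibrium_distribution(net98, ref_params, cf)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()
    with pytest.raises(ValueError):
        cc.equilibrium_distribution(net98, ref_params, 0.0)


def test_equilibrium_distribution_uniform_when_energies_flat():
    from capsid_contest.pipeline import toy_three_level_network

    net = toy_three_level_network()
    net.e_min = np.zeros(3)
    p = cc.equilibrium_distribution(net, cc.EnergyParams(e0=1.0), c_f=1.0)
    assert np.allclose(p, 1 / 4)


def test_network_adjacency_is_single_pentamer_steps(net98, dodecahedron):
    """Every stored link joins configurations whose orbits differ by
    exactly one occupied face."""
    stab = net98.stabilizer
    fp = dodecahedron.face_perms
    for n in range(12):
        for i, row in enumerate(net98.adjacency[n]):
            parent = set(net98.levels[n][i])
            for j in row:
                child = net98.levels[n + 1][j]
                # some symmetric image of the child contains the parent
                assert any(
                    parent <= {int(fp[g][f]) for f in child} for g in stab
                )


def test_network_serialization_roundtrip(cube_network):
    d = cube_network.to_dict()
    assert d["levels"][0] == {"n": 0, "m": 1, "configs": [[]]}
    assert len(d["levels"]) == cube_network.n_levels
    assert d["e_min"] == [float(x) for x in cube_network.e_min]
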