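"""Shared fixtures.

The dodecahedron spanning-tree library (~5.2M trees, 43k classes) takes
~15 s to build, and the master-equation runs at the reference parameters
are reused by several tests, so everything heavy is session-scoped.
"""

import numpy as np
import pytest

import capsid_contest as cc


@pytest.fixture(scope="session")
def dodecahedron():
    return cc.build_dodecahedron()


@pytest.fixture(scope="session")
def tetrahedron():
    return cc.build_fixture("tetrahedron")


@pytest.fixture(scope="session")
def cube():
    return cc.build_fixture("cube")


@pytest.fixture(scope="session")
def library(dodecahedron):
    return cc.dodecahedron_library()


@pytest.fixture(scope="session")
def ref_params():
    """Reference energy parameters of the packaging-competition study."""
    return cc.EnergyParams(e0=4.0, eps1=-0.5, mu0=-4.0)


@pytest.fixture(scope="session")
def class98(library, ref_params):
    return library.select(9, 8, energy_params=ref_params)


@pytest.fixture(scope="session")
def class192(library, ref_params):
    return library.select(19, 2, energy_params=ref_params)


@pytest.fixture(scope="session")
def net98(class98, dodecahedron, ref_params):
    return cc.build_network(class98, dodecahedron, ref_params)


@pytest.fixture(scope="session")
def net192(class192, dodecahedron, ref_params):
    return cc.build_network(class192, dodecahedron, ref_params)


@pytest.fixture(scope="session")
def single_traj(net98):
    """Single-species (9,8) kinetics at the reference conditions."""
    return cc.integrate(
        [net98], cc.KineticsParams(c0=1.0, d_ratio=0.5), t_end=1e6, n_times=400
    )


@pytest.fixture(scope="session")
def compete_traj(net98, net192):
    """Two-species competition at c0=1, D=0.5 (reference conditions)."""
    return cc.integrate(
        [net98, net192], cc.KineticsParams(c0=1.0, d_ratio=0.5), t_end=1e7,
        n_times=400,
    )


@pytest.fixture(scope="session")
def supersat_traj(net98, net192):
    """Supersaturated stoichiometric competition: c0=4, D=2."""
    return cc.integrate(
        [net98, net192], cc.KineticsParams(c0=4.0, d_ratio=2.0), t_end=1e6,
        n_times=400,
    )


@pytest.fixture(scope="session")
def cube_network(cube):
    """A small assembly network on the cube for exhaustive/stochastic checks."""
    lib = cc.build_library(cube)
    params = cc.EnergyParams(e0=2.0, eps1=-0.5, mu0=-1.5)
    cls = max(lib.classes, key=lambda c: c.orbit_size)
    return cc.build_network(cls, cube, params)
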