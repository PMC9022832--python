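"""Assembly energetics of pentamers on a tree-decorated polyhedron.

A configuration of *n* pentamers placed on faces of the dodecahedron, over a
fixed spanning tree of packaging signals, has assembly energy (in units of
the pentamer-pentamer binding scale E0)

    dE(n) = n1*eps1 + n2*eps2 - n3 - mu0*n

where, classifying every graph edge by whether it carries a tree link and by
how many of its two bordering faces are occupied:

* n1 — tree links along a pentamer edge not shared with another pentamer,
* n2 — tree links along an edge shared by two pentamers,
* n3 — pentamer-pentamer shared edges carrying no tree link,

and mu0 is the reference chemical potential of a free pentamer (it absorbs
the generic, non-specific RNA affinity).  -eps1 is the ratio of the
link-edge affinity to E0; additivity over the two pentamer edges meeting a
shared link fixes eps2 = -1 + 2*eps1, so eps2 is never independently
settable.  E0 itself (in kT) enters only through Boltzmann/Arrhenius
factors exp(-E0 * dE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .polyhedra import PolyhedronGraph

__all__ = [
    "EnergyParams",
    "AssemblyConfig",
    "EdgeCounts",
    "edge_counts",
    "assembly_energy",
    "equilibrium_mu0",
    "eps1_from_assembly_onset",
]


@dataclass(frozen=True)
class EnergyParams:
    """Energy model parameters.

    e0 : overall scale, the pentamer-pentamer edge binding energy in kT.
    eps1 : dimensionless link-edge affinity (typically negative).
    mu0 : reference chemical potential in E0 units, or the string
        ``"equilibrium"`` to place the full capsid at assembly equilibrium
        (dE(12) = 0).
    """

    e0: float = 4.0
    eps1: float = -0.5
    mu0: float | str = -4.0

    def __post_init__(self):
        if self.e0 <= 0:
            raise ValueError("e0 must be positive (it is an energy scale in kT)")
        if self.mu0 == "equilibrium":
            object.__setattr__(self, "mu0", equilibrium_mu0(self.eps1))
        else:
            object.__setattr__(self, "mu0", float(self.mu0))

    @property
    def eps2(self) -> float:
        """Shared-link affinity, fixed by additivity: eps2 = -1 + 2*eps1."""
        return -1.0 + 2.0 * self.eps1


@dataclass(frozen=True)
class EdgeCounts:
    n1: int
    n2: int
    n3: int


@dataclass(frozen=True)
class AssemblyConfig:
    """A spanning tree plus a set of occupied pentamer faces."""

    tree: int  # edge bitmask
    occupied_faces: frozenset[int] = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return len(self.occupied_faces)

    def with_face(self, face: int) -> "AssemblyConfig":
        return AssemblyConfig(self.tree, self.occupied_faces | {face})


def _face_occupancy(config: AssemblyConfig, graph: PolyhedronGraph) -> np.ndarray:
    occ = np.zeros(graph.n_faces, dtype=np.int64)
    for f in config.occupied_faces:
        if not 0 <= f < graph.n_faces:
            raise ValueError(f"face id {f} out of range for {graph.name}")
        occ[f] = 1
    return occ


def edge_counts(config: AssemblyConfig, graph: PolyhedronGraph) -> EdgeCounts:
    """The (n1, n2, n3) edge classification of a configuration."""
    occ = _face_occupancy(config, graph)
    k = graph.edge_face_matrix @ occ  # occupied bordering faces per edge
    tlink = np.array(
        [(config.tree >> i) & 1 for i in range(graph.n_edges)], dtype=bool
    )
    return EdgeCounts(
        n1=int(((k == 1) & tlink).sum()),
        n2=int(((k == 2) & tlink).sum()),
        n3=int(((k == 2) & ~tlink).sum()),
    )


def assembly_energy(
    config: AssemblyConfig, graph: PolyhedronGraph, params: EnergyParams
) -> float:
    """dE of a configuration in E0 units (multiply by e0 for kT)."""
    c = edge_counts(config, graph)
    return c.n1 * params.eps1 + c.n2 * params.eps2 - c.n3 - params.mu0 * config.n


def level_energies(
    tree: int,
    graph: PolyhedronGraph,
    params: EnergyParams,
    occupancy_matrix: np.ndarray,
) -> np.ndarray:
    """Vectorized dE for many configurations of one tree.

    ``occupancy_matrix`` is (n_configs, F) with 0/1 entries.  Used by the
    exhaustive per-level minimization in :mod:`capsid_contest.network`.
    """
    k = occupancy_matrix @ graph.edge_face_matrix.T  # (n_configs, E)
    tlink = np.array([(tree >> i) & 1 for i in range(graph.n_edges)], dtype=bool)
    n1 = ((k == 1) & tlink).sum(axis=1)
    n2 = ((k == 2) & tlink).sum(axis=1)
    n3 = ((k == 2) & ~tlink).sum(axis=1)
    n = occupancy_matrix.sum(axis=1)
    return n1 * params.eps1 + n2 * params.eps2 - n3 - params.mu0 * n


def equilibrium_mu0(eps1: float) -> float:
    """Reference chemical potential placing the complete capsid at assembly
    equilibrium: dE(12) = 19*eps2 - 11 - 12*mu0 = 0.  For eps1 = -0.5 this
    is -49/12 ~ -4.083."""
    return (19.0 * (-1.0 + 2.0 * eps1) - 11.0) / 12.0


def eps1_from_assembly_onset(concentration_ratio: float = 40.0, e0: float = 4.0) -> float:
    """Calibrate eps1 from the ratio of capsid-protein concentrations at
    assembly onset without vs with viral RNA.

    A concentration increase by ``concentration_ratio`` raises the chemical
    potential by ln(ratio) kT = ln(ratio)/e0 in E0 units; requiring that
    this closes the gap between the empty-capsid and virion assembly
    energies gives  -38*eps1 = 12*ln(ratio)/e0,  i.e. -eps1 ~ 0.29 for the
    measured ratio 2.0/0.05 = 40 at e0 = 4.
    """
    return -12.0 * math.log(concentration_ratio) / e0 / 38.0


def full_capsid_energy(params: EnergyParams) -> float:
    """dE(12) = 19*eps2 - 11 - 12*mu0; identical for every spanning tree."""
    return 19.0 * params.eps2 - 11.0 - 12.0 * params.mu0
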