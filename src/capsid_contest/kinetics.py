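"""Master-equation kinetics of packaging, for one or two competing species.

Each RNA species carries its own assembly network; the node occupation
probabilities P_{i,n}(t) evolve by a Markov master equation whose on-rates
follow a kinetic Monte-Carlo (Metropolis) form,

    W(n -> n+1) = lambda * c_f * min(1, exp(-E0 * ddE)),

with ddE = dE_min(n+1) - dE_min(n) in E0 units, and whose off-rates are
fixed by detailed balance against the Boltzmann distribution,

    W(n+1 -> n) = lambda * min(1, exp(+E0 * ddE)),

so that W_on / W_off = c_f * exp(-E0 * ddE) and disassembly never depends
on the free-pentamer concentration.  Ties (ddE = 0) take the unsuppressed
branch on both sides, preserving detailed balance.

The free-pentamer concentration follows from mass conservation,

    c_f / c0 = 1 - (D / (F * n_species)) * sum_species sum_nodes n * P,

with D = F * (RNA concentration) / c0 the mixing ratio (D = 1 is the
stoichiometric ratio; F = 12 pentamers per capsid on the dodecahedron).
Because the rates depend on c_f(t), the system is a coupled nonlinear ODE;
it is integrated with a stiff BDF solver and an analytic Jacobian.  The
right-hand side is exactly  dP/dt = (c_f(P) * M_on + M_off) P  with
constant sparse generator matrices, so the Jacobian is
c_f*M_on + M_off + (M_on P) (dc_f/dP)^T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticsParams",
    "Trajectory",
    "on_rate",
    "off_rate",
    "free_pentamer_fraction",
    "integrate",
    "gillespie_clamped",
]


@dataclass(frozen=True)
class KineticsParams:
    """lambda sets the time unit (1/lambda); c0 the total pentamer
    concentration in reference units; d_ratio the RNA-to-protein mixing
    ratio D.  Two-species runs assume equal RNA concentrations."""

    c0: float = 1.0
    d_ratio: float = 0.5
    lam: float = 1.0

    def __post_init__(self):
        if self.lam <= 0 or self.c0 <= 0 or self.d_ratio <= 0:
            raise ValueError("lambda, c0 and D must all be positive")


def on_rate(delta: float, c_f: float, e0: float, lam: float = 1.0) -> float:
    """Metropolis on-rate for a step with energy cost ``delta`` (E0 units)."""
    if c_f < 0:
        raise ValueError("c_f must be non-negative")
    return lam * c_f * (math.exp(-e0 * delta) if delta > 0 else 1.0)


def off_rate(delta: float, e0: float, lam: float = 1.0) -> float:
    """Off-rate fixed by detailed balance; independent of c_f."""
    return lam * (1.0 if delta > 0 else math.exp(e0 * delta))


def free_pentamer_fraction(
    level_probs: list[np.ndarray], d_ratio: float, capsid_size: int
) -> float:
    """c_f / c0 from mass conservation.

    ``level_probs`` holds, per species, the n-resolved occupation sums
    sum_i P_{i,n}; ``capsid_size`` is F (12 for the dodecahedron).  For one
    species the depletion factor is D/F, for two it is D/(2F).
    """
    nsp = len(level_probs)
    frac = 1.0
    for p in level_probs:
        n = np.arange(len(p))
        frac -= d_ratio / (capsid_size * nsp) * float(n @ p)
    if frac < -1e-9:
        raise RuntimeError(
            f"mass conservation violated: c_f/c0 = {frac:.3g} < 0"
        )
    return max(frac, 0.0)


@dataclass
class Trajectory:
    """Time-resolved solution of the packaging master equation."""

    times: np.ndarray
    node_probs: list[np.ndarray]  # per species, (n_nodes, n_times)
    c_f: np.ndarray
    networks: list
    params: KineticsParams
    clamped: bool = False

    @property
    def n_species(self) -> int:
        return len(self.node_probs)

    def packaged_fraction(self, species: int = 0) -> np.ndarray:
        """P_complete(t): occupation of the full-capsid node."""
        return self.node_probs[species][-1]

    def level_probs(self, species: int = 0) -> np.ndarray:
        """(F+1, n_times) level-summed occupations."""
        net = self.networks[species]
        out = np.zeros((net.n_levels, len(self.times)))
        k = 0
        for n, m in enumerate(net.level_sizes):
            out[n] = self.node_probs[species][k : k + m].sum(axis=0)
            k += m
        return out

    def conservation_error(self) -> float:
        return max(
            float(np.abs(p.sum(axis=0) - 1.0).max()) for p in self.node_probs
        )


def _generator_matrices(network, e0: float, lam: float):
    """Constant matrices M_on, M_off with dP/dt = (c_f*M_on + M_off) P."""
    sizes = network.level_sizes
    N = sum(sizes)
    offs = np.cumsum([0] + sizes)
    e_min = np.asarray(network.e_min, dtype=float)
    M_on = np.zeros((N, N))
    M_off = np.zeros((N, N))
    for n in range(len(sizes) - 1):
        delta = float(e_min[n + 1] - e_min[n])
        f_on = on_rate(delta, 1.0, e0, lam)  # per unit c_f
        f_off = off_rate(delta, e0, lam)
        for i, row in enumerate(network.adjacency[n]):
            gi = offs[n] + i
            for j in row:
                gj = offs[n + 1] + j
                M_on[gj, gi] += f_on
                M_on[gi, gi] -= f_on
                M_off[gi, gj] += f_off
                M_off[gj, gj] -= f_off
    return M_on, M_off, offs


def integrate(
    networks,
    params: KineticsParams,
    t_end: float,
    e0: float | None = None,
    n_times: int = 400,
    t_eval: np.ndarray | None = None,
    clamp_cf: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the coupled master equation from the all-unassembled state.

    Parameters
    ----------
    networks : AssemblyNetwork or sequence of one or two of them
        The species in solution (equal RNA concentrations).
    params : KineticsParams
    t_end : float
        Final time in units of 1/lambda; output is on a log-spaced grid.
    e0 : float, optional
        Energy scale in kT; defaults to the networks' own params.e0.
    clamp_cf : float, optional
        Freeze c_f at this value (linear master equation); used for
        detailed-balance/thermalization checks.

    Returns a :class:`Trajectory`; per-species probability is conserved to
    solver tolerance (checked, error raised beyond 1e-6).
    """
    if not isinstance(networks, (list, tuple)):
        networks = [networks]
    networks = list(networks)
    if not 1 <= len(networks) <= 2:
        raise ValueError("one or two species supported")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if e0 is None:
        e0 = networks[0].params.e0
    nsp = len(networks)
    capsid_size = networks[0].n_levels - 1

    mats = [_generator_matrices(net, e0, params.lam) for net in networks]
    blocks = np.cumsum([0] + [m[0].shape[0] for m in mats])
    N = blocks[-1]
    M_on = np.zeros((N, N))
    M_off = np.zeros((N, N))
    nvec = np.zeros(N)
    for s, (mon, moff, offs) in enumerate(mats):
        sl = slice(blocks[s], blocks[s + 1])
        M_on[sl, sl] = mon
        M_off[sl, sl] = moff
        nvec[sl] = networks[s].node_levels()
    depletion = params.d_ratio / (capsid_size * nsp)
    g = -params.c0 * depletion * nvec  # dc_f/dP

    if clamp_cf is not None:

        def cf_of(y):
            return clamp_cf

    else:

        def cf_of(y):
            return params.c0 * (1.0 - depletion * float(nvec @ y))

    def rhs(t, y):
        return (cf_of(y) * M_on + M_off) @ y

    def jac(t, y):
        J = cf_of(y) * M_on + M_off
        if clamp_cf is None:
            J += np.outer(M_on @ y, g)
        return J

    y0 = np.zeros(N)
    for s in range(nsp):
        y0[blocks[s]] = 1.0
    if t_eval is None:
        t_eval = np.concatenate(
            [[0.0], np.geomspace(min(1e-3, t_end / 100), t_end, n_times)]
        )
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        y0,
        method="BDF",
        jac=jac,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    node_probs = [sol.y[blocks[s] : blocks[s + 1]] for s in range(nsp)]
    cf_t = np.array([cf_of(sol.y[:, k]) for k in range(sol.y.shape[1])])
    traj = Trajectory(
        times=sol.t,
        node_probs=node_probs,
        c_f=cf_t,
        networks=networks,
        params=params,
        clamped=clamp_cf is not None,
    )
    err = traj.conservation_error()
    if err > 1e-6:
        raise RuntimeError(f"probability conservation violated: {err:.3g}")
    return traj


def gillespie_clamped(
    network,
    params: KineticsParams,
    t_grid: np.ndarray,
    cf: float,
    n_walkers: int,
    rng: np.random.Generator,
    e0: float | None = None,
) -> np.ndarray:
    """Stochastic (Gillespie) simulation of one molecule's assembly CTMC at
    fixed free-pentamer concentration.

    Returns mean node occupations (n_nodes, len(t_grid)) over ``n_walkers``
    independent molecules.  Fixture-scale cross-check for the ODE solver:
    at clamped c_f the master equation is linear and the ensemble mean must
    match the ODE solution within Monte-Carlo error.
    """
    if e0 is None:
        e0 = network.params.e0
    sizes = network.level_sizes
    offs = np.cumsum([0] + sizes)
    e_min = np.asarray(network.e_min, dtype=float)
    # per-node outgoing events: (rate, target_node)
    events: list[list[tuple[float, int]]] = [[] for _ in range(sum(sizes))]
    for n in range(len(sizes) - 1):
        delta = float(e_min[n + 1] - e_min[n])
        w_up = on_rate(delta, cf, e0, params.lam)
        w_dn = off_rate(delta, e0, params.lam)
        for i, row in enumerate(network.adjacency[n]):
            for j in row:
                events[offs[n] + i].append((w_up, offs[n + 1] + j))
                events[offs[n + 1] + j].append((w_dn, offs[n] + i))
    totals = np.array([sum(r for r, _ in ev) for ev in events])
    occ = np.zeros((sum(sizes), len(t_grid)))
    for _ in range(n_walkers):
        state, t, k = 0, 0.0, 0
        while k < len(t_grid):
            rate = totals[state]
            t_next = t + (rng.exponential(1.0 / rate) if rate > 0 else np.inf)
            while k < len(t_grid) and t_grid[k] < t_next:
                occ[state, k] += 1
                k += 1
            if not np.isfinite(t_next):
                break
            t = t_next
            u = rng.random() * rate
            acc = 0.0
            for r, tgt in events[state]:
                acc += r
                if u <= acc:
                    state = tgt
                    break
    return occ / n_walkers
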