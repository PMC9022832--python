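"""Master-equation kinetics: rates, detailed balance, conservation,
stationarity, and a stochastic cross-check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capsid_contest as cc
from capsid_contest.kinetics import gillespie_clamped
from capsid_contest.pipeline import toy_three_level_network


def test_on_rate_branches():
    assert cc.on_rate(-0.7, 2.0, e0=4.0) == 2.0  # downhill: bare rate
    assert cc.on_rate(0.0, 2.0, e0=4.0) == 2.0  # tie: unsuppressed branch
    assert cc.on_rate(1.0, 1.0, e0=4.0) == pytest.approx(math.exp(-4.0))
    with pytest.raises(ValueError):
        cc.on_rate(1.0, -0.1, e0=4.0)


def test_off_rate_branches():
    assert cc.off_rate(0.7, e0=4.0) == 1.0  # uphill addition: bare removal
    assert cc.off_rate(0.0, e0=4.0) == 1.0
    assert cc.off_rate(-1.0, e0=4.0) == pytest.approx(math.exp(-4.0))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    delta=st.floats(min_value=-3, max_value=3),
    cf=st.floats(min_value=1e-3, max_value=5.0),
    e0=st.floats(min_value=0.5, max_value=6.0),
)
def test_detailed_balance_ratio(delta, cf, e0):
    """on/off = c_f * exp(-e0*ddE): the Boltzmann ratio of Eq-1 levels."""
    ratio = cc.on_rate(delta, cf, e0) / cc.off_rate(delta, e0)
    assert ratio == pytest.approx(cf * math.exp(-e0 * delta), rel=1e-12)


def test_free_pentamer_fraction_limits():
    p0 = np.zeros(13)
    p0[0] = 1.0
    assert cc.free_pentamer_fraction([p0], 0.5, 12) == 1.0
    full = np.zeros(13)
    full[12] = 1.0
    # two fully packaged species at the stoichiometric ratio exhaust the pool
    assert cc.free_pentamer_fraction([full, full], 1.0, 12) == pytest.approx(0.0)
    assert cc.free_pentamer_fraction([full], 0.5, 12) == pytest.approx(0.5)
    with pytest.raises(RuntimeError):
        cc.free_pentamer_fraction([full, full], 4.0, 12)


def test_probability_conservation_and_cf_bounds(single_traj, compete_traj):
    for traj in (single_traj, compete_traj):
        assert traj.conservation_error() < 1e-6
        assert np.all(traj.c_f >= -1e-12)
        assert np.all(traj.c_f <= traj.params.c0 + 1e-12)


def test_toy_network_clamped_stationarity_analytic():
    """On the 3-level toy ladder the stationary state can be written down:
    P(n) ~ exp(-e0*dE(n) + n ln c_f), normalized with multiplicities."""
    net = toy_three_level_network()
    cf = 0.7
    traj = cc.integrate(
        net, cc.KineticsParams(c0=1.0, d_ratio=0.5), t_end=1e4, clamp_cf=cf
    )
    e0 = net.params.e0
    w = np.exp(-e0 * np.asarray(net.e_min) + np.arange(3) * math.log(cf))
    z = w[0] + 2 * w[1] + w[2]
    expected = np.array([w[0], w[1], w[1], w[2]]) / z
    assert np.allclose(traj.node_probs[0][:, -1], expected, atol=1e-8)
    # and it agrees with the package's own equilibrium distribution
    assert np.allclose(
        expected, cc.equilibrium_distribution(net, net.params, cf), atol=1e-12
    )


def test_clamped_master_equation_thermalizes_to_boltzmann(net98, ref_params):
    traj = cc.integrate(
        net98,
        cc.KineticsParams(c0=1.0, d_ratio=0.5),
        t_end=1e9,
        e0=3.0,
        clamp_cf=0.8,
        n_times=60,
    )
    eq = cc.equilibrium_distribution(net98, cc.EnergyParams(e0=3.0, eps1=-0.5, mu0=-4.0), 0.8)
    assert np.allclose(traj.node_probs[0][:, -1], eq, atol=1e-7)


def test_relative_entropy_decreases_under_clamped_dynamics(net98):
    """KL divergence to the Boltzmann state is a Lyapunov function of the
    (linear, detailed-balanced) clamped master equation."""
    cf = 0.8
    traj = cc.integrate(
        net98,
        cc.KineticsParams(c0=1.0, d_ratio=0.5),
        t_end=1e8,
        e0=3.0,
        clamp_cf=cf,
        n_times=50,
    )
    eq = cc.equilibrium_distribution(
        net98, cc.EnergyParams(e0=3.0, eps1=-0.5, mu0=-4.0), cf
    )
    p = np.clip(traj.node_probs[0], 1e-300, None)
    kl = (p * np.log(p / eq[:, None])).sum(axis=0)
    assert np.all(np.diff(kl) < 1e-9)


def test_gillespie_matches_ode_on_cube(cube_network):
    """Ensemble means of the exact stochastic process reproduce the clamped
    ODE level occupancies within Monte-Carlo error."""
    cf = 0.9
    t_grid = np.linspace(0.5, 25.0, 12)
    n_walkers = 4000
    occ = gillespie_clamped(
        cube_network,
        cc.KineticsParams(c0=1.0, d_ratio=0.5),
        t_grid,
        cf=cf,
        n_walkers=n_walkers,
        rng=np.random.default_rng(42),
    )
    traj = cc.integrate(
        cube_network,
        cc.KineticsParams(c0=1.0, d_ratio=0.5),
        t_end=float(t_grid[-1]),
        clamp_cf=cf,
        t_eval=t_grid,
    )
    ode = traj.node_probs[0]
    # aggregate to levels to keep the MC error manageable
    sizes = cube_network.level_sizes
    offs = np.cumsum([0] + sizes)
    for lvl in range(len(sizes)):
        sl = slice(offs[lvl], offs[lvl + 1])
        a = occ[sl].sum(axis=0)
        b = ode[sl].sum(axis=0)
        sigma = np.sqrt(np.maximum(b * (1 - b), 1e-4) / n_walkers)
        assert np.all(np.abs(a - b) < 5 * sigma)


def test_single_vs_competition_consistency(single_traj, compete_traj):
    """Early on (c_f ~ c0) the encoded species assembles identically whether
    or not a slow competitor is present."""
    t_probe = 300.0
    k1 = np.searchsorted(single_traj.times, t_probe)
    k2 = np.searchsorted(compete_traj.times, t_probe)
    p1 = single_traj.packaged_fraction(0)[k1]
    p2 = compete_traj.packaged_fraction(0)[k2]
    assert p2 == pytest.approx(p1, rel=0.05)


def test_thermalization_ordering(net98, net192):
    """The linear-chain species equilibrates far slower than the compact
    one — its assembly activation barrier is 2 E0 (8 kT) higher — with a
    separation of at least two orders of magnitude in time."""
    kp = cc.KineticsParams(c0=1.0, d_ratio=0.5)

    def time_to_equilibrium(net):
        traj = cc.integrate(net, kp, t_end=1e10, n_times=300)
        p = traj.packaged_fraction(0)
        final = p[-1]
        k = np.argmax(p >= 0.95 * final)
        return traj.times[k], final

    t98, f98 = time_to_equilibrium(net98)
    t192, f192 = time_to_equilibrium(net192)
    # both classes reach nearly the same equilibrium packaged fraction
    assert f192 == pytest.approx(f98, abs=0.03)
    assert t192 / t98 > 100


def test_integrate_input_validation(net98):
    kp = cc.KineticsParams(c0=1.0, d_ratio=0.5)
    with pytest.raises(ValueError):
        cc.integrate(net98, kp, t_end=0.0)
    with pytest.raises(ValueError):
        cc.integrate([net98, net98, net98], kp, t_end=1.0)
    with pytest.raises(ValueError):
        cc.KineticsParams(c0=-1.0, d_ratio=0.5)
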