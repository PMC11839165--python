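"""Shared-enzyme catalytic model: closed form, pulse, robustness mechanics."""

from dataclasses import replace

import numpy as np
import pytest

import centrosim as cs
from centrosim.catalytic import (CatalyticParams, CatalyticState,
                                 build_catalytic_network, catalytic_rhs,
                                 pulse_metrics, steady_state_volume)
from centrosim.ssa import Trajectory
from centrosim.units import initial_counts


def test_rhs_no_growth_without_enzyme_or_centriolar_assembly(fig3_params):
    p = replace(fig3_params, k_plus=0.0)
    st = CatalyticState(Sn=(100.0, 80.0), S1_star=0.0, E_star=0.0)
    d = catalytic_rhs(st, p)
    assert d[0] == pytest.approx(-p.k_minus * 100.0)
    assert d[1] == pytest.approx(-p.k_minus * 80.0)


def test_rhs_symmetric_state_symmetric_derivatives(fig3_params):
    st = CatalyticState(Sn=(500.0, 500.0), S1_star=100.0, E_star=50.0)
    d = catalytic_rhs(st, fig3_params)
    assert d[0] == d[1]


def test_rhs_rejects_constraint_violation(fig3_params):
    st = CatalyticState(Sn=(fig3_params.N, fig3_params.N), S1_star=10.0,
                        E_star=0.0)
    with pytest.raises(ValueError):
        catalytic_rhs(st, fig3_params)


def test_rhs_consistent_with_network_mean_field(fig3_params):
    """catalytic_rhs and the network's Σ aⱼ·Δⱼ are the same vector field."""
    net = build_catalytic_network(fig3_params, (25, 25))
    x = net.initial_state.astype(float)
    # move to a generic interior point
    x[net.index("S1s")] = 5000.0
    x[net.index("Es")] = 2000.0
    x[net.index("Sn1")], x[net.index("Sn2")] = 800.0, 600.0
    x[net.index("E")] = fig3_params.N_E - 2000.0 - 5000.0
    x[net.index("S1")] = fig3_params.N - 5000.0 - 800.0 - 600.0
    dx = net.propensity_vector(x) @ net.delta_matrix().astype(float)
    st = CatalyticState(Sn=(800.0, 600.0), S1_star=5000.0, E_star=2000.0)
    d = catalytic_rhs(st, fig3_params)
    assert dx[net.index("Sn1")] == pytest.approx(d[0])
    assert dx[net.index("Sn2")] == pytest.approx(d[1])
    assert dx[net.index("S1s")] == pytest.approx(d[2])
    assert dx[net.index("Es")] == pytest.approx(d[3])


def test_steady_state_volume_no_disassembly_converts_whole_pool(fig3_params):
    p = replace(fig3_params, k_minus=0.0)
    v = steady_state_volume(p, E_star_ss=1000.0)
    assert v == pytest.approx(p.rho0 * p.omega * p.delta_v)


def test_steady_state_volume_without_active_enzyme(fig3_params):
    p = fig3_params
    v = steady_state_volume(p, E_star_ss=0.0)
    expected = p.k_plus * p.rho0 * p.omega * p.delta_v / (
        p.k_plus + p.k_minus * p.omega)
    assert v == pytest.approx(expected)


def test_steady_state_volume_matches_ode_over_random_sample():
    """Closed form vs long-time single-centrosome integration, 10 random
    parameter sets, 1% relative."""
    rng = np.random.default_rng(2024)
    for _ in range(10):
        p = CatalyticParams(
            k_plus=10 ** rng.uniform(-1, 2),
            k_star=10 ** rng.uniform(2.5, 3.5),
            k1_star=10 ** rng.uniform(0, 2),
            kE_star=10 ** rng.uniform(0, 1),
            rho0=10 ** rng.uniform(-1.5, -0.5),
            E_conc=10 ** rng.uniform(-1.5, -1),
            Vc=500.0,
        )
        net = build_catalytic_network(p, (25,))
        traj = cs.simulate_ode(net, 60000.0, rtol=1e-10, atol=1e-8)
        e_star_end = traj.series("Es")[-1]
        v_closed = steady_state_volume(p, E_star_ss=e_star_end)
        assert traj.final("V1") == pytest.approx(v_closed, rel=0.01), p


def test_self_consistent_e_star_agrees_with_ode(fig3_params):
    p = replace(fig3_params, Vc=500.0)
    net = build_catalytic_network(p, (25,))
    traj = cs.simulate_ode(net, 60000.0, rtol=1e-10, atol=1e-8)
    assert steady_state_volume(p) == pytest.approx(traj.final("V1"), rel=0.01)


def test_unlimited_mode_depletes_inactive_subunit_pool():
    s = cs.load_scenario("fig3gh")
    p = replace(s.params, Vc=500.0)
    net = build_catalytic_network(p, (25, 25))
    traj = cs.simulate_ode(net, 30000.0)
    s1, s1s = traj.series("[S1]")[-1], traj.series("[S1s]")[-1]
    assert s1 < 0.1 * s1s    # free S1 ≪ free S1* at steady state


def test_unlimited_mode_has_no_enzyme_bookkeeping():
    s = cs.load_scenario("fig3gh")
    net = build_catalytic_network(s.params, (25, 25))
    assert "E" not in net.species
    assert [n for n, _, _ in net.conserved] == ["subunits"]


def test_ssa_mean_tracks_ode(small_catalytic_params):
    p = small_catalytic_params
    net = build_catalytic_network(p, (25, 25))
    ode = cs.simulate_ode(net, 2000.0, n_grid=10)
    acc = np.zeros(len(ode.times))
    n_runs = 300
    for seed in range(n_runs):
        tr = cs.simulate_ssa(net, 2000.0, seed, n_grid=10)
        acc += tr.series("Sn1")
    mean = acc / n_runs
    ref = ode.series("Sn1")
    mask = ode.times >= 200.0
    assert np.all(np.abs(mean[mask] - ref[mask]) / ref[mask] < 0.05)


def test_pulse_metrics_triangular_pulse():
    t = np.linspace(0, 100, 201)
    h, w = 4.0, 40.0    # rises 0→h over w/2, falls back over w/2
    y = np.interp(t, [0, 10, 10 + w / 2, 10 + w, 100], [0, 0, h, 0, 0])
    traj = Trajectory(times=t, states=np.zeros((len(t), 1), dtype=np.int64),
                      species=["x"], derived={"x": y})
    pm = pulse_metrics(traj, "x")
    assert pm is not None
    assert pm.amplitude == pytest.approx(h)
    assert pm.peak_time == pytest.approx(10 + w / 2, abs=1.0)
    assert pm.lifetime == pytest.approx(w / 2, rel=0.05)


def test_no_pulse_without_enzyme_activation(fig3_params):
    p = replace(fig3_params, kE_star=0.0, Vc=500.0)
    net = build_catalytic_network(p, (25, 25))
    traj = cs.simulate_ode(net, 2000.0)
    assert np.allclose(traj.series("[Es]"), 0.0)
    assert pulse_metrics(traj, "[Es]") is None


def test_monotone_series_reports_no_pulse():
    t = np.linspace(0, 10, 50)
    traj = Trajectory(times=t, states=np.zeros((50, 1), dtype=np.int64),
                      species=["x"], derived={"x": t ** 2})
    assert pulse_metrics(traj, "x") is None


def test_halving_activation_rate_lowers_and_widens_pulse(fig3_params):
    def pulse_for(scale):
        p = replace(fig3_params, kE_star=fig3_params.kE_star * scale)
        net = build_catalytic_network(p, (25, 25))
        traj = cs.simulate_ode(net, 6000.0)
        return pulse_metrics(traj, "[Es]")

    full, half = pulse_for(1.0), pulse_for(0.5)
    assert full is not None and half is not None
    assert half.amplitude < full.amplitude
    assert half.lifetime > full.lifetime


def test_deterministic_pair_forgets_initial_difference(fig3_params):
    for dv0 in (5e-4, 2e-3):
        n1, n2 = initial_counts(5e-3, dv0, fig3_params.delta_v)
        net = build_catalytic_network(fig3_params, (n1, n2))
        traj = cs.simulate_ode(net, 6000.0)
        v1, v2 = traj.final("V1"), traj.final("V2")
        assert abs(v1 - v2) / ((v1 + v2) / 2) < 1e-4


def test_size_difference_decays_monotonically(fig3_params):
    """Deterministic relaxation of an imposed perturbation (linear-stability
    prediction: exponential decay of |V1 − V2|)."""
    n1, n2 = initial_counts(5e-3, 2e-3, fig3_params.delta_v)
    net = build_catalytic_network(fig3_params, (n1, n2))
    traj = cs.simulate_ode(net, 6000.0)
    dv = np.abs(traj.series("V1") - traj.series("V2"))
    # sample every ~200 s; allow numerical jitter at the 1e-12 level
    idx = np.arange(0, len(dv), len(dv) // 30)
    diffs = np.diff(dv[idx])
    assert np.all(diffs <= 1e-12)
    assert dv[-1] < 0.01 * dv[0]


def test_sigmoidality_map_corners():
    """Hill exponent ≥ 2 in the high-[E]/low-k⁺ corner, < 2 in the
    low-[E]/high-k⁺ corner of a 3×3 grid."""
    base = cs.load_scenario("fig3f").params
    alphas = {}
    for kp in (1.0, 100.0, 1000.0):
        for econc in (0.01, 0.085, 0.3):
            p = replace(base, k_plus=kp, E_conc=econc)
            net = build_catalytic_network(p, (25,))
            traj = cs.simulate_ode(net, 30000.0, n_grid=600)
            fit = cs.fit_hill(traj.times, traj.series("V1"))
            alphas[(kp, econc)] = fit.alpha
    assert alphas[(1.0, 0.3)] >= 2.0
    assert alphas[(1000.0, 0.01)] < 2.0


def test_enzyme_conservation_includes_sequestered_s1_star(small_catalytic_params):
    net = build_catalytic_network(small_catalytic_params, (25, 25))
    traj = cs.simulate_ssa(net, 200.0, seed=12, recording="every_event")
    vec = net.vector({"E": 1.0, "Es": 1.0, "S1s": 1.0})
    sums = traj.states @ vec
    assert np.array_equal(sums, np.full(len(sums),
                                        small_catalytic_params.N_E))
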