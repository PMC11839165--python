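"""The Gillespie engine against analytically solvable processes."""

import numpy as np
import pytest

import centrosim as cs
from centrosim.ssa import Reaction, ReactionNetwork, SimulationError


def death_network(n0=100, d=0.01):
    return ReactionNetwork(
        species=["n"],
        initial_state=np.array([n0]),
        reactions=[Reaction("death", d, {"n": -1}, factor1={"n": 1.0})],
    )


def birth_death_network(b=5.0, d=0.1, n0=0):
    return ReactionNetwork(
        species=["n"],
        initial_state=np.array([n0]),
        reactions=[
            Reaction("birth", b, {"n": +1}),
            Reaction("death", d, {"n": -1}, factor1={"n": 1.0}),
        ],
    )


def test_pure_death_ensemble_mean():
    # linear death: <n(t)> = n0 exp(-d t); at t = 1/d this is n0/e ≈ 36.8
    net = death_network()
    finals = [cs.simulate_ssa(net, 100.0, seed, n_grid=2).final("n")
              for seed in range(1000)]
    mean = np.mean(finals)
    expected = 100 * np.exp(-1.0)
    se = np.std(finals, ddof=1) / np.sqrt(len(finals))
    assert abs(mean - expected) < 3 * se + 1e-9


def test_birth_death_stationary_mean():
    # stationary law is Poisson with mean b/d = 50; time-average a long run
    net = birth_death_network()
    traj = cs.simulate_ssa(net, 5000.0, seed=7, n_grid=5000)
    burn = traj.times > 200.0     # ~20 relaxation times of burn-in
    vals = traj.series("n")[burn]
    # ~1/d-spaced samples are roughly independent: conservative SE estimate
    n_eff = (traj.times[-1] - 200.0) * 0.1
    se = np.sqrt(50.0) / np.sqrt(n_eff)
    assert abs(vals.mean() - 50.0) < 3 * se


def test_all_zero_propensities_absorbed():
    net = ReactionNetwork(
        species=["n"], initial_state=np.array([5]),
        reactions=[Reaction("noop", 0.0, {"n": -1}, factor1={"n": 1.0})],
    )
    traj = cs.simulate_ssa(net, 10.0, seed=1, recording="every_event")
    assert traj.absorbed
    assert len(traj.times) == 1 and traj.states[0, 0] == 5


def test_determinism_same_seed_same_event_sequence():
    net = birth_death_network()
    a = cs.simulate_ssa(net, 200.0, seed=42, recording="every_event")
    b = cs.simulate_ssa(net, 200.0, seed=42, recording="every_event")
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)
    c = cs.simulate_ssa(net, 200.0, seed=43, recording="every_event")
    assert not np.array_equal(a.times[: len(c.times)], c.times[: len(a.times)])


def test_python_fallback_matches_kernel_rng_semantics():
    # a callable-propensity clone of the death process must reproduce the
    # kernel path draw-for-draw (same generator, same draw order)
    fast = death_network(n0=50, d=0.02)
    slow = ReactionNetwork(
        species=["n"], initial_state=np.array([50]),
        reactions=[Reaction("death", 0.02, {"n": -1},
                            propensity=lambda x: 0.02 * x[0])],
    )
    a = cs.simulate_ssa(fast, 100.0, seed=5, recording="every_event")
    b = cs.simulate_ssa(slow, 100.0, seed=5, recording="every_event")
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)


def test_reversible_isomerization_binomial_occupancy():
    # A <-> B with equal rates: stationary occupancy of A is Binomial(N, 1/2)
    N = 20
    net = ReactionNetwork(
        species=["A", "B"], initial_state=np.array([N, 0]),
        reactions=[
            Reaction("fwd", 1.0, {"A": -1, "B": +1}, factor1={"A": 1.0}),
            Reaction("rev", 1.0, {"B": -1, "A": +1}, factor1={"B": 1.0}),
        ],
        conserved=[("total", {"A": 1.0, "B": 1.0}, float(N))],
    )
    traj = cs.simulate_ssa(net, 500.0, seed=11, n_grid=5000)
    vals = traj.series("A")[traj.times > 10.0]
    n_eff = 490.0 * 2.0       # relaxation rate is (k_f + k_r) = 2 s⁻¹
    se = np.sqrt(N * 0.25) / np.sqrt(n_eff)
    assert abs(vals.mean() - N / 2) < 3 * se


def test_conserved_sums_exact_at_every_event(small_catalytic_params):
    net = cs.build_catalytic_network(small_catalytic_params, (25, 25))
    traj = cs.simulate_ssa(net, 50.0, seed=3, recording="every_event")
    for name, coefs, total in net.conserved:
        vec = net.vector(coefs)
        sums = traj.states @ vec
        assert np.array_equal(sums, np.full(len(sums), total)), name


def test_bad_propensity_diagnostics():
    neg = ReactionNetwork(
        species=["n"], initial_state=np.array([5]),
        reactions=[Reaction("broken", 1.0, {"n": -1},
                            propensity=lambda x: -1.0)],
    )
    with pytest.raises(SimulationError, match="broken"):
        cs.simulate_ssa(neg, 1.0, seed=1)
    nan = ReactionNetwork(
        species=["n"], initial_state=np.array([5]),
        reactions=[Reaction("nanprop", 1.0, {"n": -1},
                            propensity=lambda x: float("nan"))],
    )
    with pytest.raises(SimulationError, match="NaN"):
        cs.simulate_ssa(nan, 1.0, seed=1)


def test_conservation_violated_at_start_rejected():
    with pytest.raises(ValueError, match="conserved"):
        ReactionNetwork(
            species=["A"], initial_state=np.array([3]),
            reactions=[Reaction("r", 0.0, {"A": -1}, factor1={"A": 1.0})],
            conserved=[("total", {"A": 1.0}, 5.0)],
        )


def test_ode_pure_death_closed_form():
    net = death_network(n0=100, d=0.01)
    traj = cs.simulate_ode(net, 300.0, rtol=1e-10, atol=1e-10)
    expected = 100 * np.exp(-0.01 * traj.times)
    assert np.allclose(traj.series("n"), expected, rtol=1e-6, atol=1e-6)


def test_ode_zero_rate_constant_trajectory():
    net = ReactionNetwork(
        species=["n"], initial_state=np.array([7]),
        reactions=[Reaction("r", 0.0, {"n": +1})],
    )
    traj = cs.simulate_ode(net, 10.0)
    assert np.allclose(traj.series("n"), 7.0)


def test_run_ensemble_single_run_reduces_to_simulate():
    net = birth_death_network()
    summ = cs.run_ensemble(lambda seed: net, 1, base_seed=9, t_max=100.0,
                           reducers={"final_n": lambda tr: tr.final("n")},
                           n_grid=2)
    direct = cs.simulate_ssa(net, 100.0, seed=9, n_grid=2)
    assert summ.table.loc[0, "final_n"] == direct.final("n")
    assert summ.table.loc[0, "seed"] == 9


def test_run_ensemble_seed_sequence_and_reducers():
    net = death_network()
    summ = cs.run_ensemble(lambda seed: net, 5, base_seed=100, t_max=10.0,
                           reducers={"n": lambda tr: tr.final("n")}, n_grid=2)
    assert list(summ.table["seed"]) == [100, 101, 102, 103, 104]
    assert (summ.table["n"] >= 0).all()


def test_degenerate_single_path_identical_finals():
    # one irreversible chain with huge rate: every run is absorbed at the
    # same final state
    def factory(seed):
        return ReactionNetwork(
            species=["A", "B"], initial_state=np.array([10, 0]),
            reactions=[Reaction("r", 1e6, {"A": -1, "B": +1},
                                factor1={"A": 1.0})],
        )
    summ = cs.run_ensemble(factory, 5, base_seed=0, t_max=1.0,
                           reducers={"B": lambda tr: tr.final("B")}, n_grid=2)
    assert (summ.table["B"] == 10).all()


def test_trajectory_series_and_frame_round_trip(tmp_path):
    net = birth_death_network()
    traj = cs.simulate_ssa(net, 50.0, seed=2, n_grid=10)
    df = traj.to_frame()
    assert list(df.columns)[:2] == ["time", "n"]
    p = tmp_path / "t.csv"
    traj.write_csv(p)
    assert p.read_text().startswith("time,n")
    with pytest.raises(KeyError):
        traj.series("missing")
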