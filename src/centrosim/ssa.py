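"""Exact stochastic simulation (Gillespie direct method) and its
deterministic mass-action twin, over arbitrary reaction networks.

The direct method draws, at each step, a waiting time

    τ = (Σᵢ aᵢ)⁻¹ ln(1/r₁)

and selects reaction j as the first index whose cumulative propensity
exceeds r₂·Σᵢ aᵢ (half-open interval convention, first index on ties),
with r₁ drawn before r₂ from a single seeded generator per run.  The same
reaction network drives :func:`simulate_ode`, whose right-hand side is the
mean-field  dx/dt = Σⱼ aⱼ(x)·Δⱼ.

Reactions whose propensity is a product of up to two affine functions of
the state (all mass-action kinetics used in this package) are dispatched
to a compiled kernel; reactions with an arbitrary callable propensity fall
back to a pure-Python loop with identical sampling semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "EnsembleSummary",
    "SimulationError",
    "simulate_ssa",
    "simulate_ode",
    "run_ensemble",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot proceed (bad propensity, overflow...)."""


@dataclass
class Reaction:
    """A single reaction channel.

    The propensity is ``rate · f1(x) · f2(x)`` with ``f(x) = Σ coef·x + const``
    (an omitted factor is 1).  ``changes`` maps species names to their
    integer stoichiometric change.  Alternatively supply ``propensity``, an
    arbitrary ``f(state_vector) -> float``; such reactions are excluded
    from the compiled fast path.
    """

    name: str
    rate: float
    changes: Mapping[str, int]
    factor1: Mapping[str, float] | None = None
    const1: float = 0.0
    factor2: Mapping[str, float] | None = None
    const2: float = 0.0
    propensity: Callable[[np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        if self.propensity is None:
            if self.rate < 0:
                raise ValueError(f"reaction {self.name!r}: rate must be >= 0")
            if self.factor1 is None and self.const1 == 0.0:
                self.const1 = 1.0
            if self.factor2 is None and self.const2 == 0.0:
                self.const2 = 1.0


@dataclass
class ReactionNetwork:
    """Species, initial counts, reactions and conservation laws.

    ``conserved`` lists (name, coefficient-map, total) triples; each must
    hold at the initial state and — for SSA paths — at every event.
    ``derived`` maps a series name to (coefficient-map, scale): linear
    read-outs such as centrosome volume V = δv·n or a concentration
    [X] = X/(c·Vc).
    """

    species: Sequence[str]
    initial_state: np.ndarray
    reactions: Sequence[Reaction]
    conserved: Sequence[tuple[str, Mapping[str, float], float]] = field(default_factory=list)
    derived: Mapping[str, tuple[Mapping[str, float], float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        if self.initial_state.shape != (len(self.species),):
            raise ValueError("initial_state length must match species")
        if (self.initial_state < 0).any():
            raise ValueError("initial counts must be non-negative")
        self._index = {s: i for i, s in enumerate(self.species)}
        for name, coefs, total in self.conserved:
            got = self.conserved_value(coefs, self.initial_state)
            if abs(got - total) > 1e-9 * max(1.0, abs(total)):
                raise ValueError(
                    f"conserved sum {name!r} violated at initial state: "
                    f"{got} != {total}"
                )

    # -- helpers -------------------------------------------------------
    def index(self, species: str) -> int:
        return self._index[species]

    def vector(self, coefs: Mapping[str, float]) -> np.ndarray:
        v = np.zeros(len(self.species))
        for s, c in coefs.items():
            v[self._index[s]] = c
        return v

    def conserved_value(self, coefs: Mapping[str, float], state: np.ndarray) -> float:
        return float(self.vector(coefs) @ state)

    def delta_matrix(self) -> np.ndarray:
        d = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for s, c in r.changes.items():
                d[j, self._index[s]] = c
        return d

    @property
    def all_bilinear(self) -> bool:
        return all(r.propensity is None for r in self.reactions)

    def compile(self):
        """Pack bilinear reactions into the sparse arrays the kernel uses."""
        if not self.all_bilinear:
            raise ValueError("network contains callable-propensity reactions")
        R = len(self.reactions)
        nz1 = max(1, max((len(r.factor1 or {}) for r in self.reactions), default=1))
        nz2 = max(1, max((len(r.factor2 or {}) for r in self.reactions), default=1))
        nzd = max(1, max(len(r.changes) for r in self.reactions))
        rates = np.array([r.rate for r in self.reactions])
        i1 = np.zeros((R, nz1), np.int64)
        co1 = np.zeros((R, nz1), np.float64)
        c1 = np.zeros(R)
        n1 = np.zeros(R, np.int64)
        i2 = np.zeros((R, nz2), np.int64)
        co2 = np.zeros((R, nz2), np.float64)
        c2 = np.zeros(R)
        n2 = np.zeros(R, np.int64)
        d_idx = np.zeros((R, nzd), np.int64)
        d_val = np.zeros((R, nzd), np.int64)
        d_n = np.zeros(R, np.int64)
        for j, r in enumerate(self.reactions):
            c1[j], c2[j] = r.const1, r.const2
            for k, (s, c) in enumerate((r.factor1 or {}).items()):
                i1[j, k], co1[j, k] = self._index[s], c
                n1[j] = k + 1
            for k, (s, c) in enumerate((r.factor2 or {}).items()):
                i2[j, k], co2[j, k] = self._index[s], c
                n2[j] = k + 1
            for k, (s, c) in enumerate(r.changes.items()):
                d_idx[j, k], d_val[j, k] = self._index[s], c
                d_n[j] = k + 1
        return rates, i1, co1, c1, n1, i2, co2, c2, n2, d_idx, d_val, d_n

    def propensity_vector(self, state: np.ndarray) -> np.ndarray:
        """Evaluate all propensities at a (possibly continuous) state."""
        out = np.empty(len(self.reactions))
        for j, r in enumerate(self.reactions):
            if r.propensity is not None:
                out[j] = r.propensity(state)
            else:
                f1 = r.const1 + sum(
                    c * state[self._index[s]] for s, c in (r.factor1 or {}).items()
                )
                f2 = r.const2 + sum(
                    c * state[self._index[s]] for s, c in (r.factor2 or {}).items()
                )
                out[j] = r.rate * f1 * f2
        return out


@dataclass
class Trajectory:
    """Time-stamped states plus derived scalar series."""

    times: np.ndarray
    states: np.ndarray
    species: Sequence[str]
    derived: dict[str, np.ndarray] = field(default_factory=dict)
    absorbed: bool = False
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        """A species column or a derived series, by name."""
        if name in self.derived:
            return self.derived[name]
        try:
            i = list(self.species).index(name)
        except ValueError:
            raise KeyError(
                f"{name!r} is neither a species nor a derived series"
            ) from None
        return self.states[:, i]

    def final(self, name: str) -> float:
        return float(self.series(name)[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        for k, v in self.derived.items():
            df[k] = v
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_meta(self, path) -> None:
        meta = dict(self.meta)
        meta.update(seed=self.seed, absorbed=self.absorbed)
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def _attach_derived(network: ReactionNetwork, traj: Trajectory) -> Trajectory:
    for name, (coefs, scale) in network.derived.items():
        traj.derived[name] = scale * (traj.states @ network.vector(coefs))
    return traj


_STATUS_MSG = {
    -1: "negative propensity",
    -2: "NaN propensity",
    -3: "state driven negative",
}


def _raise_status(network: ReactionNetwork, status: int, info: int) -> None:
    rname = network.reactions[info].name if 0 <= info < len(network.reactions) else "?"
    raise SimulationError(f"{_STATUS_MSG[status]} in reaction {rname!r}")


def simulate_ssa(
    network: ReactionNetwork,
    t_max: float,
    seed: int,
    recording: str = "grid",
    dt: float | None = None,
    n_grid: int | None = None,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Run one exact SSA realisation of ``network`` until ``t_max``.

    recording="grid" stores the state on a uniform grid (default
    t_max/500, i.e. 501 samples); recording="every_event" stores every
    reaction event.  Identical (network, seed) pairs give bit-identical
    trajectories.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    if recording == "grid":
        if n_grid is None:
            n_grid = 500 if dt is None else max(1, int(round(t_max / dt)))
        t_grid = np.linspace(0.0, t_max, n_grid + 1)
        if network.all_bilinear:
            arrays = network.compile()
            states, status, info = _kernel.ssa_grid(
                network.initial_state.copy(), *arrays, t_grid, rng
            )
        else:
            states, status, info = _python_ssa_grid(network, t_grid, rng)
        if status < 0:
            _raise_status(network, status, info)
        traj = Trajectory(
            times=t_grid, states=states, species=network.species,
            absorbed=(status == 1), seed=seed, meta=dict(network.meta),
        )
    elif recording == "every_event":
        if network.all_bilinear:
            arrays = network.compile()
            times, states, nrec, status, info = _kernel.ssa_events(
                network.initial_state.copy(), *arrays, t_max, max_events, rng
            )
        else:
            times, states, nrec, status, info = _python_ssa_events(
                network, t_max, max_events, rng
            )
        if status < 0:
            _raise_status(network, status, info)
        if status == 2:
            raise SimulationError(
                f"exceeded max_events={max_events} before t_max={t_max}"
            )
        traj = Trajectory(
            times=times[:nrec], states=states[:nrec], species=network.species,
            absorbed=(status == 1), seed=seed, meta=dict(network.meta),
        )
    else:
        raise ValueError(f"unknown recording mode {recording!r}")
    return _attach_derived(network, traj)


def _python_ssa_step(network, x, total, props, rng):
    r2 = rng.random()
    target = r2 * total
    cum = 0.0
    j = len(props) - 1
    for jj, a in enumerate(props):
        cum += a
        if target < cum:
            j = jj
            break
    for s, c in network.reactions[j].changes.items():
        idx = network.index(s)
        x[idx] += c
        if x[idx] < 0:
            raise SimulationError(
                f"state driven negative in reaction {network.reactions[j].name!r}"
            )
    return j


def _check_props(network, props):
    for j, a in enumerate(props):
        if np.isnan(a):
            raise SimulationError(
                f"NaN propensity in reaction {network.reactions[j].name!r}"
            )
        if a < 0:
            raise SimulationError(
                f"negative propensity in reaction {network.reactions[j].name!r} "
                f"(a={a})"
            )


def _python_ssa_grid(network, t_grid, rng):
    x = network.initial_state.copy()
    ngrid = len(t_grid)
    out = np.empty((ngrid, len(x)), dtype=np.int64)
    out[0] = x
    rec, t = 1, 0.0
    t_max = t_grid[-1]
    while True:
        props = network.propensity_vector(x)
        _check_props(network, props)
        total = float(props.sum())
        if total == 0.0:
            out[rec:] = x
            return out, 1, -1
        tau = np.log(1.0 / rng.random()) / total
        t_next = t + tau
        while rec < ngrid and t_grid[rec] < t_next:
            out[rec] = x
            rec += 1
        if t_next > t_max or rec >= ngrid:
            out[rec:] = x
            return out, 0, -1
        _python_ssa_step(network, x, total, props, rng)
        t = t_next


def _python_ssa_events(network, t_max, max_events, rng):
    x = network.initial_state.copy()
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    status = 2
    while len(times) <= max_events:
        props = network.propensity_vector(x)
        _check_props(network, props)
        total = float(props.sum())
        if total == 0.0:
            status = 1
            break
        tau = np.log(1.0 / rng.random()) / total
        if t + tau > t_max:
            status = 0
            break
        _python_ssa_step(network, x, total, props, rng)
        t += tau
        times.append(t)
        states.append(x.copy())
    return np.array(times), np.array(states), len(times), status, -1


def simulate_ode(
    network: ReactionNetwork,
    t_max: float,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    n_grid: int = 500,
    method: str = "LSODA",
) -> Trajectory:
    """Deterministic mean-field twin:  dx/dt = Σⱼ aⱼ(x)·Δⱼ.

    Uses an adaptive stiff-capable integrator; conserved sums hold to
    integration tolerance.  States are continuous (floats).
    """
    from scipy.integrate import solve_ivp

    deltas = network.delta_matrix().astype(float)

    def rhs(t, x):
        return network.propensity_vector(x) @ deltas

    t_grid = np.linspace(0.0, t_max, n_grid + 1)
    sol = solve_ivp(
        rhs, (0.0, t_max), network.initial_state.astype(float),
        t_eval=t_grid, method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed at t={sol.t[-1] if len(sol.t) else 0:.3g}: "
            f"{sol.message}"
        )
    traj = Trajectory(
        times=sol.t, states=sol.y.T, species=network.species,
        seed=None, meta=dict(network.meta),
    )
    return _attach_derived(network, traj)


@dataclass
class EnsembleSummary:
    """Per-run reducer outputs over an ensemble of SSA realisations."""

    table: pd.DataFrame          # one row per run; columns: seed + reducers
    base_seed: int
    n_runs: int
    t_max: float
    meta: dict = field(default_factory=dict)

    def mean(self, column: str) -> float:
        return float(self.table[column].mean())

    def sem(self, column: str) -> float:
        return float(self.table[column].std(ddof=1) / np.sqrt(len(self.table)))


def run_ensemble(
    network_factory: Callable[[int], ReactionNetwork],
    n_runs: int,
    base_seed: int,
    t_max: float,
    reducers: Mapping[str, Callable[[Trajectory], float]],
    recording: str = "grid",
    n_grid: int = 50,
) -> EnsembleSummary:
    """Run ``n_runs`` SSA realisations with seeds base_seed..base_seed+n−1.

    ``network_factory(seed)`` may return a seed-dependent network (e.g.
    jittered initial condition); reducers map each trajectory to a scalar.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for k in range(n_runs):
        seed = base_seed + k
        net = network_factory(seed)
        try:
            traj = simulate_ssa(net, t_max, seed, recording=recording, n_grid=n_grid)
        except SimulationError as err:
            raise SimulationError(f"run {k} (seed {seed}): {err}") from err
        row = {"seed": seed}
        for name, fn in reducers.items():
            row[name] = fn(traj)
        rows.append(row)
    return EnsembleSummary(
        table=pd.DataFrame(rows), base_seed=base_seed, n_runs=n_runs, t_max=t_max
    )
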