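"""Catalytic centrosome growth in a shared enzyme pool.

A single coarse-grained PCM subunit exists in an inactive form S₁, an
enzyme-activated form S₁*, or incorporated in a centrosome (Sₙ,ᵢ counts
subunits in centrosome i).  The enzyme E is activated to E* inside the
PCM at a rate proportional to centrosome size; E* activates subunits in
the cytoplasm; both S₁ and S₁* assemble at size-INDEPENDENT
(centriole-localised) rates while turnover k⁻·Sₙ is distributed through
the PCM.  Reaction channels per centrosome i (Ω = c·Vc):

    R1  S₁  + Cᵢ → Cᵢ⁺¹            a = k⁺⁽ⁱ⁾·S₁/Ω
    R2  S₁* + Cᵢ → Cᵢ⁺¹ + E        a = k*·S₁*/Ω      (enzyme released inactive)
    R3  E → E*                     a = k_E*·Sₙ,ᵢ·E/Ω  (size-proportional)
    R4  S₁ + E* → S₁*              a = k₁*·S₁·E*/Ω    (enzyme held in S₁*)
    R5  Cᵢ → Cᵢ⁻¹ + S₁             a = k⁻·Sₙ,ᵢ

with conservation  S₁ + S₁* + ΣSₙ = N  and  E + E* + S₁* = N_E.
Because assembly is size-independent and the positive feedback (R3) feeds
a *shared* cytoplasmic pool, a size difference between the two centrosomes
relaxes at rate k⁻ instead of being amplified — the property that
distinguishes this model from autocatalytic growth.

The "unlimited_pool" variant clamps the inactive-enzyme concentration [E]
(R3 uses a constant count, R2 returns nothing): the subunit pool remains
limiting, the enzyme pool does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ssa import Reaction, ReactionNetwork, Trajectory
from .units import AVOGADRO, UnitSystem

__all__ = [
    "CatalyticParams",
    "CatalyticState",
    "catalytic_rhs",
    "build_catalytic_network",
    "steady_state_volume",
    "PulseMetrics",
    "pulse_metrics",
]


@dataclass(frozen=True)
class CatalyticParams:
    """Rate constants and pools for the shared-enzyme catalytic model.

    k_plus   : inactive-subunit assembly rate constant, μM⁻¹s⁻¹ (the
               centriolar activity; ``k_plus_2`` sets a different value
               for the second centrosome)
    k_star   : active-subunit assembly rate constant, μM⁻¹s⁻¹
    k1_star  : enzyme-dependent subunit activation, μM⁻¹s⁻¹
    kE_star  : PCM-dependent enzyme activation; quoted in s⁻¹ but acting
               bimolecularly on Sₙ·E — interpreted as μM⁻¹s⁻¹ at a 1 μM
               reference, i.e. propensity k_E*·Sₙ·E/(c·Vc)
    k_minus  : disassembly rate constant, s⁻¹
    rho0     : total subunit concentration, μM  (N = ρ₀·c·Vc)
    E_conc   : total (limited mode) or clamped (unlimited mode) enzyme
               concentration, μM
    """

    k_plus: float
    k_star: float
    k1_star: float
    kE_star: float
    rho0: float
    E_conc: float
    k_minus: float = 5e-3
    Vc: float = 5000.0
    delta_v: float = 2e-4
    units: UnitSystem = AVOGADRO
    enzyme_mode: str = "limited_pool"
    k_plus_2: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_star", "k1_star", "kE_star", "k_minus",
                     "rho0", "E_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.Vc > 0 or not self.delta_v > 0:
            raise ValueError("Vc and delta_v must be positive")
        if self.enzyme_mode not in ("limited_pool", "unlimited_pool"):
            raise ValueError(f"unknown enzyme_mode {self.enzyme_mode!r}")

    @property
    def omega(self) -> float:
        return self.units.omega(self.Vc)

    @property
    def N(self) -> int:
        return round(self.rho0 * self.omega)

    @property
    def N_E(self) -> int:
        return round(self.E_conc * self.omega)

    @property
    def k_plus_pair(self) -> tuple[float, float]:
        return (self.k_plus, self.k_plus if self.k_plus_2 is None else self.k_plus_2)


@dataclass
class CatalyticState:
    """Explicit state of the pair model; free S₁ and inactive E are derived
    from the conservation laws rather than stored."""

    Sn: tuple[float, float]
    S1_star: float
    E_star: float

    def free_subunits(self, params: CatalyticParams) -> float:
        return params.N - sum(self.Sn) - self.S1_star

    def free_enzyme(self, params: CatalyticParams) -> float:
        return params.N_E - self.E_star - self.S1_star


def catalytic_rhs(state: CatalyticState, params: CatalyticParams) -> np.ndarray:
    """Mean-field time derivatives (dSₙ,₁, dSₙ,₂, dS₁*, dE*)/dt."""
    om = params.omega
    S1 = state.free_subunits(params)
    Sn1, Sn2 = state.Sn
    S1s, Es = state.S1_star, state.E_star
    if min(S1, Sn1, Sn2, S1s, Es) < 0:
        raise ValueError("state violates non-negativity / conservation")
    if params.enzyme_mode == "limited_pool":
        E = state.free_enzyme(params)
        if E < 0:
            raise ValueError("state violates enzyme conservation")
    else:
        E = params.E_conc * om
    kp1, kp2 = params.k_plus_pair
    a1 = kp1 * S1 / om
    a1b = kp2 * S1 / om
    a2 = params.k_star * S1s / om
    act = params.k1_star * S1 * Es / om
    e1 = params.kE_star * (Sn1 + Sn2) * E / om
    return np.array([
        a1 + a2 - params.k_minus * Sn1,
        a1b + a2 - params.k_minus * Sn2,
        act - 2.0 * a2,
        e1 - act,
    ])


def build_catalytic_network(
    params: CatalyticParams, initial: Sequence[int]
) -> ReactionNetwork:
    """Reaction network for M centrosomes (M = len(initial)) with shared
    subunit and enzyme pools.  See the module docstring for the channels."""
    M = len(initial)
    if M < 1:
        raise ValueError("need at least one centrosome")
    om = params.omega
    N, NE = params.N, params.N_E
    if sum(initial) > N:
        raise ValueError("initial bound subunits exceed pool N")
    limited = params.enzyme_mode == "limited_pool"
    species = ["S1", "S1s"] + (["E"] if limited else []) + ["Es"] + [
        f"Sn{i+1}" for i in range(M)
    ]
    x0 = {s: 0 for s in species}
    x0["S1"] = N - sum(initial)
    if limited:
        x0["E"] = NE
    for i, n in enumerate(initial):
        x0[f"Sn{i+1}"] = n
    kps = params.k_plus_pair if M == 2 else (params.k_plus,) * M
    reactions = [
        Reaction(
            name="subunit_activation",            # R4: S1 + E* -> S1*
            rate=params.k1_star / om,
            changes={"S1": -1, "Es": -1, "S1s": +1},
            factor1={"S1": 1.0},
            factor2={"Es": 1.0},
        ),
    ]
    for i in range(M):
        sn = f"Sn{i+1}"
        reactions.append(Reaction(
            name=f"assembly_inactive_{i+1}",      # R1
            rate=kps[i] / om,
            changes={"S1": -1, sn: +1},
            factor1={"S1": 1.0},
        ))
        r2_changes = {"S1s": -1, sn: +1}
        if limited:
            r2_changes["E"] = +1                  # enzyme released inactive
        reactions.append(Reaction(
            name=f"assembly_active_{i+1}",        # R2
            rate=params.k_star / om,
            changes=r2_changes,
            factor1={"S1s": 1.0},
        ))
        if limited:
            reactions.append(Reaction(
                name=f"enzyme_activation_{i+1}",  # R3
                rate=params.kE_star / om,
                changes={"E": -1, "Es": +1},
                factor1={sn: 1.0},
                factor2={"E": 1.0},
            ))
        else:
            reactions.append(Reaction(
                name=f"enzyme_activation_{i+1}",  # R3, clamped [E]
                rate=params.kE_star * params.E_conc,
                changes={"Es": +1},
                factor1={sn: 1.0},
            ))
        reactions.append(Reaction(
            name=f"disassembly_{i+1}",            # R5
            rate=params.k_minus,
            changes={sn: -1, "S1": +1},
            factor1={sn: 1.0},
        ))
    conserved = [(
        "subunits",
        {"S1": 1.0, "S1s": 1.0, **{f"Sn{i+1}": 1.0 for i in range(M)}},
        float(N),
    )]
    if limited:
        conserved.append(("enzyme", {"E": 1.0, "Es": 1.0, "S1s": 1.0}, float(NE)))
    dv = params.delta_v
    derived = {f"V{i+1}": ({f"Sn{i+1}": 1.0}, dv) for i in range(M)}
    derived["[Es]"] = ({"Es": 1.0}, 1.0 / om)
    derived["[S1]"] = ({"S1": 1.0}, 1.0 / om)
    derived["[S1s]"] = ({"S1s": 1.0}, 1.0 / om)
    derived["cyto_fraction"] = ({"S1": 1.0, "S1s": 1.0}, 1.0 / N if N else 0.0)
    return ReactionNetwork(
        species=species,
        initial_state=np.array([x0[s] for s in species], dtype=np.int64),
        reactions=reactions,
        conserved=conserved,
        derived=derived,
        meta={"model": "catalytic", "enzyme_mode": params.enzyme_mode,
              "convention": params.units.convention_id},
    )


def steady_state_volume(
    params: CatalyticParams, E_star_ss: float | None = None
) -> float:
    """Closed-form steady-state volume of a single centrosome,

        V = (E*k₁* + k⁺)·k*·N·δv / [k*(k⁺ + k⁻Ω) + E*k₁*(k* + k⁻Ω)]

    with Ω = c·Vc, N = ρ₀Ω, and E* the steady-state count of activated
    enzyme.  If ``E_star_ss`` is None it is solved self-consistently from
    the enzyme balance (limited mode) before substituting.
    """
    om = params.omega
    if E_star_ss is None:
        E_star_ss = _solve_steady_E_star(params)
    num = (E_star_ss * params.k1_star + params.k_plus) * params.k_star \
        * params.rho0 * om * params.delta_v
    km = params.k_minus * om
    den = params.k_star * (params.k_plus + km) \
        + E_star_ss * params.k1_star * (params.k_star + km)
    if den == 0.0:
        raise ZeroDivisionError("steady-state volume denominator is zero")
    return num / den


def _solve_steady_E_star(params: CatalyticParams) -> float:
    """Steady-state free activated-enzyme count for a single centrosome,
    from the full balance equations (limited mode) or the clamped-[E]
    balance (unlimited mode)."""
    from scipy.optimize import brentq

    om = params.omega
    N, NE = params.N, params.N_E
    kp, ks, k1, kE, km = (params.k_plus, params.k_star, params.k1_star,
                          params.kE_star, params.k_minus)

    if params.enzyme_mode != "limited_pool":
        raise ValueError(
            "self-consistent E* requires the limited enzyme pool; pass "
            "E_star_ss explicitly for the unlimited variant"
        )

    def residual(Es):
        # from the R-balances: k1*S1*Es = k*·S1s  and  kp*S1 + ks*S1s = km·Ω·Sn
        # => S1s = k1*S1*Es/ks ;  Sn = S1*(kp + k1*Es)/(km·Ω)
        # subunit conservation: S1*(1 + k1*Es/ks + (kp + k1*Es)/(km·Ω)) = N
        denom = km * om
        S1 = N / (1.0 + k1 * Es / ks + (kp + k1 * Es) / denom) if N else 0.0
        S1s = k1 * S1 * Es / ks if ks > 0 else 0.0
        Sn = S1 * (kp + k1 * Es) / denom
        E = NE - Es - S1s
        return kE * Sn * E - k1 * S1 * Es

    if params.k1_star == 0 or params.kE_star == 0 or NE == 0:
        return 0.0
    lo, hi = 0.0, float(NE)
    if residual(lo) <= 0:
        return 0.0
    return float(brentq(residual, lo, hi, xtol=1e-9, rtol=1e-12))


@dataclass
class PulseMetrics:
    """Peak description of a transient (pulse-like) time series."""

    amplitude: float
    peak_time: float
    lifetime: float      # full width at half maximum, s


def pulse_metrics(traj: Trajectory, name: str = "[Es]") -> PulseMetrics | None:
    """Detect and measure an activation pulse in ``traj.series(name)``.

    Returns None ("no pulse") when the series is empty of structure: all
    zero, monotone, or with its maximum at either boundary.  The lifetime
    is the full width at half maximum, with the crossing times found by
    linear interpolation.
    """
    y = np.asarray(traj.series(name), dtype=float)
    t = np.asarray(traj.times, dtype=float)
    if len(y) == 0:
        raise ValueError("empty series")
    ipk = int(np.argmax(y))
    amp = y[ipk]
    if amp <= 0 or ipk == 0 or ipk == len(y) - 1:
        return None
    diffs = np.diff(y)
    if (diffs >= 0).all() or (diffs <= 0).all():
        return None
    half = amp / 2.0
    # left crossing
    left = t[0]
    for i in range(ipk, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    # right crossing; if the series never falls below half, use last time
    right = t[-1]
    for i in range(ipk, len(y) - 1):
        if y[i] >= half > y[i + 1]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    return PulseMetrics(amplitude=float(amp), peak_time=float(t[ipk]),
                        lifetime=float(right - left))
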