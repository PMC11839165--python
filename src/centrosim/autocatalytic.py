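"""Autocatalytic growth of a centrosome pair in a shared limiting pool.

Each centrosome i of size nᵢ (subunit count) grows as

    dnᵢ/dt = (k₀⁺ + k₁⁺ nᵢ) ρ(t) − k⁻ nᵢ ,   ρ(t) = (N − n₁ − n₂)/(c·Vc)

where k₀⁺ is the size-independent (centriole-driven) assembly rate
constant, k₁⁺ the cooperative (size-proportional, autocatalytic) one, k⁻
the disassembly rate constant, N the total subunit count in the cell, and
ρ the free cytoplasmic concentration.  The limits k₁⁺ = 0 (non-cooperative,
closed-form steady state) and k₀⁺ = 0 (purely autocatalytic) bracket the
behaviour; the linearised criterion

    2 k₀⁺ + k⁻·c·Vc > k₁⁺ N

predicts whether the pair reaches equal sizes (True) or amplifies an
initial size difference (False).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssa import Reaction, ReactionNetwork
from .units import AVOGADRO, UnitSystem, concentration_to_count

__all__ = [
    "AutocatalyticParams",
    "autocatalytic_rhs",
    "build_autocatalytic_network",
    "noncooperative_steady_volume",
    "equality_condition_holds",
    "symmetric_steady_state",
]


@dataclass(frozen=True)
class AutocatalyticParams:
    """Rate constants and pool size for the autocatalytic pair model.

    Rates k0_plus, k1_plus are in μM⁻¹s⁻¹, k_minus in s⁻¹; N is the total
    subunit count.  ``k0_plus_2`` (if set) gives the second centrosome a
    different centriolar activity.  ``off_mode`` selects the disassembly
    propensity: "per_subunit" (k⁻·nᵢ, the mean-field-consistent default)
    or "constant" (k⁻ independent of size, for comparison).
    """

    k0_plus: float
    k1_plus: float
    N: int
    k_minus: float = 5e-3
    Vc: float = 5000.0
    delta_v: float = 2e-4
    units: UnitSystem = AVOGADRO
    k0_plus_2: float | None = None
    off_mode: str = "per_subunit"

    def __post_init__(self) -> None:
        if min(self.k0_plus, self.k1_plus, self.k_minus) < 0 or self.N < 0:
            raise ValueError("rates and N must be non-negative")
        if not self.Vc > 0 or not self.delta_v > 0:
            raise ValueError("Vc and delta_v must be positive")
        if self.off_mode not in ("per_subunit", "constant"):
            raise ValueError(f"unknown off_mode {self.off_mode!r}")

    @classmethod
    def from_concentration(cls, rho0: float, **kw) -> "AutocatalyticParams":
        """Build from a total subunit concentration ρ₀ (μM): N = ρ₀·c·Vc."""
        Vc = kw.get("Vc", 5000.0)
        units = kw.get("units", AVOGADRO)
        return cls(N=concentration_to_count(rho0, Vc, units), **kw)

    @property
    def omega(self) -> float:
        return self.units.omega(self.Vc)

    @property
    def k0_pair(self) -> tuple[float, float]:
        return (self.k0_plus, self.k0_plus if self.k0_plus_2 is None else self.k0_plus_2)


def autocatalytic_rhs(state, params: AutocatalyticParams) -> np.ndarray:
    """Deterministic growth rates (dn₁/dt, dn₂/dt) at counts (n₁, n₂)."""
    n1, n2 = float(state[0]), float(state[1])
    if n1 < 0 or n2 < 0 or n1 + n2 > params.N:
        raise ValueError(
            f"state ({n1}, {n2}) outside the simplex 0 <= n1+n2 <= N={params.N}"
        )
    rho = (params.N - n1 - n2) / params.omega
    k01, k02 = params.k0_pair
    return np.array([
        (k01 + params.k1_plus * n1) * rho - params.k_minus * n1,
        (k02 + params.k1_plus * n2) * rho - params.k_minus * n2,
    ])


def build_autocatalytic_network(
    params: AutocatalyticParams, initial: tuple[int, ...]
) -> ReactionNetwork:
    """Reaction network for M centrosomes (M = len(initial)) sharing a pool.

    Species: free subunits S, then n₁..n_M.  Assembly propensity for
    centrosome i is (k₀⁺⁽ⁱ⁾ + k₁⁺nᵢ)·S/(c·Vc); disassembly is k⁻·nᵢ
    (or constant k⁻ in ``off_mode="constant"``).
    """
    M = len(initial)
    if M < 1:
        raise ValueError("need at least one centrosome")
    if sum(initial) > params.N:
        raise ValueError("initial bound subunits exceed pool N")
    species = ["S"] + [f"n{i+1}" for i in range(M)]
    x0 = np.array([params.N - sum(initial), *initial], dtype=np.int64)
    om = params.omega
    k0s = params.k0_pair if M == 2 else (params.k0_plus,) * M
    reactions = []
    for i in range(M):
        ni = f"n{i+1}"
        reactions.append(Reaction(
            name=f"assembly_{i+1}",
            rate=1.0 / om,
            changes={"S": -1, ni: +1},
            factor1={"S": 1.0},
            factor2={ni: params.k1_plus},
            const2=k0s[i],
        ))
        if params.off_mode == "per_subunit":
            reactions.append(Reaction(
                name=f"disassembly_{i+1}",
                rate=params.k_minus,
                changes={ni: -1, "S": +1},
                factor1={ni: 1.0},
            ))
        else:
            # literal size-independent off-propensity; guarded so the
            # channel switches off at nᵢ = 0
            idx = 1 + i
            km = params.k_minus
            reactions.append(Reaction(
                name=f"disassembly_{i+1}",
                rate=km,
                changes={ni: -1, "S": +1},
                propensity=lambda x, idx=idx, km=km: km if x[idx] >= 1 else 0.0,
            ))
    dv = params.delta_v
    derived = {f"V{i+1}": ({f"n{i+1}": 1.0}, dv) for i in range(M)}
    derived["rho"] = ({"S": 1.0}, 1.0 / om)
    return ReactionNetwork(
        species=species,
        initial_state=x0,
        reactions=reactions,
        conserved=[("subunits", {s: 1.0 for s in species}, float(params.N))],
        derived=derived,
        meta={"model": "autocatalytic", "convention": params.units.convention_id},
    )


def noncooperative_steady_volume(
    k_plus: float,
    N: float,
    k_minus: float = 5e-3,
    Vc: float = 5000.0,
    delta_v: float = 2e-4,
    units: UnitSystem = AVOGADRO,
) -> float:
    """Closed-form steady-state volume of the non-cooperative (k₁⁺=0) pair:

        V = k⁺·N·δv / (k⁻_eff + 2k⁺),   k⁻_eff = k⁻·c·Vc

    with the disassembly constant converted to the μM⁻¹s⁻¹ units of k⁺.
    """
    if k_plus < 0 or k_minus < 0:
        raise ValueError("rates must be non-negative")
    k_minus_eff = k_minus * units.omega(Vc)
    denom = k_minus_eff + 2.0 * k_plus
    if denom == 0.0:
        raise ZeroDivisionError("k_plus and k_minus cannot both be zero")
    return k_plus * N * delta_v / denom


def equality_condition_holds(params: AutocatalyticParams) -> bool:
    """Linear-stability criterion for size equality:  2k₀⁺ + k⁻·c·Vc > k₁⁺N.

    All three terms are expressed in μM⁻¹s⁻¹-equivalent units (the
    disassembly term is multiplied by c·Vc, the factor that also appears
    in every bimolecular propensity).  True predicts that an initial size
    difference decays; False predicts amplification.
    """
    return 2.0 * params.k0_plus + params.k_minus * params.omega > params.k1_plus * params.N


def symmetric_steady_state(params: AutocatalyticParams) -> float:
    """Symmetric fixed point n* of the pair model, (k₀⁺+k₁⁺n*)ρ* = k⁻n*.

    Solved by bracketing on n ∈ [0, N/2].  Returns a subunit count.
    """
    from scipy.optimize import brentq

    om = params.omega

    def f(n):
        rho = (params.N - 2 * n) / om
        return (params.k0_plus + params.k1_plus * n) * rho - params.k_minus * n

    if params.k0_plus == 0.0:
        # n = 0 is always a fixed point; the non-trivial one exists when
        # the pool can sustain ρ* = k⁻/k₁⁺
        if params.k1_plus == 0.0:
            return 0.0
        return max(0.0, (params.N - params.k_minus * om / params.k1_plus) / 2.0)
    lo, hi = 0.0, params.N / 2.0
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))
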