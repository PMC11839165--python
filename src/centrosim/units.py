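"""Unit conventions and fixed parameters.

The models mix three kinds of quantities: cytoplasmic concentrations (μM),
discrete molecule counts, and volumes (μm³).  A single conversion factor

    c = molecules per μm³ per μM

ties them together: a species at concentration ρ μM in a cell of volume
``Vc`` μm³ corresponds to ``ρ · Vc · c`` molecules.  Two conventions are
supported:

* ``"avogadro"`` — the physical factor, 10⁻⁶ mol/L × N_A × 10⁻¹⁵ L/μm³
  ≈ 602.214 molecules μm⁻³ μM⁻¹.  This is the default and the convention
  pinned by the calibration of the shared-enzyme growth scenario (it
  reproduces the μm³-scale steady-state centrosome volumes; the "unity"
  convention yields volumes 10–100× too small).
* ``"unity"`` — c = 1, i.e. concentrations are read as molecules per μm³.
  Kept available for sensitivity checks.

All model dynamics run on integer molecule counts.  Every bimolecular
propensity carries a factor 1/(c·Vc) so that rate constants quoted in
μM⁻¹s⁻¹ can be used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "AVOGADRO_FACTOR",
    "UnitSystem",
    "AVOGADRO",
    "UNITY",
    "get_units",
    "FixedParams",
    "Assignment",
    "concentration_to_count",
    "count_to_concentration",
    "volume_of",
    "initial_counts",
]

#: molecules per μm³ per μM: 1e-6 mol/L · 6.02214076e23 /mol · 1e-15 L/μm³
AVOGADRO_FACTOR = 602.214


@dataclass(frozen=True)
class UnitSystem:
    """Conversion convention between μM concentrations and molecule counts."""

    count_per_uM_um3: float = AVOGADRO_FACTOR
    convention_id: str = "avogadro"

    def __post_init__(self) -> None:
        if not self.count_per_uM_um3 > 0:
            raise ValueError("count_per_uM_um3 must be positive")

    def omega(self, Vc: float) -> float:
        """Molecules per μM for a cell of volume ``Vc`` μm³ (c · Vc)."""
        return self.count_per_uM_um3 * Vc


AVOGADRO = UnitSystem(AVOGADRO_FACTOR, "avogadro")
UNITY = UnitSystem(1.0, "unity")

_CONVENTIONS = {"avogadro": AVOGADRO, "unity": UNITY}


def get_units(name: str) -> UnitSystem:
    """Look up a unit convention by its label."""
    try:
        return _CONVENTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown unit convention {name!r}; choose from {sorted(_CONVENTIONS)}"
        ) from None


@dataclass(frozen=True)
class FixedParams:
    """Global fixed parameters shared by every growth model.

    delta_v : effective volume of one incorporated subunit (μm³)
    V0      : default initial centrosome volume (μm³)
    k_minus : disassembly rate constant (s⁻¹)
    Vc      : cell volume (μm³)
    """

    delta_v: float = 2e-4
    V0: float = 5e-3
    k_minus: float = 5e-3
    Vc: float = 5000.0

    def __post_init__(self) -> None:
        for name in ("delta_v", "V0", "k_minus", "Vc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


class Assignment(str, Enum):
    """How an initial size difference δV₀ is distributed over the pair."""

    SYMMETRIC_SPLIT = "symmetric_split"
    DEFICIT_ON_FIRST = "deficit_on_first"


def concentration_to_count(rho: float, Vc: float, units: UnitSystem = AVOGADRO) -> int:
    """Convert a concentration (μM) in volume ``Vc`` (μm³) to a molecule count.

    Rounds half-to-even, so the inverse conversion recovers ``rho`` to
    within 1/(Vc·c) absolute error.
    """
    if rho < 0:
        raise ValueError(f"concentration must be non-negative, got {rho}")
    if not Vc > 0:
        raise ValueError(f"volume must be positive, got {Vc}")
    return round(rho * units.omega(Vc))


def count_to_concentration(n: float, Vc: float, units: UnitSystem = AVOGADRO) -> float:
    """Concentration (μM) of ``n`` molecules in volume ``Vc`` (μm³)."""
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    if not Vc > 0:
        raise ValueError(f"volume must be positive, got {Vc}")
    return n / units.omega(Vc)


def volume_of(n: float, delta_v: float = 2e-4) -> float:
    """Volume (μm³) of a centrosome holding ``n`` subunits: V = n·δv."""
    if n < 0:
        raise ValueError(f"subunit count must be non-negative, got {n}")
    return n * delta_v


def initial_counts(
    V0: float,
    dV0: float,
    delta_v: float = 2e-4,
    assignment: Assignment | str = Assignment.SYMMETRIC_SPLIT,
) -> tuple[int, int]:
    """Initial subunit counts (n₁, n₂) for a centrosome pair.

    ``symmetric_split`` puts V₀ ± δV₀/2 on the two centrosomes;
    ``deficit_on_first`` gives the first centrosome V₀ − δV₀ and the second
    V₀ (the convention for differential-growth runs, where the first
    centrosome carries the higher centriole activity and starts smaller).
    Counts are rounded half-to-even and clamped to ≥ 1: a centrosome must
    exist before it can grow.
    """
    assignment = Assignment(assignment)
    if not V0 > 0:
        raise ValueError("V0 must be positive")
    if dV0 < 0:
        raise ValueError("dV0 must be non-negative")
    if assignment is Assignment.DEFICIT_ON_FIRST:
        if dV0 >= V0:
            raise ValueError("deficit_on_first requires dV0 < V0")
        v1, v2 = V0 - dV0, V0
    else:
        if dV0 >= 2 * V0:
            raise ValueError("symmetric_split requires dV0 < 2·V0")
        v1, v2 = V0 + dV0 / 2, V0 - dV0 / 2
    # snap 9-decimal float noise before the half-to-even rounding so that
    # e.g. 27.499999999999996 (== 27.5 in exact arithmetic) rounds to 28
    n1, n2 = round(round(v1 / delta_v, 9)), round(round(v2 / delta_v, 9))
    if n1 < 1 or n2 < 1:
        if min(v1, v2) <= 0:
            raise ValueError(
                f"initial volumes ({v1:g}, {v2:g}) μm³ give a non-positive count"
            )
        n1, n2 = max(n1, 1), max(n2, 1)
    return n1, n2
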