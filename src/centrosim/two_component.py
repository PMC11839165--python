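"""Two-scaffold centrosome growth: scaffold formers a and b plus enzyme E.

Component a (Spd-2-like) assembles at a centriole-seeded, size-independent
rate; component b (Cnn-like) binds the scaffold in an a-dependent
intermediate form bᵢ that falls off rapidly unless captured by the active
enzyme E* (Polo-like) and incorporated into the b-scaffold.  The enzyme is
activated within the PCM scaffold at a size-proportional rate.  Reaction
channels per centrosome i (Ω = c·Vc, counts Sa, bi, Ebi, Sb per
centrosome; A, B, E, E* in the cytoplasm):

    A1  A → Saᵢ             a = k_a⁺·A/Ω · s₀          (centriole-seeded)
    A2  Saᵢ → A             a = k_a⁻·Saᵢ
    B1  B → biᵢ             a = k_b0⁺·B/Ω · Saᵢ        (a-dependent binding)
    B2  biᵢ → B             a = k_b0⁻·biᵢ              (rapid fall-off)
    E1  E → E*              a = k_aE⁺·E/Ω · (Saᵢ+Sbᵢ)  (size-proportional)
    E2  E* + biᵢ → Ebiᵢ     a = k_Eb⁺·E*·biᵢ/Ω
    B3  Ebiᵢ → Sbᵢ          a = k_b1⁺                  (pseudo-first-order)
    B4  Sbᵢ → B + E         a = k_b1⁻·Sbᵢ              (enzyme released inactive)

Conservation: A + ΣSa = N_a;  B + Σ(bi + Ebi + Sb) = N_b;
E + E* + Σ(Ebi + Sb) = N_E (each incorporated b subunit holds one enzyme
until it disassembles — this sequestration is what produces the E*
activation pulse at growth onset).

In ``enzyme_mode="shared"`` the activated enzyme joins one cytoplasmic
pool feeding both centrosomes; in ``"localized"`` the E* produced at
centrosome i is a separate species usable only by that centrosome's E2.
Enzyme sharing is the only difference between the modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ssa import Reaction, ReactionNetwork
from .units import AVOGADRO, UnitSystem

__all__ = [
    "TwoComponentParams",
    "build_two_component_network",
    "radial_spread",
]


@dataclass(frozen=True)
class TwoComponentParams:
    """Rates (Table-style, μM⁻¹s⁻¹ / s⁻¹) and total concentrations (μM)."""

    rho_a: float
    rho_b: float
    rho_E: float
    ka_plus: float = 10.0
    ka_minus: float = 5e-3
    kb0_plus: float = 0.5
    kb0_minus: float = 0.01
    kaE_plus: float = 5e3
    kEb_plus: float = 1e3
    kb1_plus: float = 1e4
    kb1_minus: float = 5e-3
    Vc: float = 5000.0
    delta_v: float = 2e-4
    units: UnitSystem = AVOGADRO
    enzyme_mode: str = "shared"
    seed_sites: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho_a", "rho_b", "rho_E", "ka_plus", "ka_minus",
                     "kb0_plus", "kb0_minus", "kaE_plus", "kEb_plus",
                     "kb1_plus", "kb1_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.enzyme_mode not in ("shared", "localized"):
            raise ValueError(f"unknown enzyme_mode {self.enzyme_mode!r}")
        if not self.Vc > 0 or not self.delta_v > 0 or not self.seed_sites > 0:
            raise ValueError("Vc, delta_v, seed_sites must be positive")

    @property
    def omega(self) -> float:
        return self.units.omega(self.Vc)

    @property
    def N_a(self) -> int:
        return round(self.rho_a * self.omega)

    @property
    def N_b(self) -> int:
        return round(self.rho_b * self.omega)

    @property
    def N_E(self) -> int:
        return round(self.rho_E * self.omega)


def build_two_component_network(
    params: TwoComponentParams, initial_a: Sequence[int]
) -> ReactionNetwork:
    """Network for M centrosomes whose a-scaffolds start at ``initial_a``
    subunits (b-scaffolds start empty: b requires a and enzyme)."""
    M = len(initial_a)
    if M < 1:
        raise ValueError("need at least one centrosome")
    om = params.omega
    Na, Nb, NE = params.N_a, params.N_b, params.N_E
    if sum(initial_a) > Na:
        raise ValueError("initial a-scaffolds exceed pool N_a")
    localized = params.enzyme_mode == "localized"
    es_names = [f"Es{i+1}" for i in range(M)] if localized else ["Es"]
    species = ["A", "B", "E"] + es_names
    for i in range(M):
        species += [f"Sa{i+1}", f"bi{i+1}", f"Ebi{i+1}", f"Sb{i+1}"]
    x0 = {s: 0 for s in species}
    x0["A"] = Na - sum(initial_a)
    x0["B"], x0["E"] = Nb, NE
    for i, n in enumerate(initial_a):
        x0[f"Sa{i+1}"] = n
    reactions = []
    for i in range(M):
        sa, bi, ebi, sb = (f"Sa{i+1}", f"bi{i+1}", f"Ebi{i+1}", f"Sb{i+1}")
        es = es_names[i] if localized else "Es"
        reactions += [
            Reaction(name=f"a_assembly_{i+1}", rate=params.ka_plus * params.seed_sites / om,
                     changes={"A": -1, sa: +1}, factor1={"A": 1.0}),
            Reaction(name=f"a_disassembly_{i+1}", rate=params.ka_minus,
                     changes={sa: -1, "A": +1}, factor1={sa: 1.0}),
            Reaction(name=f"b_binding_{i+1}", rate=params.kb0_plus / om,
                     changes={"B": -1, bi: +1}, factor1={"B": 1.0}, factor2={sa: 1.0}),
            Reaction(name=f"b_falloff_{i+1}", rate=params.kb0_minus,
                     changes={bi: -1, "B": +1}, factor1={bi: 1.0}),
            Reaction(name=f"enzyme_activation_{i+1}", rate=params.kaE_plus / om,
                     changes={"E": -1, es: +1}, factor1={"E": 1.0},
                     factor2={sa: 1.0, sb: 1.0}),
            Reaction(name=f"enzyme_capture_{i+1}", rate=params.kEb_plus / om,
                     changes={es: -1, bi: -1, ebi: +1},
                     factor1={es: 1.0}, factor2={bi: 1.0}),
            Reaction(name=f"b_incorporation_{i+1}", rate=params.kb1_plus,
                     changes={ebi: -1, sb: +1}, factor1={ebi: 1.0}),
            Reaction(name=f"b_disassembly_{i+1}", rate=params.kb1_minus,
                     changes={sb: -1, "B": +1, "E": +1}, factor1={sb: 1.0}),
        ]
    b_members = {"B": 1.0}
    e_members = {"E": 1.0, **{es: 1.0 for es in es_names}}
    for i in range(M):
        b_members.update({f"bi{i+1}": 1.0, f"Ebi{i+1}": 1.0, f"Sb{i+1}": 1.0})
        e_members.update({f"Ebi{i+1}": 1.0, f"Sb{i+1}": 1.0})
    conserved = [
        ("a_total", {"A": 1.0, **{f"Sa{i+1}": 1.0 for i in range(M)}}, float(Na)),
        ("b_total", b_members, float(Nb)),
        ("enzyme_total", e_members, float(NE)),
    ]
    dv = params.delta_v
    derived = {}
    for i in range(M):
        derived[f"Va{i+1}"] = ({f"Sa{i+1}": 1.0}, dv)
        derived[f"Vb{i+1}"] = ({f"Sb{i+1}": 1.0}, dv)
        derived[f"V{i+1}"] = ({f"Sa{i+1}": 1.0, f"Sb{i+1}": 1.0}, dv)
    total_es = {es: 1.0 for es in es_names}
    derived["[Es]"] = (total_es, 1.0 / om)
    derived["[E]"] = ({"E": 1.0}, 1.0 / om)
    return ReactionNetwork(
        species=species,
        initial_state=np.array([x0[s] for s in species], dtype=np.int64),
        reactions=reactions,
        conserved=conserved,
        derived=derived,
        meta={"model": "two_component", "enzyme_mode": params.enzyme_mode,
              "convention": params.units.convention_id},
    )


def radial_spread(sa, sb, delta_v: float = 2e-4):
    """Equivalent-sphere radii (μm) of the a-core and the enveloping
    b-scaffold:  R_a = (3·Sa·δv/4π)^{1/3},  R_b = (3·(Sa+Sb)·δv/4π)^{1/3}.

    b spreads around a, so its radius uses the total scaffold volume.
    Accepts scalars or arrays.
    """
    sa = np.asarray(sa, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if (sa < 0).any() or (sb < 0).any():
        raise ValueError("subunit counts must be non-negative")
    pref = 3.0 * delta_v / (4.0 * np.pi)
    r_a = (pref * sa) ** (1.0 / 3.0)
    r_b = (pref * (sa + sb)) ** (1.0 / 3.0)
    if r_a.ndim == 0:
        return float(r_a), float(r_b)
    return r_a, r_b
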