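# Methods

## Scope and state representation

All models describe a pair (optionally a single, or M > 2) of centrosomes
growing by stochastic assembly/disassembly of discrete subunits drawn from
shared, finite cytoplasmic pools in a well-mixed cell. Growth is treated
as reaction-limited: the diffusion timescale across the 5–10 μm
centrosome separation is ≈0.1–1 s (see the estimates below), two to three
orders of magnitude shorter than the observed turnover times, so no
spatial degrees of freedom are kept. Centrosome volume is V = n·δv with
δv = 2×10⁻⁴ μm³ per subunit; a and b subunits of the two-scaffold model
share the same δv.

**Units.** Rate constants are quoted in μM⁻¹s⁻¹ (bimolecular) and s⁻¹
(unimolecular); the dynamics run on integer molecule counts. One factor
c = 602.214 molecules μm⁻³ μM⁻¹ converts: a pool at concentration ρ holds
N = ρ·c·Vc molecules, and every bimolecular propensity carries 1/(c·Vc)
(written Ω = c·Vc throughout). The factor is runtime-selectable
("avogadro" = 602.214, default; "unity" = 1): the avogadro convention is
pinned because it alone reproduces the μm³-scale steady-state volumes and
the qualitative behaviour of the published scenarios — under "unity" the
same parameter rows give 0.01–0.5 μm³ centrosomes.

Two rate constants are printed with unimolecular units but act
bimolecularly; both are normalised at a 1 μM reference, in one place each:

- enzyme activation k_E\* (s⁻¹): propensity k_E\*·Sₙ·E/Ω;
- b-incorporation k_b1⁺ (μM⁻¹s⁻¹): pseudo-first-order propensity
  k_b1⁺·Ebi (numerically unchanged).

## Stochastic engine

Exact Gillespie direct method: waiting time τ = (Σaᵢ)⁻¹ln(1/r₁), channel
selected by cumulative-propensity inversion with r₂ (first index whose
cumulative sum exceeds r₂·Σaᵢ; ties resolved by the half-open interval),
r₁ before r₂ from one numpy PCG64 generator per run. No tau-leaping:
desk-scale pools (≤ ~3×10⁶ molecules, ~10⁶–10⁷ events per run) run in
0.1–1 s through a compiled kernel. Propensities are declared as products
of up to two affine functions of the state, which covers all mass-action
channels used here; arbitrary callable propensities fall back to a Python
loop with identical sampling semantics (the generator streams match
bit-for-bit, so the two paths are interchangeable). Recording is either a
uniform grid (default 501 points, bounding memory) or every event (used by
the conservation tests). Negative or NaN propensities abort with the
offending reaction named; stoichiometry can never drive a count negative
because every consuming channel's propensity vanishes at zero copies (the
size-independent disassembly variant, which cannot satisfy this by
construction, carries an explicit guard).

The deterministic twin integrates dx/dt = Σⱼ aⱼ(x)Δⱼ with LSODA
(default rtol 10⁻⁸, atol 10⁻⁶); conservation holds to integrator
tolerance there and exactly along SSA paths.

**Seeding.** Ensembles use consecutive seeds base..base+n−1; every
artifact (CSV + JSON manifest) records seeds, parameters, convention and
version, and re-running a manifest reproduces byte-identical files.

## Model families

### Autocatalytic (one component)

dnᵢ/dt = (k₀⁺⁽ⁱ⁾ + k₁⁺nᵢ)ρ − k⁻nᵢ with ρ = (N − Σnⱼ)/Ω. SSA channels:
assembly (k₀⁺⁽ⁱ⁾ + k₁⁺nᵢ)·S/Ω and disassembly k⁻nᵢ. The per-subunit
disassembly propensity is the default because its mean field recovers the
rate equation; the size-independent variant (off-propensity k⁻
irrespective of n) is available as `off_mode="constant"` for comparison.
Linearising about the symmetric state at the undepleted pool gives the
size-equality criterion 2k₀⁺ + k⁻Ω > k₁⁺N (all terms in μM⁻¹s⁻¹
equivalents, i.e. the disassembly constant multiplied by the same Ω that
appears in the propensities). Two caveats found numerically and kept in
the tests: (i) the criterion describes growth-phase amplification around
the *initial* pool; deep in the high-k₀⁺ corner the pool depletes before
the instability acts and the late-time pair is equal although the
criterion is violated; (ii) near the boundary the finite readout time
resolves only finite margins, so the map tests assert separation for
points violating the criterion by ≥3×.

Closed form for k₁⁺ = 0 (non-cooperative): V = k⁺Nδv/(k⁻Ω + 2k⁺).

### Catalytic (shared enzyme pool)

Species S₁ (inactive subunit), S₁\* (activated, holds one enzyme), E, E\*,
Sₙ,ᵢ. Channels per centrosome i: assembly k⁺⁽ⁱ⁾S₁/Ω and k\*S₁\*/Ω (both
size-independent — centriole-localised; incorporation of S₁\* releases its
enzyme inactive, forced by the conservation law E + E\* + S₁\* = N_E);
enzyme activation k_E\*Sₙ,ᵢE/Ω (size-proportional — the positive
feedback); subunit activation k₁\*S₁E\*/Ω; disassembly k⁻Sₙ,ᵢ returning
inactive S₁. Because assembly is size-independent and the feedback is
pooled, the difference mode obeys d(δSₙ)/dt = −k⁻δSₙ: initial differences
decay exponentially while growth remains sigmoidal. The "unlimited"
variant clamps [E] (no enzyme bookkeeping), leaving only the subunit pool
limiting.

Steady state of a single centrosome (E\* given or solved from the enzyme
balance):

V = (E\*k₁\* + k⁺)·k\*·N·δv / [k\*(k⁺ + k⁻Ω) + E\*k₁\*(k\* + k⁻Ω)].

Two quantitative consequences of this bookkeeping, verified analytically
and numerically, temper the published round numbers:

- S₁\* sequesters enzyme, so Sₙ ≤ k\*N_E/(k⁻Ω): at [E] = 0.1 μM the
  plateau is ≈4.0 μm³, not 5 μm³ (5 would need [E] ≥ 0.125 μM).
- the pair's size-difference mode is an Ornstein–Uhlenbeck process with
  restoring rate k⁻ and event flux ≈ 2k⁻Sₙ per centrosome, so the
  stationary mean relative difference is √(2/π)·√(2Sₙ)/Sₙ ≈ 0.8% at
  Sₙ ≈ 2×10⁴ (a 2% figure would require Sₙ ≈ 3×10³, inconsistent with a
  μm³-scale centrosome at this δv).

### Two-scaffold (a, b, enzyme)

The printed information fixes the reaction topology (a assembles
independently; b binds a-dependently as an intermediate bᵢ that falls off
fast unless captured by E\*; E is activated in the scaffold and E\* is
cytoplasmic in shared mode, centrosome-local in localized mode) but not
the propensity forms. The choices here, each isolated in one reaction
definition:

- **a-assembly is centriole-seeded and size-independent** (propensity
  k_a⁺·[A]·s₀, s₀ = 1 seed site). A size-proportional a-assembly term is
  numerically untenable with the published rates: k_a⁺ρ_a/k_a⁻ = 500, so
  any such term drives complete a-pool condensation (≈75 μm³ per
  centrosome) and makes the feedback private, destroying shared-mode
  equality.
- **enzyme activation is proportional to the whole scaffold** (Sa+Sb),
  carrying the size-dependent feedback through the enzyme loop exactly as
  in the single-component catalytic model.
- **incorporated b keeps its enzyme** until b-disassembly releases it
  inactive (conservation E + E\* + Σ(Ebi + Sb) = N_E). Returning the
  enzyme at incorporation leaves the cycle without a stationary sink, and
  [E\*] then rises monotonically to ρ_E with no activation pulse;
  sequestration reproduces the pulse and mirrors the S₁\* bookkeeping.
- no spontaneous E\* deactivation; b-disassembly returns inactive B.

With these choices the shared mode gives equal sizes (≈3.1–3.5 μm³ total
per centrosome for the published concentration rows), an E\* pulse, and
b ≫ a; the localized mode — identical except that E\* is usable only at
its source centrosome — amplifies an initial volume difference by two
orders of magnitude at the growth-phase readout. The steady b:a abundance
ratio is rate-determined, Sb/Sa ≈ k_b0⁺[B]ss/k_b1⁻ ≈ 34–48, so the radial
spread ratio R_b/R_a = (1 + Sb/Sa)^{1/3} comes out ≈3.1–3.3 rather than
the reported ≈2 (which would need Sb/Sa = 7); we report the simulated
value. Radii are equivalent-sphere: R_a = (3Sa·δv/4π)^{1/3}, with b
enveloping a so R_b uses the total volume.

## Analyses

- **Hill fit**: least squares of V(t) = A·tᵅ/(Bᵅ+tᵅ), initialised at
  A₀ = max V, B₀ = first half-max crossing, α₀ = 2; "sigmoidal" means
  α ≥ 2. α of a non-Hill curve depends on the fitted window (a saturating
  exponential gives 1.2–1.7 over 3–50 relaxation times) but stays below 2.
- **Steady-state readout time**: first grid time at which total volume
  changes < 0.1% per 100 s in the deterministic twin; stochastic finals
  are read at that time (≈1500 s for the pinned catalytic scenario).
- **Robustness scan**: ensembles over a δV₀ grid; per-run δV₀ jittered
  uniformly within ±¼ grid spacing so the Pearson correlation between
  per-run δV₀ and final |δV| is computed over a spread of initial
  conditions; flatness is the regression slope of |δV| on δV₀ with its
  standard error. No multiple-testing correction: one planned comparison
  per analysis.
- **Asymmetry efficiency** ε = N₊/N_tot: fraction of runs where the
  centrosome with the higher centriolar activity (listed first, given the
  initial deficit per the differential-growth protocol) ends larger; exact
  ties count ½; 95% CI is the Wilson interval.
- **Size scaling**: single-centrosome steady states across a Vc grid at
  fixed ρ₀ (limiting pool: N ∝ Vc); slope dV/dVc by central differences,
  reported absolute and in δv units, alongside the steady cytoplasmic
  subunit fraction. Strong scaling (V → ρ₀Vcδv, depleted pool) requires
  k⁺, k\* ≫ k⁻Ω; weak assembly gives flat size and an undepleted pool.
- **Diffusion estimates**: D(M) = 30·(30 kDa/M)^{1/3} μm²/s anchored to
  GFP, τ_D = L²/6D. Enzyme (≈60 kDa): ≈24 μm²/s; scaffold (100–150 kDa):
  17–20 μm²/s, τ_D ≈ 0.95 s over 10 μm.

## Problem sizes and defaults

Registered scenarios default to 100-run ensembles (a `--paper-scale` flag
restores 1000) and desk-scale horizons of 2000–3000 s chosen as ≥2× the
deterministic settling time. The acceptance script uses 500 runs per
initial-difference value (2,000 total) at the published cell volume
Vc = 5000 μm³ and full pool sizes; unit tests shrink Vc to 200–500 μm³
(same concentrations and rates, 10–50× fewer molecules) where only
mean-field or conservation properties are at stake. The robustness-map
protocol imposes the 0.1 μm³ initial difference as a surplus on the
second centrosome (the default V₀ = 5×10⁻³ μm³ is 20× too small to split
a 0.1 μm³ difference symmetrically).

## What the simulations do and do not show

The synthetic dynamics implement exactly the mass-action reaction schemes
above: a well-mixed cytoplasm, a single coarse-grained subunit species
(or two scaffold species), no cell-cycle regulation of rates (an optional
on/off enzyme schedule is out of scope), no spatial gradients, and no
measurement noise. Passing tests therefore validate the *mechanisms* —
shared-pool feedback yields robust equality, private feedback does not —
not any particular organism's absolute numbers. Known quantitative
departures from the published round figures (plateau 4.0 vs ~5 μm³,
stationary size difference 0.8% vs ~2%, spread ratio 3.3 vs ~2) follow
from the printed constants themselves and are derived explicitly above.
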