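# Methods

## Scope and state representation

`thermocomm` models sealed batch co-cultures as a system of ODEs over

* one pool per **acid–base family** (total lactate, acetate, carbonate,
  sulfide, ammonium), in mol per litre of liquid;
* **free aqueous species** that do not speciate (sulfate, dissolved H2,
  dissolved CH4);
* **headspace gas contents**, in mol per litre of gas;
* one **biomass pool per population**, in C-mol per litre of liquid.

Protons, hydroxide and water are never state variables. The pH is an
algebraic constraint: at every derivative evaluation the charge balance

    sum_families total_f * sum_i z_i f_i(pH) + sum_free z c + [H+] - [OH-] = 0

is solved on pH ∈ [0, 14] (public API: Brent's method, guaranteed on a
sign-changing bracket; inside the integrator a warm-started safeguarded
Newton iteration with analytic slope reproduces the same root and falls
back to Brent whenever it misbehaves). Speciation fractions use the
closed-form ladder `log10(f_i/f_0) = i·pH − Σ pK_k`, normalized with
max-subtraction. This design follows the per-step procedure: (i) solve pH
and speciate, (ii) evaluate the biochemical and the gas-transfer
derivative terms separately at that state, (iii) sum them.

Because every modelled reaction is charge-balanced, dropping H+ from the
pools is consistent: a reaction that releases protons shifts the charge
inventory of the tracked ions and the solved pH falls accordingly.

## Free energies

Reaction energies are `dG0(T) + RT ln Q` with proton activity `10^-pH`,
water activity 1, and concentrations used as activities (no
activity-coefficient model). Biomass, a generic C1H1.8O0.5N0.2 molecule
with formation energy −67 kJ mol⁻¹, is also assigned fixed activity 1: it
is treated as a separate solid-like phase, so the anabolic reaction
energy does not diverge at low inoculum densities. A concentration floor
of 10⁻¹² mol L⁻¹ (configurable) keeps `ln Q` finite in product-free
initial states.

Formation energies are temperature-adjusted by the linear Gibbs–Helmholtz
form `dGf(T) = dHf − (T/T_ref)(dHf − dGf)` whenever an enthalpy is
tabulated. The bundled species table (`data/formation_energies.csv`)
carries Alberty/NBS enthalpies and Gibbs energies of the Thauer/Alberty
lineage in which the eight core dissolved metabolites were recalibrated
as a self-consistent set (largest single adjustment 3.0 kJ mol⁻¹ —
comparable to the spread between published aqueous-phase compilations,
which differ in solubility reference conventions for dissolved gases).
With this table the six growth-pathway energies of the Dv/Mm/Mb system
evaluate at pH 7 and 310.15 K to 27.57, −170.17, −56.33, −48.12, −14.65
and −64.72 kJ mol⁻¹ (lactate fermentation; lactate + sulfate per mol
sulfate; H2 + sulfate; hydrogenotrophic methanogenesis; acetoclastic
methanogenesis; hydrogenotrophic anabolism) — the values the test suite
asserts. Note that the lactate + sulfate energy is quoted per mol of
sulfate (2 lactate): by reaction algebra it is identically the
fermentation energy plus twice the H2-respiration energy, and the
per-sulfate scaling is the one consistent with the 2:1 lactate:sulfate
capacity of the pathway. Internally the pathway is normalized per mol of
lactate; the dynamics are invariant to this choice because `lambda_cat`
rescales with `dG_cat`.

The lactate-assimilating anabolic reaction of the sulfate reducer is
encoded as printed in the source energetics and does not balance
elementally (+0.05 C, +0.1 H, −0.05 O per C-mol biomass);
`balance_check`/`validate_reactions` report this, and the conservation
tests verify that carbon drift along community trajectories equals
exactly this printed rounding times the biomass formed. Users can
override the reaction in their config.

## Growth law and gating

Rates are `v_max · F_D · F_T` with `F_D` a product of Monod terms over
the substrates that carry a declared `K_S` (water and protons never do)
and `F_T = 1 − exp(min(0, dG_cat − dG_min)/RT)`. `lambda_cat` and the
yield are evaluated only when the pathway can run (`F_T > 0`, which
implies `dG_cat < dG_min < 0`); in the forward-kinetics variant
(`thermodynamics=False`, i.e. `F_T ≡ 1`) the coupling gate is
`dG_cat < 0` alone — an endergonic pathway then still converts substrate
but cannot fund growth. If the energy balance ever yields
`lambda_cat ≤ 0` the anabolic term is dropped for that evaluation. A
depletion guard zeroes any pathway consuming a pool at or below the
floor, protecting the integrator against overshoot; `F_T` is exactly 0 at
`dG_cat = dG_min` by construction (`min(0, ·)` before the exponential).

Decay is linear (`k_d = 8.33×10⁻⁴ h⁻¹` for all populations by default,
per-population override allowed). Decayed biomass leaves the system —
there is no lysis-recycling — so strict element conservation holds for
the reaction network only; the conservation tests therefore run with
`k_d = 0`.

## Gas/liquid exchange

Each exchanged substance is two species (aq and g), each in mol per litre
of its own phase. The transfer law is
`d[aq]/dt = −k_La([aq] − C_eq)`, `d[gas]/dt = +k_La(V_aq/V_g)([aq] − C_eq)`
with `C_eq = H(T)·R·T·[gas]` — the Henry-equilibrium aqueous
concentration implied by the current headspace partial pressure via the
ideal-gas law; the pair conserves total moles identically. Henry
solubilities are adjusted as `H(T) = H_ref·exp(c(1/T − 1/T_ref))` with
the standard positive-`c` solubility convention (solubility falls with
temperature). Headspace pressure is emergent; there is no venting.
`fit_kla` estimates `k_La` by bounded scalar least squares (on
`log10 k_La`, since the response spans decades) against an integrated
equilibration series, and raises if the series starts at equilibrium
(flat objective).

## Calibration

`weighted_sse` standardizes each observed variable by its own observed
maximum before squaring so metabolites spanning orders of magnitude
contribute comparably, with a floor of 10⁻⁶ mol L⁻¹ on the
standardization constant: a variable whose observed maximum sits at
instrument detection level (e.g. methane in a methanogen-free culture)
carries no information, and without the floor its near-zero normalizer
amplifies integrator noise into the objective.

`parameter_effect` perturbs one `dG_min` by ±5 kJ mol⁻¹ (matching the
resolution at which the error landscapes are examined), re-simulates, and
reports the number of observed variables whose trajectory changes by more
than 1% of its own maximum (extent) and the largest such change (scale).
`hierarchical_calibrate` ranks the remaining parameters by (extent
ascending, scale descending, declaration order), fits the winner by
truncated-Newton (`scipy` TNC, bounds [−60, −1] kJ mol⁻¹, start −40,
finite-difference step 0.05) against data weighted proportionally to that
parameter's per-variable sensitivity (renormalized to sum 1), fixes it,
and repeats; the outer loop restarts from Gaussian-jittered starts
(σ = 3 kJ mol⁻¹, seeded) until the improvement falls below tolerance. If
*every* requested parameter has zero extent the problem is declared
unidentifiable; parameters that lose all effect after others are fixed
are reported as uncalibrated rather than fitted. The upper bound of
−1 kJ mol⁻¹ deliberately excludes the spurious optimum at 0 (a vanishing
threshold would mean no catabolic energy is ever stored as driving
force). Calibration loops integrate at slightly coarsened tolerances
(rtol 10⁻⁵, atol 10⁻¹⁰); the final reported SSE uses the same solver so
comparisons are internally consistent.

`sweep` freezes all parameters but one, walks a grid, records
per-variable (and per-subset) standardized SSE curves and normalizes each
by its own maximum; failed integrations become missing points.

## The synthetic experiment

`build_dv_mm_mb_system` emulates the wet protocol: 5 mL of medium with
30 mM Na-lactate, 7.5 mM Na2SO4, 10 mM NaHCO3 and 5 mM NH4Cl under a
~12.3 mL headspace of 0.8 atm N2 / 0.2 atm CO2 at 310.15 K, inoculated at
OD600 = 0.05 (converted to C-mol L⁻¹ by
`DW = exp(5.12·OD − 4.987)` g L⁻¹ and the 24.6 g C-mol⁻¹ biomass molar
mass, split evenly across the populations present). Observations are
sampled daily for 21 days with multiplicative lognormal noise
(σ = 0.05 by default; geometric-mean unbiased), covering lactate,
acetate, headspace H2 and CH4, plus pH and total biomass.

Pathway stoichiometries, `dG_met` values, the biomass formation energy
and `k_d` follow the published energetics of this model system. The
remaining kinetic and transfer constants are stated assumptions chosen
once at literature-plausible magnitudes:

| parameter | value | rationale |
|---|---|---|
| v_max (lactate fermentation / lactate+sulfate / H2+sulfate) | 0.2 / 0.25 / 1.5 mol_S (mol_X h)⁻¹ | yields μ ≈ 0.04–0.09 h⁻¹ for the sulfate reducer, the observed timescale of multi-day conversion |
| v_max (Mm HM / Mb HM / Mb AM) | 1.2 / 0.6 / 0.12 | hydrogenotrophs turn over H2 fast at tiny yield; acetoclastic growth is slow |
| K_S | lactate 0.5 mM, sulfate 0.2 mM, H2 1–10 µM, acetate 3 mM, HCO3⁻ 0.1 mM | typical half-saturation ranges for these guilds |
| k_La | 0.4–0.6 h⁻¹ | static sealed tubes, no stirring |
| Henry (H2, CO2, CH4, H2S) | 7.8×10⁻⁶, 3.3×10⁻⁴, 1.4×10⁻⁵, 1.0×10⁻³ mol m⁻³ Pa⁻¹ with c = 530, 2400, 1900, 2100 K | standard solubility compilation values |
| default dG_min | −30 (fermentation), −44.66 (sulfate respiration), −25 (HM), −40 (AM) kJ mol⁻¹ | ranges reported for these pathways; sulfate respiration from the earlier monoculture estimate |
| pK values | lactate 3.86, acetate 4.76, carbonate 6.35/10.33, sulfide 7.05, ammonium 9.25, pK_w 14.0 | 25 °C literature values; pK_w configurable (≈13.6 at 310 K if a user prefers the corrected value) |

What the generator does **not** emulate: pyruvate carry-over from the
inocula, stock-culture passaging history, replicate tube-to-tube
variability beyond the lognormal noise, headspace pressure measurement
and venting, and temperature excursions. Passing recovery tests on these
synthetic data therefore demonstrate that the estimation machinery is
correct and the parameter identifiable *under the model's own dynamics
and an honest noise level* — not that any particular literature value is
the true threshold of a real organism.

## Numerics

Integration uses stiff-capable adaptive solvers (`LSODA` default,
rtol 10⁻⁶, atol 10⁻¹² mol L⁻¹); pH-coupled batch systems stiffen near
substrate exhaustion. Terminal concentrations move by <0.1% under
tolerance halving (asserted in the suite). The acceptance-level recovery
tests use the full 504 h horizon with 22 daily samples; unit tests of the
calibration machinery use a 240 h horizon with 11 samples to keep the
default suite around five minutes. `F_T`'s strict upper bound (<1) is
mathematical; in double precision `1 − exp(x)` rounds to exactly 1.0 once
`x < −34`, and tests assert strictness only where `1 − F_T` is
representable.

Known limitations: constant maintenance lumped into `dG_met` (no dynamic
maintenance model), no diauxic or regulatory effects, no ionic-strength
corrections, no precipitation or ion pairing, temperature-fixed pK
values, fixed-volume batch operation only, and decayed biomass vanishing
from the mass balance.
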