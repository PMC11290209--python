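# Methods

## Models and assumptions

Both process models are deterministic batch mass balances with
growth-coupled product formation. Biomass X [g L⁻¹], liquid analytes
[g L⁻¹]; time in hours.

The **heterotrophic model** assumes a single limiting substrate (fructose,
Monod kinetics with affinity K_S,F), an exponential lag factor
(1 − e^(−t/t_lag)) applied to growth only (not to lysis), an optional
product-inhibition factor K_I,B/(K_I,B + c_B) on growth, and a lysis rate
interpolating between μ_d,min (substrate-replete) and μ_d,min + μ_d,max
(substrate-exhausted) with the inhibition factor scaling only the variable
part. Acetoin and 2,3-BDO formation are proportional to growth through the
coupling yields Y_X,A and Y_X,B. After fructose depletion a back-reaction
reoxidizes 2,3-BDO to acetoin: its rate is Monod in c_B with maximum uptake
q_B,max, and its products are coupled by the mass yield Y_A,B (acetoin
produced per BDO consumed), so d c_A/dt gains +q_AB·X and d c_B/dt loses
(q_AB/Y_A,B)·X. The reaction activates when fructose falls below a small
positive threshold (default 0.05 g L⁻¹) rather than exactly zero, to avoid a
discontinuity at the origin.

The **autotrophic model** treats the closed bottle as two well-mixed
compartments. Headspace composition is tracked as mole fractions; dissolved
O₂/CO₂/H₂ in mol L⁻¹. Transfer follows k_La·(c\* − c_l) with the Henry
equilibrium c\* = x·P·H; the headspace balance is the mirror flux scaled by
V_L·R·T/(V_G·P). Pressure is held at 1 atm (experimentally restored with
inert N₂), temperature at 303.15 K. Growth is μ_max times the product of
the three dissolved-gas Monod factors; lysis mirrors it above μ_d,min.
Product formation is growth-coupled exactly as in the heterotrophic model;
product carbon is therefore not explicitly balanced against CO₂ uptake — a
deliberate simplification of the model family, which ties all gas uptake to
growth through the yields Y_X,O₂/CO₂/H₂ [g_cell mol⁻¹].

**Regime switching.** Depletion events change the active kinetics
discretely: when dissolved CO₂ falls below its threshold the CO₂ Monod
factor is dropped from growth and lysis (otherwise all rates would pin at
zero and the remaining gases would stop depleting), the first forward
acetoin→BDO exchange activates, and the reverse BDO→acetoin exchange runs
while O₂ lasts; when dissolved O₂ also depletes, the reverse reaction stops
and the second forward exchange takes over. Each stage is independently
enableable so per-strain model structures can be expressed. Lysis is always
switched together with growth. Thresholds default to 1% of the initial
equilibrium solubility of the gas ("almost depleted" made proportional and
scale-free); the fructose threshold defaults to 0.05 g L⁻¹. Switches are
one-way by default (the order observed in practice); a reversible mode
exists for exploration. The integrator locates each crossing with solve_ivp
event detection and restarts from the event state, so switch times are not
grid-limited.

## Numerical choices

* Integration: scipy BDF (variable-order implicit, the NDF family used for
  stiff biokinetic systems), rtol 1e-6 / atol 1e-9 by default.
* Negative-state protection: rate evaluations clip small negative state
  excursions to zero because implicit solvers probe beyond the boundary
  during Newton iterations; grossly negative or NaN states raise an error
  naming the field. Reported trajectories clip dips above −1e-4 to zero.
* Gas-uptake regularization: each uptake term carries a smooth availability
  factor c_l/(c_l + ε), ε = 1e-8 mol L⁻¹. After the kinetic switch the
  dropped gas no longer limits μ, so its uptake term alone would push the
  dissolved concentration negative; the factor shuts uptake off continuously
  at zero and is indistinguishable from 1 above ~1e-6 mol L⁻¹.
* Henry solubilities are compilation reference values at 298.15 K
  (O₂ 1.3e-3, CO₂ 3.4e-2, H₂ 7.8e-4 mol L⁻¹ atm⁻¹) moved to 30 °C by the
  van 't Hoff form; they are physical constants, not fitted, and can be
  overridden. The gas-phase ODEs use R = 0.082057 L atm mol⁻¹ K⁻¹ so that
  atm-based Henry constants are dimensionally consistent without Pa/m³
  conversions; a validation heuristic rejects environments mixing the SI
  gas constant with atm-scale pressures. Headspace mole *accounting* for
  yields deliberately uses SI (R = 8.314, 298.15 K ambient) because samples
  are drawn and measured at ambient conditions — the two temperatures are
  intentionally not reconciled.
* Initial dissolved gases default to equilibrium with the initial headspace.

## Estimation

The objective is the weighted SSE between observations and the trajectory
evaluated exactly at the observation times (the observation times are part
of the solver output grid — no interpolation error). OD₆₀₀ readings are
converted to biomass through the linear dry-weight calibration
(0.6416·OD + 0.0632 g L⁻¹) before residuals are formed. Per-observable
weights default to the inverse variance of that observable's measurements so
g L⁻¹ analytes and mole fractions contribute commensurably. Optimization is
scipy `least_squares` (Trust Region Reflective) under box bounds with a
3000-evaluation / 200-iteration budget. Two settings matter in practice:
the finite-difference step is 1e-3 (relative) so the numerical Jacobian
clears the adaptive-solver noise floor, and termination tolerances are tight
(ftol = xtol = 1e-14) because the sloppy parameter directions of kinetic
models otherwise stall the search far from the optimum. Candidates that
crash the solver receive a large finite penalty instead of raising. A
multi-start option (seeded uniform restarts, best objective kept) exists but
defaults to a single start. The condition number of the Jacobian at the
optimum is reported as an identifiability diagnostic — with 12–25 parameters
and roughly daily sampling, non-identifiability is the norm, not the
exception.

## Yield accounting

* OD→biomass: 0.6416·OD₆₀₀ + 0.0632 g L⁻¹ (dry-weight calibration).
* Biomass moles use the lumped formula C₄H₇O₁.₅N ≈ 93 g mol⁻¹.
* Headspace moles: n = P·V/(R·T); per-gas moles are fraction·n with the
  untracked remainder reported as inert N₂.
* Carbon yields correct for the sampling protocol: liquid volume shrinks by
  each withdrawn sample, withdrawn product moles still count as formed, and
  withdrawn substrate does not count as consumed; gas-sample withdrawals are
  credited back to the CO₂ balance. Heterotrophic yields are percent of the
  1 mol product / mol fructose pathway ceiling; autotrophic yields default
  to the carbon basis (4 product carbons per molecule, 100% = every CO₂
  carbon ends in product), with the mole basis (ceiling 25%, net 4 CO₂ per
  product) available.
* Hydrogen efficiency: theoretical H₂ from the element balance
  C·CO₂ + a·H₂ (+ N·NH₃) → product + w·H₂O, giving a = H/2 + 2C − O − 1.5N
  (11 mol for 2,3-BDO, 10 for acetoin, 8.5 for biomass), divided by H₂
  actually consumed. Biomass is excluded by default (the efficiency is
  defined for products) and can be included with NH₃ as nitrogen source.
* Volumetric productivity: concentration gained since t₀ over elapsed time,
  at the first sample, a named time, or maximized over a dense grid.
* NaHCO₃ carbon is counted in the initial carbon pool only.

## Synthetic data

The generator emulates the two study designs with known ground truth:
heterotrophic flasks inoculated at OD₆₀₀ 0.05 in 20 mM fructose, sampled at
12 evenly spaced points over 120 h; autotrophic closed 1-L bottles at OD₆₀₀
4, 50 mL liquid under 1.08 L of 80/5/15% H₂/CO₂/O₂ at 1 bar, with 1 mL
liquid and 30 mL gas withdrawn per sample and pressure restored with N₂
(each gas sample therefore multiplies the tracked fractions by
1 − v/V_G). Observations are truth values corrupted by multiplicative
Gaussian noise (default CV 5% for liquid analytes and OD, 2% for gas
fractions) plus a small additive floor, clipped at zero; noisy gas fractions
are renormalized when their sum exceeds one, as a gas chromatogram report
would be. OD₆₀₀ observations are generated by inverting the dry-weight
calibration from true biomass so that estimation exercises the conversion
path. A seed fixes the entire output.

Ground-truth parameters were chosen once to reproduce the magnitudes of the
published campaigns: heterotrophic runs consume 20 mM fructose within about
two days at μ ≈ 0.05 h⁻¹ and accumulate ~15 mM acetoin and ~6 mM 2,3-BDO
with a slow back-reaction (Y_A,B = 0.97 g g⁻¹) afterwards; autotrophic
bottles barely grow, deplete their ~2.2 mmol of headspace CO₂ within the
first days at an H₂/CO₂ consumption ratio near 6.5 (gas yields follow the
knallgas biomass stoichiometry), and reach ~8–10 mM 2,3-BDO. What the
generator does **not** emulate: instrument artifacts (HPLC drift, GC split
ratios), biological replicate variability beyond the stated noise law,
pH/temperature excursions, and any mismatch between model structure and
reality — passing recovery tests therefore demonstrates correctness of the
estimation machinery, not that the model is structurally adequate for any
particular real dataset.

## Study sizes used in tests and the acceptance script

Noiseless recovery fits six free parameters (μ_max, K_S,F, Y_X,F, Y_X,A,
Y_X,B, t_lag) from starts perturbed ±20%. The noisy Monte-Carlo study (20
seeded replicates, 5% CV, 10 time points) frees μ_max and the three yields
while holding t_lag and K_S,F at their generating values: those shape
parameters are weakly identifiable from sparse noisy data and trade off
against μ_max, and the study profiles growth-rate recovery, not joint
identifiability. The solver-oracle comparison runs both models for 100 h
against a fixed-step RK4 at h = 1e-3 h; conservation checks run an abiotic
bottle for 50 h.

## Known limitations

* Product formation is strictly growth-coupled except for the exchange
  reactions; carbon is not conserved between CO₂ uptake and product output
  (inherited from the model family's structure).
* The interior of a regime is smooth but rates jump at switches; fits with
  data points straddling a switch inherit that discontinuity.
* Fed-batch and continuous operation, CO utilization, pressure dynamics and
  bicarbonate speciation are out of scope.
* Single-start local optimization can land in local minima for poorly
  chosen starts; use `n_starts > 1` when bounds are wide.
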