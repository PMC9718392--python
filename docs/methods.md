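# Methods

This note records the models behind `aragsim`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not establish about real laboratory data.

## Carbonate-system model

Speciation at fixed (pH, DIC) is closed-form: with h = [H⁺] on the seawater
scale (SWS),

    [CO2*]  = DIC / (1 + K1/h + K1·K2/h²),
    [HCO3⁻] = [CO2*]·K1/h,   [CO3²⁻] = [HCO3⁻]·K2/h,
    Ω       = [Ca²⁺][CO3²⁻] / Ksp_aragonite.

pH is logged on the NBS scale (glass electrode, NBS buffers) and converted
via the apparent activity coefficient fH (Takahashi et al. GEOSECS
convention): [H⁺]_SWS = 10^(−pH_NBS)/fH. All constants are evaluated at
(T, S) and converted to SWS internally:

| constant | formulation | note |
|---|---|---|
| K1, K2 | Mehrbach et al. refit by Dickson & Millero (1987) | default; `lueker2000` selectable |
| KB | Dickson (1990) | total→SWS converted |
| KW | Millero (1995) | SWS |
| KS | Dickson (1990) | free scale, used in scale conversions |
| KF | Perez & Fraga (1987) | |
| K0 | Weiss (1974) | for pCO₂ |
| B_T | Uppström (1974) | salinity-scaled |
| Ksp (aragonite) | Mucci (1983), 25 °C, 1 atm | 6.48×10⁻⁷ mol² kg⁻² at S = 35 |

The Mehrbach-refit default was chosen because it reproduces the Ω means of
the two stock waters at the three experimental set points (6.86/11.28/19.35
against the documented 6.9/11.3/19.2); the Lueker set runs ~0.3 Ω lower at
Ω ≈ 11 and both sets agree to ≤ 0.02 pK after scale conversion, which
cross-validates the conversion machinery. Independent anchors: the
stock artificial seawater (TA 2309, DIC 2015 μmol kg⁻¹, S 33.7) solves to
pCO₂ ≈ 397 μatm, consistent with equilibration against ~410–420 μatm
ambient air; and total alkalinity round-trips pH ↔ TA to < 10⁻⁴ pH units.

Total alkalinity includes the carbonate, borate, water, bisulfate and
fluoride terms; nutrient and organic alkalinity are neglected (the waters
are filtered and the experiments short). Pressure dependence is not
modelled (bench-top, 1 atm).

**Mass convention.** The experimental budgets treat a 330 mL solution as
0.330 kg; `SeawaterState.solution_mass` therefore defaults to the numerical
value of the volume in litres, which reproduces the printed dose budgets
(ΔTA = 1156/640, ΔDIC = 578/320 μmol kg⁻¹ for 0.318/0.176 mL of 0.6 M
Na₂CO₃) exactly. Pass an explicit mass to apply a density correction.
The Sr²⁺ in the CaCl₂ titrant (1% molar) is counted as Ca-equivalent: Ω
uses Ca only and the substitution is below every tolerance used here.

## Seed geometry and epitaxial growth

The seed powder is idealised as N identical cubes; SSA = 6/(ρa) fixes the
starting edge a = 0.486 μm from BET 4.2 m² g⁻¹ and ρ = 2.94 g cm⁻³.
Epitaxial growth distributes deposited volume equally over the cubes, which
remain cubes (a′ = (a³ + ΔV/N)^⅓) at constant N, so area ∝ mass^(2/3).
Polydispersity, face-specific growth and clumping-induced area loss are
deliberately not modelled; the cubic model exists to ask whether the
*magnitude* of area growth explains the curvature of dosing profiles, and
it is exactly solvable (the test suite checks the simulator against the
closed form m^⅓(t) = m₀^⅓ + R·A₀·t/(3·m₀^⅔)).

The wetted apparatus area (beaker wall + bottom disc + immersed probe
laterals, ≈ 0.0297 m² for the documented geometry) bounds the surface
available for off-seed heterogeneous nucleation; even a 50 mg seed aliquot
(0.210 m²) exceeds it sevenfold.

## Forward titration model

Explicit time stepping (default Δt = 10 s, valid range 1–60 s): per step
the seed of area A precipitates R·A·Δt μmol, dosing moles/molarity of each
titrant, and the deposit grows the seed. Halving Δt changes total duration
by < 0.1% at the default. Dosing is continuous in the forward model; the
2 μL burette quantisation is applied only by the synthetic-data generator,
so the model prediction used in fitting stays smooth.

CO₂ invasion (flux F μmol kg⁻¹ h⁻¹) lowers pH and triggers paired dosing
without precipitation; it is modelled as an extra dosing rate
F·m/(2·M) per titrant — the 50/50 split across the titrant pair is a
package convention recorded in the profile metadata, since only the summed
dosing is observable. Nucleation lags suppress growth (not invasion
dosing) for their duration. Unseeded runs are represented only
descriptively (user-supplied onset time and effective area): homogeneous
nucleation was found irreproducible experimentally and is out of scope.

## Rate/lag inversion

`TitrationRateModel` varies R (bounded Brent search on [1, 10⁴]
μmol m⁻² h⁻¹, `xatol` 0.05) to maximise r² = 1 − SS_res/SS_tot between the
observed cumulative volumes and a third-order polynomial regressed through
the predicted profile, evaluated at the observed times inside the 1–5 mL
window. The cubic is fitted to the *prediction* (which is smooth) and
serves as its continuous interpolant; r² is evaluated at all logged
in-window points. The lag is t_obs(1 mL) − t_pred(1 mL), clipped at zero,
and the prediction is right-shifted by it before scoring; lags < 300 s are
flagged unreliable because seed addition itself takes 60–120 s. Runs
deliberately stopped early (e.g. 2 mL at the slowest condition) scale the
window proportionally (0.4–2 mL), recorded in the diagnostics.

On noiseless forward-model output the estimator recovers the generating
rate to < 0.5% with r² ≥ 0.999 across seed masses 50–400 mg and rates
100–3000 μmol m⁻² h⁻¹ (unimodality of r² in R holds empirically across
this grid); with 1% dosing noise and 2 μL quantisation the median of 20
replicates stays within 5%. Duplicate reproducibility is summarised as
CV = 100·sd/mean (1σ, ddof = 1).

## Raman ν₁ analysis

The ν₁ band is fitted over 1060–1110 cm⁻¹ with a linear baseline plus a
Voigt profile (lmfit; Gaussian σ and Lorentzian γ both free). The window
isolates ν₁ while excluding the aspartic-acid band near 936 cm⁻¹. FWHM is
measured on the fitted Voigt component by bisection at half maximum rather
than from the Olivero–Longbothum approximation (the tests show the two
agree to ~0.03%). Initial guesses come from the window maximum and a
moment-based width; a fitted centre within two grid steps of the window
edge raises a flag.

Polymorph identification estimates the noise floor from the band-free
800–1000 cm⁻¹ region, then requires: a strong (≥10σ) peak near 1084 cm⁻¹,
plus two resolvable maxima in 695–715 cm⁻¹ for aragonite (one for
calcite). A relative prominence floor (20% of the strongest ν₄ prominence)
prevents noise wiggles from mimicking the doublet; smoothing is kept to a
5-point Savitzky–Golay window because the doublet components are only
~4 cm⁻¹ apart.

Group comparisons use one-way ANOVA (scipy) with Tukey HSD (statsmodels)
at α = 0.05; zero-variance inputs short-circuit to "no significant pairs"
with F reported as NaN. A permutation test on mean differences serves as
the independent oracle in the test suite.

The in-vitro fraction 100·precipitated/(seed+precipitated) carries a
resolvability flag at ≥ 60% — the dilution at which the precipitate's ν₁
signature separates statistically from the seed's.

## Synthetic-data generator

The generator emulates: profile shapes (linear at high seed mass, curved
at low), nucleation lags (long at Ω = 6.9 with ≤ 100 mg seed, longer in
natural water), CO₂-invasion drift in unseeded runs (26/31 μmol kg⁻¹ h⁻¹),
the 2 μL dose quantum, ~2 s timestamp jitter, 1% multiplicative dosing
noise, and a 6% log-normal between-replicate rate variability calibrated
so duplicate CVs land in the observed "typically ~6%, always < 10%"
envelope. Rates default to the power law R = k(Ω−1)^1.7 anchored at
617 μmol m⁻² h⁻¹ (Ω = 6.9, natural water) with artificial water ~19%
slower; these are plausibility defaults for exercising the pipeline, not
fitted kinetics. Aspartic-acid effects are purely phenomenological rate
multipliers (+20% at 1–10 μM, −45% at ≥ 1 mM) and a +1 cm⁻¹ ν₁ FWHM
offset at ≥ 1 mM.

Synthetic spectra put a Voigt ν₁ at 1084.3 cm⁻¹ (40% Lorentzian share),
the ν₄ doublet at 701.1/705.5 cm⁻¹, Gaussian lattice-mode humps at 152 and
206 cm⁻¹, a linear baseline and white noise on a 1 cm⁻¹ grid spanning
100–1311 cm⁻¹.

**What passing tests show — and don't.** The synthetic data share the
analysis's own noise model, so recovery tests demonstrate estimator
correctness and noise robustness, not the realism of the forward model:
real runs add clumping-induced area loss (the suspected cause of the low
rates recovered from 50 mg seeds), electrode drift, true titrator
controller dynamics, and Raman baselines that are not exactly linear.
None of those are claimed to be captured.

## Numerical conventions and edge cases

- DIC = 0 speciates to all-zero with Ω = 0 rather than failing.
- A dosing profile must start at (0, 0) and be monotone in both series;
  `time_at_volume` interpolates linearly and refuses extrapolation.
- Zero observed dosing variance in the fit window returns rate 0 with a
  `flat_profile` diagnostic; profiles never reaching 1 mL raise an
  insufficient-data error; a zero-rate, zero-invasion simulation raises a
  non-termination error carrying the partial profile.
- Rate-search ties break toward the lower rate (bounded minimiser).
- All random draws flow from explicit integer seeds
  (`numpy.random.default_rng((seed, replicate))`); reports contain no
  timestamps so reruns are byte-identical.
- Problem sizes in the test suite (≤ 20 replicates per noisy condition,
  ≤ 3000 permutations in oracles, ~3000-step simulations via an adaptive
  internal step) were chosen to keep the full suite under a minute on one
  CPU while leaving every statistical check well-powered.

## Known limitations

- The carbonate constants reproduce the documented Ω means to ±0.05–0.15;
  the exact constant formulations behind the original CO2SYS v2.1 runs are
  configurable, not asserted.
- The Ω shift from swapping the natural and artificial water compositions
  is ≤ 0.2 at the two lower set points but ≈ 0.27 at Ω ≈ 19 with the
  default constants.
- The inversion assumes the cubic-seed area trajectory; systematic area
  errors (clumping, polydispersity) bias R̂ proportionally.
- No uncertainty beyond duplicate CV and Monte-Carlo spread; no joint
  hierarchical fitting across experiments.
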