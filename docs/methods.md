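# Methods

This note documents the models, defaults, and numerical choices behind
`smtzkit`, and what the synthetic-data generators do and do not emulate.

## Porewater conversions

**Porosity.** Φ = ((m_w − m_d)/ρ_pw) / (m_d/ρ_sm + (m_w − m_d)/ρ_pw), with
porewater density ρ_pw = 1.025 g/cm³ (near-seawater) and solid-matter
density ρ_sm = 2.34 g/cm³ by default; both are parameters. Φ is strictly
increasing in wet mass at fixed dry mass and bounded in [0, 1).

**Headspace methane.** Vials of V_s = 4 mL sediment in 60 mL serum vials
(V_h = 55 mL headspace) are shaken so that essentially all methane
partitions into the headspace. Dissolved CH₄ (mM) = ppm·V_h /
(R·T·Φ·V_s·1000), with R = 0.082057 L·atm·mol⁻¹·K⁻¹ and T = 295 K by
default. The headspace is assumed to be at exactly 1 atm after N₂ sparging
(`HEADSPACE_PRESSURE_ATM`); the formula is then identical to an ideal-gas
mole balance attributing the headspace moles to the porewater volume Φ·V_s.
No correction is applied for the 1 mL of KOH fixative; the 55 mL headspace
geometry is used as given.

**Cline sulfide.** A linear absorbance(667 nm)-vs-concentration calibration,
either supplied directly or fit by OLS to ≥3 standards, inverted and scaled
by the dilution factor. Absorbance outside the linear band (default
0.1–0.9) raises an error instructing re-dilution rather than extrapolating.
Slightly negative back-calculated concentrations (blank-level noise) are
clamped to 0 with a logged warning instead of raising.

**Organic fractions.** Organic C and N are totals minus inorganic fractions;
inorganic exceeding total is a domain error.

## Gibbs-energy window model

The reaction is written in bicarbonate form, 4 H₂(aq) + HCO₃⁻ + H⁺ →
CH₄(aq) + 3 H₂O(l), because HCO₃⁻ is the measured carbonate species in
porewater. Default standard free energies of formation (kJ/mol, aqueous,
25 °C, from standard compilations): H₂(aq) +17.57, HCO₃⁻ −586.85, H⁺ 0,
CH₄(aq) −34.39, H₂O(l) −237.18, giving ΔG°rxn ≈ −229.4 kJ/mol. All are
user-overridable. Default conditions: CH₄ = 5.3×10⁻⁴ M, HCO₃⁻ = 4.84×10⁻²
M, T = 295 K, pH 7.8 (a typical organic-rich marine porewater value; pH is
an explicit parameter because the quotient contains [H⁺]).

Deliberate simplifications, documented as limitations:

* activities = molar concentrations (no ionic-strength correction); water
  activity = 1;
* ΔG° is used at 25 °C without van 't Hoff correction to 295 K (≤3 K
  offset);
* acetoclastic/methylotrophic methanogenesis and the sulfate-reduction
  half-reaction are out of scope.

ΔG_AOM ≡ −ΔG_meth exactly (reverse reaction), and d(ΔG_meth)/d(ln[H₂]) =
−4RT exactly; both identities are enforced by tests to 10⁻⁹ kJ/mol. The
critical-H₂ inverse is closed-form and must plug back to the target ΔG
within 10⁻⁹ kJ/mol.

**Regime classification.** With biological energy quantum BEQ = 10 kJ/mol
(parameter), conditions are classified on ΔG_meth: ≤ −BEQ →
methanogenesis; ≥ +BEQ → AOM (the reverse direction then clears the BEQ);
otherwise no_reaction. Boundary values exactly at ±BEQ are assigned to the
reactive regime — an arbitrary but fixed tie-break. H₂ sweeps use a
log-spaced grid, on which ΔG_meth is strictly decreasing, so the regime
column changes at most twice, in the order aom → no_reaction →
methanogenesis.

## Depth-profile diagnostics

**Onset.** The methane-onset depth is the shallowest section where CH₄
reaches the threshold (default 0.1 mM) and stays at or above it,
non-decreasing within a noise tolerance (default 0.05 mM), over the next
k = 3 sections. The persistence window is the noise guard: an isolated
spike does not qualify, and adding sub-threshold sections above the onset
never changes the result. Sulfate at the onset is linearly interpolated.
A profile with no qualifying depth returns an absent-onset result, not an
error.

**Concavity.** Second derivatives of CH₄ vs depth are estimated with the
three-point divided-difference stencil, which is exact for quadratics on
irregular grids; values are reported in mM/cm² (on a uniform grid of
spacing h this equals the plain second difference divided by h²). The mean
is tested against zero with a two-sided one-sample t-test: the profile is
"linear" unless zero curvature is rejected at α = 0.05, in which case the
sign of the mean gives concave_up/concave_down, demoted to "mixed" when
fewer than 70% of the individual values share that sign. The t-test rule
was chosen over a fixed fraction-of-SE band because with the handful of
interior points a typical methanocline window offers, a tight band
misclassifies genuinely linear noisy profiles most of the time; the test
controls that error at α. The second differences of overlapping stencils
are correlated, so the test is approximate — it is a classification rule,
not an inference procedure.

**SMTZ crossing.** Both profiles are interpolated piecewise linearly (no
spline smoothing: small n, irregular grids) and the first sign change of
CH₄ − SO₄ is solved exactly on its bracketing segment; the shallowest
crossing is reported, or absent when the curves never cross.

**Regressions.** OLS (scipy) with a two-sided t-test on the slope at
df = n − 2; results are verified against a hand-coded normal-equation
oracle to 10⁻¹⁰ relative error. The sulfate–sulfide regression pools cores
by default (replicate cores are usually reported together); per-core mode
is available.

## Incubation analysis

Production rates are OLS slopes of headspace ppm vs day over a window.
Inhibition is tested as a two-tailed two-sample t-test of controls vs
treated vials — Welch (unequal variance) by default, pooled-variance
available — on either headspace CH₄ interpolated to a comparison day
(default) or per-vial rates. Release from inhibition is the first
observation exceeding baseline mean + 3 SD (baseline = first 3
observations), by at least 1 ppm so a zero-noise flat baseline cannot
trigger, and staying above that level for all later observations. The
δ¹³C-shift onset is the first observation starting a monotone decline
sustained over ≥2 further observations with total drop ≥5‰ and a first
step of ≥2‰ (the first-step floor keeps baseline instrument noise from
pulling the onset one sample early).

## Synthetic-data generators

All generators are pure functions of (scenario, seed); the root seed is
split into per-stream sub-seeds (`numpy.random.SeedSequence.spawn`) so that
adding a noise stream never perturbs existing ones. Noise-free outputs equal
the closed-form curves exactly and are tested so.

**Cores** (2-cm sections, midpoints at odd cm): sulfate declines
exponentially from 25 mM toward a floor (5 mM by default — sulfate stays
millimolar at depth in the organic-rich preset); sulfide is the
stoichiometric yield (0.8 mol/mol) times cumulative sulfate loss; porosity
drifts linearly 0.85 → 0.70; methane is either zero above an onset then
linear to saturation 1.5 mM (`clb_linear`, onset 32–34 cm, slope 0.15
mM/cm) or a logistic methanocline (`aom_sigmoidal`) paired with near-zero
sulfate at depth so an equimolar crossing exists. Gaussian noise per analyte
(CH₄ σ = 0.02 mM by default), truncated at zero. The `aom` preset uses a
smaller CH₄ noise (0.005 mM) so the curvature of its methanocline — the
feature the preset exists to exhibit — is resolvable over the few sections
a 42-cm core provides. The generators emulate the *shape* of real
profiles, not their physics: there is no diffusion–reaction transport, so
recovery tests validate the estimators, not sediment biogeochemistry.

**Incubations**: controls rise linearly from a 10 ppm baseline to a target
(1,500 ppm by day 28 in the `experiment1` preset; 6,750 ppm by day 35 in
`experiment2`); treated vials stay at baseline until a release day (default
30) then rise at the same rate; CO₂ rises identically in all vials
(the inhibitor does not suppress heterotrophy); δ¹³C holds at −50‰ and
declines at 2‰/day starting 20 days (the isotope lag) after each vial's
methane rise. Noise: CH₄ 20 ppm, CO₂ 50 ppm, δ¹³C 0.5‰.

**Communities**: 300 ASVs (20 methanogen/ANME, 30 sulfate-reducer, 250
background) with guild-consistent taxonomy; the methanogen guild's expected
fraction follows a logistic ramp 0.6% → 2.0% in depth with midpoint at the
methane onset; sulfate reducers hold 7%. Within-guild weights are drawn
once per table (Dirichlet(1)); per-sample counts are Dirichlet-multinomial
(concentration 5000) at 130,000 reads per sample. Real amplicon features
*not* emulated: contaminants, variable read depth, phylogenetic correlation
among ASVs, taxonomy-assignment error.

## Community metrics

Relative abundances are plain per-sample fractions (no rarefaction or
compositional transform). Shannon uses the natural log by default (base
configurable), Simpson is 1 − Σp², and Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) by default (finite when doubletons are absent;
the classical form is available). Bray–Curtis comes from
`scipy.spatial.distance` and is verified against elementwise brute force.
Guild matching is exact string match at a configured rank with OR semantics
across a guild's matchers; definitions claiming the same ASV for two guilds
are a configuration error. Alpha diversity offers both per-sample and
pooled-counts modes, since whole-study single numbers can be computed either
way.

## Problem sizes in the test suite

Recovery suites use 200 synthetic cores (onsets 20–38 cm, CH₄ σ up to 0.05
mM), 100 incubation seeds, and 50 community seeds at 50,000 reads — sizes
chosen so each Monte-Carlo proportion is estimated well inside its pass
margin while the whole suite stays interactive. Recovery criteria compare
against the discretized truth (e.g. the first 2-cm section midpoint where
the noise-free curve crosses the onset threshold), since a continuous onset
parameter is only observable at section resolution.
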