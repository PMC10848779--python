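# Methods

## Physical model

The system is a well-mixed aqueous solution of a damaged (CPD-carrying)
oligonucleotide and its repaired counterpart in a cuvette of path length
*l* and irradiated volume *V*, exposed to a continuous polychromatic
source. The model makes four assumptions:

1. **Beer–Lambert competitive absorption.** At each wavelength the sample
   absorbs a fraction 1 − 10^(−A_tot) of the incident photons and species
   *i* receives the share A_i/A_tot of them. For A_tot < 10⁻⁶ the factor
   (1 − 10^(−A_tot))/A_tot is evaluated by its series limit ln 10 to avoid
   0/0. No radiative transfer, re-emission or photoselection effects.
2. **Scalar quantum yields.** Each absorbed photon converts the absorbing
   molecule with probability Φ_rep (damaged → repaired), Φ_dam
   (repaired → damaged) or Φ_side (repaired → irreversible side product).
   Yields are treated as wavelength-independent across the 15 nm source
   band and are defined per photon absorbed by the whole oligomer — not
   per photon absorbed by the guanine chromophore alone. The two
   definitions differ by the guanine share of the oligomer absorbance at
   the excitation band; the whole-oligomer convention matches what a
   dose–response experiment actually measures.
3. **Direct photoreversal folded in.** Direct absorption by the TT dimer
   at the excitation wavelengths is minimal by design of the source; any
   residual photoreversal is absorbed into the effective Φ_rep rather than
   modelled as a separate channel.
4. **Dose bookkeeping.** "Absorbed dose" is the cumulative radiant energy
   (J) absorbed by the whole sample across all species, integrated
   alongside the concentrations. Per-species absorbed photon counts are
   tracked separately for quantum-yield attribution.

The ODE system is integrated with LSODA (rtol 10⁻⁸, atol 10⁻¹² M).  The
damaged concentration is eliminated through the conservation law
c_dam = c_tot − c_rep − c_side, so total oligomer concentration is
conserved exactly (the side channel converts repaired molecules into a
third species; it does not destroy oligomers).

The photostationary state (PSS) has the optically thin closed form
f_pss = Φ_rep ε̄_D / (Φ_rep ε̄_D + Φ_dam ε̄_R), with ε̄ the photon-weighted
(s(λ)·λ) mean molar absorption coefficients over the source band. The ODE
route (`pss_fraction(..., "ode_limit")`) integrates until the fraction is
stationary; the two agree within 1% for peak band absorbances ≲ 0.05, and
the ODE limit is independent of the starting composition.

## Quantum-yield extraction

The observable is ΔA at the 266 nm probe vs absorbed dose D. Molecules
repaired per joule are slope/(Δε₂₆₆ l) · V N_A; photons absorbed per joule
are 1/Ē_ph, giving Φ = slope · V N_A Ē_ph / (Δε₂₆₆ l). Ē_ph is the mean
absorbed-photon energy (absorbed power over absorbed photon rate) at t = 0;
treating the band as monochromatic 285 nm changes it by < 0.5%.

*Linear range.* The longest initial prefix (≥ 4 points) whose quadratic
curvature term is statistically indistinguishable from zero (t-test,
α = 0.05) is used, and points beyond 25% of the estimated plateau ΔA are
excluded outright. The plateau is estimated by a saturating-exponential
fit; when the data never bend that fit is unidentifiable and the cap is
inactive. If no prefix qualifies, the first 4 points are used and the
result is flagged.

*Saturation correction.* Under the default conditions the response is
already ~20% of the way to the plateau at the last exposure — forced by
the experimental magnitudes themselves (a few tens of mOD of recovery
within 10 minutes against a ~190 mOD plateau) — so any straight-line slope
over an admissible range is biased low by 5–13%. The estimator therefore
rescales the measured OLS slope by the ratio of the initial slope of a
saturating-exponential fit to the OLS slope that model would produce over
the same points. The factor is exactly 1 for data with no detectable
bending, so the plain linear-trendline estimate is recovered in the
strictly linear regime; with the correction the noiseless default-schedule
extraction is accurate to ~0.4% and the noisy median to ~2%.

*Uncertainty.* Reported yields carry an absolute uncertainty of 40% of the
value (the empirical error estimate for this irradiation/HPLC setup),
applied after extraction; 0.40 × 0.58% → ±0.23% and 0.40 × 0.44% → ±0.18%
at two-decimal rounding.

*Equilibrium convention.* "Equilibrium reached" is the first dose within
5% (relative) of the plateau, i.e. D_eq = D₀ ln 20 from the fitted
saturating exponential. The plateau fit requires the data to span at least
80% of the fitted plateau.

## Synthetic-data generator

The generator emulates the study conditions: c₀ = 30 μM damaged oligomer,
LED at 285 nm (Gaussian, 15 nm FWHM, truncated at ±3σ, renormalised) with
0.36 mW at the sample, 1 cm path and 200 μL irradiated volume (cell
geometry is not part of the study conditions and is exposed as a
parameter), exposures of 1–10 min in 1-min steps, homoscedastic Gaussian
absorbance noise of σ = 1 mOD, and HPLC peaks at 8.4/9.9 min with σ = 0.12
min and 1% amplitude noise.

Species spectra are parametric Gaussian bands: a purine band (27 000
M⁻¹ cm⁻¹ at 257 nm, 31 nm FWHM) shared by both oligomers carries the
285 nm excitation (ε₂₈₅ ≈ 2 800 M⁻¹ cm⁻¹, band absorbance ≈ 0.08), and the
repaired species adds a thymine band at 266 nm whose amplitude equals the
configured Δε₂₆₆ (default 16 000 M⁻¹ cm⁻¹ per oligomer — a fixture value
standing in for literature coefficients, not a measured number). These
amplitudes were fixed once so that ten minutes of irradiation yields a few
tens of mOD of 266 nm recovery, the reported experimental scale.

Default truth parameters per scenario: Φ_rep = 0.58% (T<>TAG) and 0.44%
(GAT<>T). Φ_dam is not set directly: it is calibrated so the analytic PSS
equals the scenario's equilibrium level (40% and 33% respectively), which
gives Φ_dam ≈ 0.42% and 0.44% — a derived calibration, recorded as such.
Every simulated observable is accompanied by its noiseless truth channel,
and all randomness derives from a single recorded seed.

What the generator does **not** emulate: wavelength-correlated detector
noise, photoproduct absorption beyond a generic side species, pH and
temperature effects, injection-volume variability in the chromatograms,
and any conformational kinetics. Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain under
the stated noise model, not robustness to every systematic error of a real
spectrometer.

## Chromatogram quantification

Peaks are Gaussian (no asymmetry is modelled); the baseline is a linear
fit to the regions more than 4σ from every annotated retention time; a
peak counts as detected when its local maximum exceeds 5× the noise MAD;
areas are trapezoid integrals of the corrected signal over ±3σ of a
per-peak Gaussian fit, and composition comes from response-corrected area
shares. Response factors default to equal (both oligomers share base
composition); CPD hypochromicity can be expressed through the factor
table. Quantification is relative-area only — detector response and
injection volume are not modelled.

## Stacking geometry

χ is the standard glycosidic dihedral (O4′–C1′–N9–C4 for purines,
O4′–C1′–N1–C2 for pyrimidines), signed, in (−180°, 180°]; syn is
χ ∈ (−90°, +90°] and anti the complement, so the circle is fully
partitioned and ±90° boundaries are deterministic. Stacking overlap
projects both ring systems onto the least-squares plane of one base's
rings, intersects the ring polygons (hexagon ∪ fused pentagon for
purines) with exact polygon geometry, and averages the two projection
directions so the metric is symmetric; per-ring components (six/six,
six/five, five/five) are also available. No quantitative overlap metric is
standard in the field; this projected-intersection definition is this
package's choice, validated against Monte-Carlo point sampling. Rise is
the centroid separation along the mean ring normal. Ensembles enter as
multi-model PDB files; trajectory formats are out of scope.

The idealized stacked-pair generator builds planar purines (regular
hexagon + fused pentagon, bond 1.39 Å) with a minimal C1′/O4′ sugar stub
placed by internal coordinates to realise a requested χ (anti ≈ −120°,
syn ≈ +60°, Gaussian angular noise), stacked at 3.4 Å rise with optional
twist. It is a labelled-truth fixture for the census and overlap
operators, not a conformational model of real DNA.

## Energy ladders

The packaged datasets transcribe the published excited-state energetics of
the sequential electron transfer cascade. Only text- and table-printed
numbers are stored; energies that the source text gives only as relative
gaps are chained into absolute values and tagged `derived-from-text`
(e.g. the MECP of the A⁻˙G⁺˙ state at 4.27 − 0.12 + 1.18 = 5.33 eV), and
the < 0.1 eV CPD-splitting barrier is stored as a 0.1 eV upper bound
(`upper-bound-from-text`). Figure-read bar positions are excluded. The two
GAT<>T conformer ladders have no published absolute anchor above their
ground state, so they are referenced to their own G* S₁ minimum (G* ≡ 0,
points below it negative) with the reference recorded in the dataset; the
positivity and FC-presence invariants apply only to ground-state-referenced
ladders. A gap whose endpoints cannot both be anchored (the GA-syn
MECP_AG at +0.42 eV above its unanchored CT minimum) is kept as a
"floating gap" record rather than fabricating an anchor.

Validation checks are report entries, never exceptions: wavelength/energy
consistency of every vertical excitation (|Δλ| ≤ 0.5 nm, tolerating the
printed rounding), positivity, the monotone cascade G* ≥ A⁻G⁺ ≥ TT⁻AG⁺,
and the "MECP above the bright state" consistency of the relaxation
barrier arithmetic.

## Problem sizes and numerical choices

The recovery studies use 200 noisy replicates per scenario for the
quantum-yield medians and a single 41-point long-dose run per scenario
(five characteristic doses) for the plateau fits; these sizes put the
Monte-Carlo error of the medians well below the 40% experimental
uncertainty band while keeping the whole analysis interactive. Spectral
work uses a 1 nm grid over 220–340 nm (the 15 nm source band and the
266 nm probe are both well resolved); physical constants are CODATA exact
values with 1239.84198 eV·nm for energy/wavelength conversion. Degenerate
inputs are handled explicitly: zero beam power gives zero rates, all-zero
concentrations absorb nothing, collinear ring atoms and non-monotone grids
are rejected with named errors, and Φ_side > 0 makes the PSS undefined
(raised as such).

## Known limitations

- Quantum yields are effective, per whole-oligomer photon, averaged over
  the source band; wavelength-resolved yields would need narrowband
  dose-response data.
- The saturating-exponential plateau model is exact only in the optically
  thin limit; at band absorbances of ~0.1 the fitted plateau sits ~1–2%
  (relative) below the true stationary fraction.
- The stacking-overlap metric is geometric; it correlates with, but does
  not compute, electronic coupling.
- The packaged ladders carry no uncertainties: none are published for the
  underlying excited-state calculations.
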