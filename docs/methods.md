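# Methods

This note records the models implemented in `dimerswap`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Subunit-exchange analysis (`exchange`)

**Model.** Chromatograms are baseline-subtracted differential-refractive-
index traces on a strictly increasing time grid.  The residual is the
pointwise difference between the mixture trace and the sum of the
component traces after linear interpolation onto a common grid.  The
fraction sum residual is

θ_res = 100 · ∫ᵢʲ|S_res| dt / (f_d · ∫ᵢʲ|S_A+S_B| dt),  (i, j) = (14, 18) min,

computed by trapezoidal quadrature with the window edges interpolated
exactly; limits outside the grid are clipped.  The denominator factor
f_d defaults to 2 and is a configuration field.  The factor-2 reading was
adopted because each unit of exchanged (heterodimer) signal contributes
twice to ∫|S_res| — once as the positive intermediate peak and once, in
total, as depletion of the two homodimer peaks — so dividing by twice the
summed component signal makes θ_res equal the heterodimer signal fraction
for resolved peaks.  Under this reading complete statistical exchange of
an equimolar mixture (dimer population 25/50/25) gives exactly 50 %, and
θ_res = 100·f for heterodimer fraction f; both identities are verified in
the test suite against independent quadrature oracles.  An alternative
reading without the factor would double all values and make the
statistical-exchange ceiling 100 %.

**Scoring.** The background is the mean ± sample SD (n−1) of θ_res over
flagged non-exchanging pairs — by default the pairs whose two components
carry different three-residue Dimer-1 motifs (AVL vs VTF).  Scores use
strict inequalities against 1.3×/2×/5× the background mean; exact ties
fall to the lower score, following the ">" convention of the published
scoring scheme.

**Caveats.** Peak overlap cancels residual lobes, so θ_res is a lower
bound on the true exchanged fraction; the test suite asserts that
shrinking the homodimer–heterodimer retention gap never increases θ_res.
Inputs are assumed baseline-subtracted; `fit_linear_baseline` provides a
two-window linear correction when they are not.

## Sedimentation equilibrium (`sedeq`)

**Forward model.** Ideal (non-interacting with buffer, no second virial
term) self-association in a sector-shaped cell at equilibrium.  The
monomer follows c₁(r) = c₁(r_ref)·exp[σ₁(r²−r_ref²)/2] with the reduced
buoyant coefficient σ₁ = M(1−v̄ρ)ω²/RT evaluated in CGS units
(R = 8.31446×10⁷ erg mol⁻¹ K⁻¹), and the n-mer has σ_n = n σ₁, so mass
action (c₂ = c₁²/K12, c₄ = c₂²/K24) holds at every radius.  Exponents are
evaluated in log space.  Detector responses per molar monomer-equivalent:
absorbance ε₂₈₀·l; interference (dn/dc)·M·l/(1000·λ) fringes with
λ = 675 nm.  Defaults: v̄ = 0.73 mL/g, ρ = 1.005 g/mL, ε₂₈₀ = 9970
M⁻¹cm⁻¹, dn/dc = 0.185 mL/g, l = 1.2 cm, T = 293 K, speeds
20 000/23 000/26 000 rpm — generic values for a small (≈11.5 kDa)
tryptophan-containing protein domain in dilute saline buffer; the
absolute optical scales are absorbed by the fitted concentrations and do
not affect dissociation constants.

**Global fit.** K12 and K24 are optimised as log₁₀ values (positivity by
construction, bounds 10⁻¹²–1 M), shared across all profiles.  The default
parameterization floats one loading concentration per cell and derives
the meniscus monomer concentration of every speed column by conservation
of the sector-weighted column average (solved by bracketed root finding);
baselines are shared per (cell, detector).  This choice is what makes the
small, slowly-varying monomer amplitude identifiable: with an independent
reference concentration and baseline per profile the likelihood is nearly
flat in K12 — on synthetic data a fit with K12 sixteen-fold from the
generating value can beat the truth — because the monomer exponential is
almost collinear with a baseline offset.  Fully local parameterization
(`conserve_loading=False`, `baseline_per="profile"`) and a soft
mass-conservation penalty remain available for real data whose columns
may leak or mis-calibrate.  For closed-loop simulation studies the fits
use `baseline_per="none"`, because the generator draws no instrument
offsets and fitting parameters absent from the data-generating process
only destroys precision.

The optimizer is trust-region least squares restarted from a 3×3
log-spaced grid of (K12, K24) starting pairs, keeping the lowest-SSR
solution; per-detector noise SDs are then estimated from the residuals
and one re-weighted pass is run.  Reduced χ² is SSR/(N−p).  Estimates at
a box bound are flagged and clear the `success` field.

**Precision.** Noise-free round trips recover both constants to better
than 0.1 %.  At the reference closed-loop design (single 45 µM cell,
three speeds, two detectors, 1 % of-maximum Gaussian noise) the
per-replicate K12 maximum-likelihood estimate is information-limited with
roughly ±50 % scatter; the median over 20 replicates carries a standard
error near 10 %, so recovery to the 15 % documented tolerance holds in
repeated batches but is not far from the information limit.  K24 medians
land within a few percent.

## Retromobility statistics (`mobility`)

Per-replicate frequency is the His⁺ titre over the viable titre, each
count scaled by its dilution and plated volume.  Fold restriction is the
ratio of mean frequencies (ratio of means, not mean of ratios, matching
how mean frequencies are tabulated).  When a restricted condition yields
no events in any replicate, a single hypothetical event is substituted
into the replicate with the highest viable titre — the most conservative
choice, since it yields the smallest one-event frequency and hence the
largest defensible lower bound is avoided — and the fold is flagged as a
lower bound.  Significance uses the classical equal-variance two-sided
Student's t (Welch available by flag); the degenerate all-constant
equal-means case returns (t, p) = (0, 1).  Gradient peak fractions are
those carrying strictly more than 1/n of the summed densitometric signal
(n = 9 by default), so a perfectly uniform profile has none.

## Sequence conservation (`seqcons`)

Family identity is the percentage of alignment columns in which every
sequence carries the same non-gap residue; any gap disqualifies a column.
This is deliberately strict — with near-full-length families the choice
is low-impact, but it is the stated rule.  Pairwise identity aligns two
sequences globally (BLOSUM62, gap open −10, extend −0.5, Biopython's
`PairwiseAligner`) and applies the same column rule to the two-row
alignment; the built-in aligner replaces an external alignment program,
and for sequences at ≥75 % identity the result is insensitive to the
exact parameters (verified against an exhaustive small-case aligner in
the tests).  Logo heights are R = log₂20 − H per column over non-gap
residues, with no small-sample correction by default (matching common
logo output); the e_n correction is available by flag.  Diagnostic
positions are columns fixed for one residue in one family and a different
residue in the other — the pattern the three Dimer-1 residues show across
the two Ty1 subfamilies.

## Structure comparison (`structcomp`)

Structures are chains of residues in a shared (Gag) numbering; pairing is
by residue number, which for near-identical folds (sub-ångström RMSD) is
equivalent to structural alignment and avoids re-implementing one.
Superposition is the closed-form Kabsch solution with the reflection
excluded by sign-correcting the smallest singular vector; the result is
cross-checked in the tests against an independent rotation-alignment
routine and a brute-force minimiser.  Collinear point sets are rejected
(the in-plane rotation is then undetermined).  Interface contacts list
residue pairs with any inter-chain heavy-atom distance strictly below the
cutoff (default 4.5 Å), computed with a k-d tree and verified against an
all-pairs scan.  This is a contact list, not a buried-surface-area
calculation.

## Synthetic data (`synthetic`)

What the generators emulate, and what they do not:

* **Chromatograms** are sums of Gaussian peaks in time whose areas are
  loading × molar mass (refractive signal tracks mass concentration;
  dn/dc assumed equal across species), plus i.i.d. Gaussian noise.  Real
  SEC peaks are asymmetric (tailing) and real detector noise is
  correlated; θ_res is a ratio of integrals and is insensitive to peak
  shape, which is why Gaussians suffice for exercising the analysis,
  including overlap cancellation.  The retention-time calibration
  t_R = 26.0 − 2.3·log₁₀M min places a 23 kDa dimer near 16 min and a
  42 kDa dimer near 15.4 min, inside the 14–18 min window; the
  heterodimer elutes between its parents by local log-mass
  interpolation.  The molar-mass trace is masked below 5 % of the peak
  maximum, mimicking the noise masking of light-scattering software.
  `resolved_exchange_scenario` narrows the peaks to 0.03 min so all
  three species are baseline-resolved and θ_res = 100·f exactly.
* **Exchange mixtures** place each homodimer at its loading minus the
  material consumed by exchange and the heterodimer at f·(c_A+c_B), so
  total refractive signal is conserved identically (the heterodimer mass
  is the mean of its parents).
* **Equilibrium gradients** come from the exact forward model;
  reference concentrations are solved so the sector-weighted column
  average equals the loading (mass conservation).  The default radial
  grid spans a 0.25 cm solution column (6.90–7.15 cm) at 0.001 cm steps,
  the radial resolution class of modern equilibrium optics.  Noise is
  1 % of each profile's maximum by default.  Time-invariance
  (equilibrium attainment) and baseline/jitter artefacts of real
  acquisitions are not simulated, so closed-loop recoveries demonstrate
  estimator correctness and information content, not robustness to
  instrument drift.
* **Colony counts** are Poisson around the expectations implied by
  frequency, dilution and plated volume.  Plating efficiency and colony
  miscounting are not modelled; the frequency estimator is verified
  unbiased against the generator by Monte Carlo.
* **Sequence families** mutate each site independently and uniformly
  over the 19 alternatives, with designated positions held fixed —
  matching the fixation pattern of the interface residues but not
  phylogenetic correlation between family members (real families share
  ancestry, so their effective n is smaller).
* **Structures** are rigid motions plus isotropic per-atom noise, for
  which the expected post-superposition RMSD is σ√3.

All generators take an integer seed and are exactly reproducible.

## Problem sizes

Default test and reproduction runs use: 4-minute chromatogram windows at
0.25 s sampling; six equilibrium profiles (3 speeds × 2 detectors) of 251
points per simulated cell with 20 replicate noise seeds per recovery
study; quadruplicate platings; families of up to 98 length-97 sequences;
and structures of ≈100–200 Cα atoms.  These match the scale of the
emulated experiments while keeping a full test run within a few minutes
on one CPU.
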