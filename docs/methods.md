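# Methods

This note documents the models, numerical choices and design decisions
behind `nanosorb`, and what the synthetic-data tests do and do not
demonstrate about real data.

## PMF post-processing

A PMF profile is a sampled curve G(Z) (kcal/mol) on a strictly
increasing, approximately uniform grid of adsorbate–surface distances
(canonically 3–15 Å in 0.05 Å bins, the standard output of
adaptive-biasing-force sampling).  Profiles are normalized by
subtracting the mean of G over a far window (default 14–15 Å, ≥ 3 grid
points required); the far value is a plateau, not a single point, so
the window mean is the operational G(Z_far).  Normalization is
idempotent, and a non-fatal warning is emitted when the window's
standard deviation exceeds a configurable tolerance (default
0.25 kcal/mol) — the profile has then not truly plateaued and ΔG and K
inherit that uncertainty.

ΔG_MD is the grid minimum of the normalized profile (ties broken
toward the smallest Z, deterministically).  The equilibrium constant

K = S_A ∫ exp(−G/RT) dZ

is evaluated by the trapezoidal rule on the profile's own grid.  The
molar convention is used throughout (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
T default 300 K); it is mathematically identical to the per-molecule
k·T form since G is a molar energy.  The integrand is accumulated in
log space (log-sum-exp over trapezoid weights), so wells of arbitrary
depth cannot overflow.  Units: S_A (m²/g) ×10⁴ → cm²/g, dZ (Å)
×10⁻⁸ → cm, so K comes out in cm³/g = mL/g.  Integration runs over the
full profile extent; no lower cutoff is applied because exp(−G/RT)
vanishes on the repulsive wall.  Grid-refinement tests show halving the
0.05 Å spacing moves logK by < 0.01 for smooth wells, and the
trapezoidal result agrees with adaptive quadrature of a cubic-spline
interpolant to well within 0.5 %.

The decadic relation logK = −ΔG/2.303RT + logC ties the two
quantities; its theoretical slope at 300 K is −0.73 mol/kcal.  The
conventional printed factor 2.303 is used for this constant and for
the generator's ΔG↔logK link (the Boltzmann integral itself uses exact
log10); the 0.02 % difference from ln 10 is far below all tolerances.
For ensembles of congruent wells the regression of logK on ΔG has
intercept ≈ log10(S_A·w_eff), with w_eff the Boltzmann width of the
well; w_eff ≈ 0.42 Å and S_A = 2400 m²/g give ≈ −1.0.  Empirical
slopes flatten slightly (≈ −0.70) because the flat background of the
profile contributes noticeably to K for shallow wells.

Human-readable reports round logK and ΔG to one decimal; all stored
artifacts keep full precision.

## pp-LFER modeling and validation

Models are ordinary least squares of an endpoint on the Abraham
descriptors plus intercept — (E, S, A, B, L) for gaseous endpoints,
(E, S, A, B, V) for aqueous ones.  The descriptor sets are fixed per
phase; no automated subset search is performed.  Rank-deficient
designs raise an error; variance inflation factors > 10 raise a
warning.  Statistics:

- R²_adj = 1 − (1−R²)(n−1)/(n−p−1); RMSE = √(Σe²/n).
- Q²_LOO = 1 − PRESS/SS_tot with PRESS computed through the exact
  hat-matrix identity e₍ᵢ₎ = eᵢ/(1−hᵢ); the test suite verifies
  equality with an explicit n-refit loop to 1e−10.
- Q²_kfold: mean over repetitions (default 5 folds, 5000 repetitions)
  of the fold-pooled 1 − PRESS/SS_tot on random unstratified
  partitions; the Monte-Carlo spread is reported alongside.
- Q²_ext = 1 − Σ_ext(y−ŷ)²/Σ_ext(y−ȳ_train)², the external variant
  referenced to the training mean; documented and swappable.

The train/validation split is purely random at ratio 4:1
(⌈0.8n⌉/remainder; 41 → 33 + 8), deterministic per seed.  Williams
plots use leverage hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ with the intercept column,
threshold h* = 3(p+1)/n, and residuals standardized by the training
RMSE (not leave-one-out studentized) with a ±3 cutoff — the
conventional applicability-domain choices.

## Decomposition

Two identities hold by construction to machine precision:
ΔG_aq = E_ad − TΔS (E_ad, the DFT adsorption energy, standing in for
the enthalpy) and ΔG_aq = ΔG_H2O + ΔG_gas.  Per-term contributions of
a model are signed fractions — (coefficient·descriptor)/(six-term sum)
per compound, averaged and reported in percent — so negative cells and
intercept shares above 100 % are meaningful; an unsigned |term|/Σ|terms|
convention could not produce them.  Compounds whose denominator is
within 1e−6 of zero are excluded with a warning and counted.
Averaging runs over the training set of the corresponding model.

The aggregate report's four decomposition columns (TΔS, enthalpic
|E_ad|, ΔG_H2O, ΔG_gas) are referenced against a *common* denominator
— the direct aqueous-logK model's prediction — scaled by ±1/(2.303RT).
Self-normalized fractions are scale invariant, so they cannot
distinguish the enthalpic decomposition of logK from the direct
|E_ad| column; the common-denominator form is what makes paired
columns approximately additive (enthalpic + entropic ≈ direct logK,
water + gaseous ≈ direct logK), and the report emits those per-term
consistency diagnostics, which are small but nonzero because each
column comes from its own fit.  The sum row covers the five explicit
descriptor terms and excludes the intercept.

## Synthetic data

The generator's defaults are the study conditions: 41 compounds,
descriptors uniform within E∈[0,3], S∈[0,2], A∈[0,1], B∈[0,1.2],
V∈[0.3,1.8], L∈[1,10], with L coupled to V at Pearson ρ = 0.8 through
a Gaussian copula (normal correlation 2·sin(πρ/6) so the uniform
marginals attain ρ).  Endpoints are exact linear predictions of the
packaged reference models plus Gaussian noise whose standard deviation
is set analytically to √(var_signal·(1−R²)/R²) with target R² = 0.9.
ΔG endpoints invert the decadic link (slope −0.73, intercept −1.0);
the per-compound gaseous advantage is clipped into 1.6–6.1 kcal/mol
(clip events counted), applied to the ΔG columns only so the logK and
|E_ad| columns keep their exact linear structure and the
noiseless-closure contract (exact coefficient recovery) holds.

PMF profiles are a Gaussian well at 4.4 Å plus an exponential
repulsive wall (height 25 kcal/mol at 3 Å, decay 0.25 Å); the well
depth is solved by scalar root finding so the grid minimum equals the
requested ΔG exactly, and the curvature κ = 2πRT/w_eff² is fixed by
the configured thermal width (0.42 Å), keeping wells congruent across
depths.  The functional form is an invention — only the extracted
observables (ΔG, Z_min, K) are contractual.

What passing tests show: the pipeline's algebra, statistics and unit
handling are correct, and parameters of a known generating model are
recovered at nominal CI coverage under realistic spread and
collinearity.  What they do not show: anything about force-field
accuracy, sampling convergence of real PMFs, or how real compounds'
descriptor correlations beyond L–V affect model selection.

## Pipeline

Stages run in a fixed order (simulate → pmf2k → correlate → fit →
decompose → report); each artifact embeds the config hash, every
stochastic stage takes an explicit seed, and reruns with the same
config are byte-identical.  pp-LFER models are fitted on the endpoint
table (the stand-in for MD/DFT results), while the PMF-derived records
feed the logK-vs-ΔG conformance regressions — mirroring how the two
data routes coexist in a real study.  Stage failures abort with the
stage name attached.  Problem sizes in the test suite and acceptance
script (cohorts of 20–41 compounds, k-fold repetitions 100–5000) are
the package's default desk-scale choices.

## Known limitations

- The Q²_ext variant and the k-fold aggregation are conventions; other
  choices (e.g. validation-mean referencing, stratified folds) give
  slightly different numbers.
- Contribution percentages depend on the denominator convention;
  near-cancelling predictions make fractions unstable (hence the ε
  exclusion).
- The generator's uniform-with-copula descriptors do not reproduce any
  specific compound set; absolute endpoint ranges are soft targets.
- No regularized or robust regression; descriptor values are inputs,
  never computed from structure.
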