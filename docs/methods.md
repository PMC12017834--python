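# Methods

This note documents the statistical models implemented in `paleorange`,
their assumptions and tunable parameters, the design choices made where the
problem was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Phylogenetic allometry

Home range Y (km²) is regressed on body mass X (kg) on base-10 log scales.
Base-10 is used throughout because the macropodid coefficients the package
reproduces (slope 1.4, intercept −1.82) only return the published
predictions (3.6 km² at 50 kg, 19.8 km² at 170 kg) in base 10.

Under Brownian-motion (BM) trait evolution the expected covariance of two
tip values is the branch length shared by their root-to-tip paths, so
`bm_covariance` accumulates every edge over the clade below it. The root's
stem edge is excluded: the root state is the origin of the process and a
shared stem would only add a constant to every entry. The GLS estimator is
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y, computed by Cholesky whitening. R² is defined
against the GLS-weighted intercept-only model, which makes the fit reduce
*exactly* to OLS when C = I (tested to 1e-10) and makes R² invariant to
uniform rescaling of branch lengths. F = (n−2)·R²/(1−R²) on (1, n−2)
degrees of freedom. Pagel's λ is fixed at 1 (pure BM); `pgls_fit` accepts
any covariance matrix, so a caller can supply a λ-transformed C if wanted.

Multiple published estimates of one trait are combined by inverse-variance
weighting, Σ(vᵢ/eᵢ²)/Σ(1/eᵢ²). Weighting "in proportion to error" is
ambiguous between 1/e and 1/e²; inverse variance is the statistically
standard reading and the default, with `error_power=1` available.

Predictions exponentiate the fitted line; the interval is the ±z·SE band of
the regression line at log10(mass), propagated from the coefficient
covariance and exponentiated (asymmetric in km²). z defaults to 2,
mirroring the ±2SE convention of the source material. This is a confidence
band for the *mean* home range at that mass, not a prediction interval for
a new species; the residual variance is reported separately for callers who
want the latter.

## Single-grain luminescence

**Central age model (CAM).** Log equivalent doses z_i = ln De_i with
relative errors s_i are modelled as z_i ~ N(δ, σ_OD² + s_i²). The ML
solution uses the standard fixed-point iteration (δ as the precision-
weighted mean, σ_OD from the weighted residuals); near the σ_OD → 0
boundary, where the fixed point contracts slowly, a direct Nelder–Mead
polish finishes the job. SE(δ) = (Σwᵢ)^(−1/2); SE(σ_OD) comes from the
numerical observed information. The fit is verified against a brute-force
(δ, σ_OD) grid search of the likelihood.

**Minimum age model (MAM-3/4).** The truncated-normal mixture in log space
(Galbraith-style): a proportion p of grains sits exactly at the minimum log
dose γ, the rest follow a normal truncated below at γ (MAM-3 ties the
untruncated mean µ to γ; MAM-4 frees it). Before fitting, σ_b (default
0.10, the conventional single-grain overdispersion floor) is added in
quadrature to each grain's relative error; σ_b must match across models
being compared. Optimisation is Nelder–Mead from 8 data-driven quantile
starts with a fixed seed; the best likelihood wins and exact ties resolve
to the smallest γ. Boundary solutions (p → 0 or 1) are flagged.

**Model selection.** The maximum-likelihood comparison between CAM and the
MAMs is a likelihood-ratio χ² test at α = 0.05 on the added parameters,
preferring the simpler model unless the richer one significantly improves
the fit (CAM is treated as nested at p = 1). A raw highest-likelihood mode
with parsimony tie-break is available. On unmixed synthetic data this
selects CAM; on strong mixtures it switches to a MAM.

**Weighted skewness.** Precision-weighted skewness of log De (weights
1/s_i², normalised), compared against c·√(6/n) with c = 2 by default (a 2σ
criterion; c = 1 available).

**Dose rates and ages.** The budget sums beta, gamma, cosmic and internal
components (Gy/ka); σ of the total is the quadrature of component σs.
Moisture attenuation is wet = dry/(1 + k·W) with k = 1.25 (beta) and 1.14
(gamma), W the long-term water content as a fraction of dry mass.
Conversion factors from radionuclide concentrations to dose rates are out
of scope — component dose rates are inputs. The age is De/Ḋ in ka; the
random relative error combines the De and dose-rate relative errors in
quadrature, and a systematic 2% of age (beta-source calibration) is added
in quadrature for the total. Removing the systematic term reproduces plain
quadrature propagation exactly.

**Radial plots.** Coordinates only: x = 1/s_i, y = (z_i − ln ref)/s_i;
grains with |y| ≤ 2 are consistent with the reference dose at 2σ.

## U-series dating

Decay constants default to half-lives of 75.584 ka (²³⁰Th), 245.62 ka
(²³⁴U), 4.4683 Gyr (²³⁸U) and 14.05 Gyr (²³²Th), configurable through
`DecayConstants`.

**Closed system.** a230(t) = 1 − e^(−λ₂₃₀t) + (a234 − 1)·λ₂₃₀/(λ₂₃₀−λ₂₃₄)·
(1 − e^(−(λ₂₃₀−λ₂₃₄)t)) is inverted by Brent root-finding on [1 yr, 50 Myr]
(forward-inverse consistency 1e-10). Uncertainties on both input ratios
propagate linearly via finite-difference sensitivities; the initial
²³⁴U/²³⁸U back-extrapolates the ²³⁴U excess with e^(+λ₂₃₄t). Ratios at or
beyond secular equilibrium raise "no finite age".

**Open system (DAD).** U uptake into a planar enamel slab: ²³⁸U and ²³⁴U
diffuse from both surfaces with a common effective (adsorption-retarded)
diffusivity D, the surfaces held at the ambient-water activities (²³⁸U
normalised to 1, ²³⁴U/²³⁸U = R0); ²³⁰Th is insoluble, does not diffuse, and
grows in locally from the evolving ²³⁴U. The coupled linear PDEs are solved
exactly by expansion in cos((2m+1)πx/2): the ²³⁸U solution is the classical
slab series, the ²³⁴U modes obey first-order ODEs with the ²³⁸U series as
source, and ²³⁰Th is the ingrowth integral of the ²³⁴U solution — all in
closed form. The series is truncated at 50 terms (tail far below 1e-8 at
ka-scale ages); near-degenerate exponential differences use a stable
expm1-style form. The implementation is validated against an independent
Crank–Nicolson finite-difference integration of the same PDEs (agreement
2e-3) and by exact forward→invert round trips.

D defaults to 5×10⁻³ (half-thickness)² per ka, i.e. an uptake timescale of
order 10² ka — profiles at 200–300 ka are near-saturated in ²³⁸U but still
carry curvature in both ratio profiles. D is a model parameter, not fitted:
transect positions are relative (x/L), so D and slab thickness are not
separately identifiable from ratios alone.

**Inversion.** Both ratio profiles are fit jointly (a ²³⁰Th-only mode
exists) by weighted least squares over (age, R0). The forward model is
affine in R0, so R0 is profiled out in closed form and the age is found by
a 1-D grid plus bounded refinement — better conditioned than a 2-D simplex
search. Asymmetric 2σ bounds are the Δχ² = 4 crossings of the profile
objective. Transects whose relative 2σ exceeds 50% are flagged "excluded",
mirroring the treatment of a single anomalous transect in the source
analysis. No detrital-Th correction is applied (²³²Th/²³⁸U is carried
through but not used), matching the source treatment of clean enamel.

**Laser-ablation calibration.** Ratio calibration against a reference
material is a per-ratio multiplicative session factor accepted/measured,
with the factor's standard error propagated in quadrature; concentrations
use single-point linear calibration against a glass standard.

## Sr isotope reduction

Per spot, the chain is: (1) subtract the per-mass mean of the spot's
baseline window (per-spot, not session-wide, so baseline drift between
spots cancels); (2) strip Kr from masses 84 and 86 using the ⁸²Kr monitor
and natural Kr abundances (option: average the ⁸²Kr- and ⁸³Kr-based
predictions); (3) compute the exponential-law mass bias
β = ln(R_canonical/R_measured)/ln(m₈₈/m₈₆) from the Kr-corrected ⁸⁸/⁸⁶ per
cycle, taking the median across cycles to resist low-beam cycles; (4)
remove ⁸⁷Rb from mass 87 by predicting the *measured* Rb ratio,
natural ⁸⁷Rb/⁸⁵Rb·(m₈₇/m₈₅)^(−β) — the sign follows from the β convention,
since corrected = measured·(m_num/m_den)^β; (5) correct ⁸⁷Sr/⁸⁶Sr
internally by (m₈₇/m₈₆)^β and average cycles (2SE from cycle scatter); (6)
bracket against the carbonate standard pinned to modern seawater
⁸⁷Sr/⁸⁶Sr = 0.709182, interpolating the accepted/measured factor linearly
in acquisition order between the nearest standards. The corrected ⁸⁴Sr/⁸⁶Sr
is checked against the natural 0.0565 as a quality flag, and sessions are
judged by the seal-enamel accuracy standard; failing spots are flagged,
never auto-corrected.

The end-to-end invariants: exact recovery (< 5×10⁻⁵, in practice ~1e-9) of
a known ⁸⁷Sr/⁸⁶Sr at zero noise for any (β, Kr, Rb, baseline, drift) in
realistic ranges; no bias above 1×10⁻⁵ over 200 noisy replicates;
invariance to uniform beam scaling; bracketing idempotence.

Group statistics: Welch's t with Satterthwaite df (identical groups return
p = 1 rather than 0/0); Kruskal–Wallis with tie correction plus Dunn's
pairwise z tests on pooled mean ranks, Holm-adjusted by default (raw and
Bonferroni available) — Dunn's p-values are checked against a seeded
permutation null. One-way ANOVA (in `foraging`) is the classical
sums-of-squares decomposition, used on per-tooth mean U-Th ages across
stratigraphic units.

## Baselines and classification

Vegetation samples give per-geological-unit means ± 2SE (SE = sd/√n);
single-sample units get 2SE = 0 and a "range_unknown" flag. A specimen is
classified against the local units in priority order — host limestone
first, then the broader formation; when the caller does not give an order,
local units are tried narrowest-interval first, which is stable under
permutation of baseline rows. The default match criterion is containment
of the specimen's mean ± 2SE inside the unit's interval, following the
"falls within the range of values" logic of the source narrative;
interval-intersection mode is available. Degenerate (zero-width) baselines
are compared by |Δmean| against a tolerance of 3×10⁻⁴ — the scale of the
observed baseline 2SEs. Non-matching specimens are "extra-local" and all
units are ranked by |Δmean|. Widening a local unit's interval can only
move verdicts toward local (monotonicity, tested). Specimen-level means
pool transect means unweighted. No spatial interpolation (isoscape
kriging) is attempted; candidate ranking is purely in ratio space.

`range_geometry` converts a home-range area to the equivalent-circle
radius √(A/π) for map comparison.

## Synthetic data: what it does and does not show

Defaults encode the study conditions: 17 trait species with BM residual
noise tuned to R² ≈ 0.34; grain regimes (n = 40, De ≈ 277 Gy, OD 30%) and
(n = 27, De ≈ 375 Gy, OD 3%) with 32% relative grain errors, which
reproduces the published De standard errors; transect noise of 2% (2σ) over
20 spots, giving age bounds of the observed order at 210–280 ka; Sr
sessions with clam/seal bracketing, β ≈ −1.8, Kr/Rb contamination,
baseline, drift and shot noise. Generators are deterministic given (config,
seed).

Passing recovery tests shows the estimators are correct and approximately
unbiased *under the assumed generating models* — log-normal dose
dispersion, the DAD uptake model with Gaussian ratio noise, linear
instrumental drift. It does not validate those models against real
materials: real De distributions can be partially bleached or mixed in ways
the mixture scenario only sketches; real U uptake can violate the constant
boundary assumption (e.g. U leaching gives unphysical profiles); real
ablation signals have time-structured matrix effects that a linear drift
does not capture. The published summary tables bundled as the `mt_etna`
fixture contain only published numbers and are used as inputs for
desk-scale checks, never as evidence of fit quality.

## Numerical choices

- PGLS: Cholesky whitening; singular covariance raises rather than
  regularises.
- CAM fixed point: tolerance 1e-10, 2000 iterations, Nelder–Mead fallback.
- MAM: 8 multistarts, Nelder–Mead xatol 1e-8; SE from numerical Hessian
  with a dispersion-based fallback (flagged).
- Closed-system solve: Brent on [1 yr, 50 Myr], rtol 1e-14.
- DAD series: 50 terms (80 in the oracle test); stable exponential
  differences; inversion grid 60 points geometric on [1, 2000] ka, bounded
  refinement xatol 1e-4 ka, Δχ² = 4 bounds by Brent.
- Sr reduction: β median across cycles; negative corrected beams flagged,
  not clipped.
- Classification: zero-width intervals detected at 1e-10 absolute.

## Known limitations

- The MAM overdispersion SE is not reported (the minimum dose SE is);
  profile-likelihood intervals for MAM parameters are future work.
- The DAD model is planar with symmetric boundaries only; cylindrical
  geometry and U-leaching scenarios are out of scope.
- The Sr reduction assumes interference-free monitor beams (⁸²Kr, ⁸⁵Rb)
  and natural interference compositions.
- Classification treats baseline units as points/intervals in ratio space;
  it knows nothing about geography, so "nearest candidate unit" is an
  isotopic, not spatial, statement.
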