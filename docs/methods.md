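# Methods

## Measurement model

All density measurements are areas under a wide-line intensity profile.
For a drawn segment the image is sampled at 1 px steps along the segment
axis; at each step, bilinear samples are taken along the perpendicular at
0.1 px spacing across the configured width and averaged. The profile AUC is
the trapezoidal integral of those averages over position. Positions (and
hence AUC units) are in millimetres whenever the image carries pixel
spacing, in pixels otherwise; the unit is recorded on every output record.

Region conventions:

* tibiotarsal density — axis = the operator's line across the mid-shaft
  (length = drawn bone width), profile width 100 px. The measure therefore
  deliberately scales with bone width; a width-normalised variant
  (AUC / line length) is available behind `width_normalized=True` but is not
  the default, because the bone-width contribution is part of the measure's
  definition.
* keel density — axis = 10 mm from the anchor point along the dragged
  direction across the pila carinae, width 25 px. The cranial site is used
  because it is rarely fractured, so the value is not inflated by callus
  mineralisation. A missing pixel spacing makes the 10 mm length
  unrealisable and is an error unless a fallback spacing is configured.

Background correction subtracts (median intensity of a user-designated
off-bone rectangle) × (profile axis length) from the raw AUC, clamped at
zero. The median is robust to bone spill-over at the rectangle edge; a
uniform haze pedestal cancels exactly, which the phantom tests verify to
within 1 %.

Keel length is the arc length of a natural cubic spline interpolating the
clicked points from the pila carinae to the keel tip, parameterised by
cumulative chord length with arc length evaluated by 1000-segment
quadrature. The spline midpoint is the point at half arc length; a warning
fires when the annotated mid-depth line passes more than 10 px from it.
Mid-depth and cranial depth are plain Euclidean lengths of their annotation
lines, and `xlm` = length / mid-depth. At week 16 the keel is not fully
ossified, so length refers to the ossified portion; week-16 records carry
an `ossified_only` flag.

Photometric convention: images are canonicalised on load so that denser
tissue is brighter (MONOCHROME1-style sources are inverted); the
normalisation is idempotent. Coordinates are 0-based with x = column,
y = row, continuous positions at pixel centres.

## Scoring model

The keel is divided into cranial, middle and caudal thirds. Localization
codes 0–7 enumerate the subsets of affected thirds; the extent score is the
subset size (0–3). Deviation size is {0, < 0.5 cm, ≥ 0.5 cm}; callus size
{none, minimal, moderate-severe}; the fracture count is 0–4 with 4 meaning
"at or above four", stored as the count plus a censored flag that the
censored-Poisson likelihood consumes. Headline damage prevalence counts
birds with any deviation or fracture; callus is tabulated separately.
Scorer identity (`operator`) is a mandatory covariate since every
regression adjusts for it.

## Latent-normal correlations

Ordinal scores are modelled as thresholded versions of underlying normal
variables. The polychoric correlation maximises the multinomial likelihood
of the contingency table over (ρ, both threshold vectors) in one stage;
cell probabilities are rectangle sums of the bivariate normal CDF, which is
evaluated through the exact Owen's-T decomposition (absolute error below
1e-7; exact zeros in the arguments are nudged by 1e-13, a perturbation far
below that tolerance). The polyserial likelihood multiplies the normal
density of the standardised continuous variable by the conditional
probability of the observed ordinal interval; μ, σ, thresholds and ρ are
estimated jointly. Standard errors come from the inverse observed
information (central-difference Hessian) at the optimum, with ρ optimised
through an atanh transform. Estimates with |ρ| ≥ 0.9999 are clamped and
flagged `at_boundary` with an undefined SE. A two-step variant (thresholds
fixed at marginal quantiles) exists for cross-checking; tests compare the
2×2 case against an independent likelihood grid search.

Cross-age matrices use Pearson r with SE = √((1 − r²)/(n − 2)) on
pairwise-complete birds, at least 3 pairs per cell. Live and post-mortem
timepoints share one matrix by default — correlations are scale-free, so
the re-calibration of the machine between live and post-mortem imaging
shifts means but not r; `pool_live_postmortem=False` restricts to live ages
when means would otherwise be compared.

Group comparisons of the length:mid-depth ratio use one-way ANOVA plus
Tukey HSD at α = 0.05; the compact-letter display labels the maximal
cliques of the "not significantly different" graph, so two groups share a
letter exactly when no significant difference separates them. Groups with
fewer than two observations are excluded with a warning.

## Regression models

The damage model regresses a dissected-keel response on operator
(treatment-coded, reference = first level alphabetically), tibiotarsal
density, keel density, `xlm` and body weight, separately per age. Equally
spaced ordinal responses use OLS; binary responses use ML logistic
regression (perfect separation is flagged, with coefficients reported from
a BFGS fit when the Newton Hessian is singular); fracture counts use a
right-censored Poisson likelihood with log link,

    logL = Σ_uncensored [y log λ − λ − log y!] + Σ_censored log P(Y ≥ c; λ),

maximised by BFGS with the analytic gradient (the censored score term is
λ·pmf(c−1; λ)/P(Y ≥ c)); Wald SEs come from the numerically observed
information. With no censored flags this reproduces ordinary Poisson
regression to machine precision, which a statsmodels GLM cross-check
verifies.

The pelvic model adds the pelvic × tibiotarsal interaction. Pelvic
dimensions correlate ≈ 0.65 with body weight, so each is first
residualised on body weight by OLS and re-centred at its original mean;
only residualisation is applied (body weight is not additionally entered
as a covariate). Pelvic capacity must equal width × depth, enforced at
validation. No multiple-testing correction is applied across ages or
responses (each model is reported per se); a Benjamini–Hochberg helper is
available but off by default.

## Synthetic data

**Phantoms.** Attenuation is additive (no Beer–Lambert exponentiation)
because all measurements are linear in intensity: a vertical uniform band
(tibiotarsal-like), a constant-half-width band around a circular arc
(keel-like — its centreline arc length is R·Δθ in closed form) and a
uniform cranial block for the keel-density line, plus a uniform haze
pedestal and i.i.d. Gaussian noise. The returned annotation places every
measurement region strictly inside a uniform area, so the analytic truths
(level × line length for densities, R·Δθ for the spline) are exact.
Defaults: 400 × 400 px at 0.2 mm/px, bone levels 120/80/60 a.u., arc radius
220 px over 45°, mid-depth = arc length / 5 (so the true `xlm` is exactly
5). Identical seeds give bit-identical images; DICOM output rounds to
uint16 and clamps negative noise excursions at the detector floor.

**Flocks.** Each bird draws a 10-dimensional latent normal over
{keel density, tibiotarsal density, xlm, body weight, pelvic width, pelvic
depth, deviation liability, fracture liability, callus liability, keel
length}. Generator defaults are the study conditions and are fixed, not
tuning knobs:

* deviation size thresholds at cumulative (0.25, 0.54) and extent
  thresholds at (0.25, 0.55, 0.82), reproducing the observed marginal
  frequencies; sharing the first threshold makes "extent > 0 iff size > 0"
  hold by construction. The localization code is then drawn uniformly
  among the codes of that extent.
* fracture counts are Poisson with log λ = a + 0.35·Z_frac, right-censored
  at 4. The intercept a is solved (1-D quadrature + bisection) so that
  P(count = 0) = 0.135, the value of a plain Poisson with mean 2; the
  resulting marginal is close to the observed count distribution, though
  the liability mixing unavoidably thickens the "≥ 4" tail relative to a
  pure Poisson(2) (≈ 0.21 vs 0.15). Matching the zero cell exactly was
  preferred because damage presence drives the prevalence and
  co-frequency targets.
* the deviation–fracture latent correlation is calibrated (quadrature +
  Brent root-finding) so that P(deviation > 0 and fracture > 0) = 0.67,
  the observed co-occurrence; with the marginals above this lands near
  r ≈ 0.72 and yields ≈ 95 % overall damage prevalence.
* callus occurs only on fractured keels (a callus is healed fracture
  tissue; the observed fracture–callus co-occurrence equals the callus
  prevalence, implying the nesting). Conditional size categories cut the
  callus liability of fractured birds at its empirical quantiles chosen to
  reproduce the marginal (0.17, 0.41, 0.42).
* pelvic width ~ N(40.43, 5.30²) mm and depth ~ N(71.92, 10.38²) mm, each
  with latent correlation 0.65 to body weight; capacity = width × depth.
* longitudinal measurements follow mean trajectories (tibiotarsal density
  rising with age, `xlm` low at week 16 while the keel is incompletely
  ossified) plus √w·(persistent bird effect) + √(1−w)·AR(1) noise, with
  w = 0.6 and AR persistence 0.5, giving adjacent-age correlations near
  0.8 as observed for keel density. Setting w = 0 recovers a pure AR(1)
  for closed-form tests.
* dissected keel length is N(10, 0.8²) cm and mid-depth =
  length / (5·exp(0.12·Z_xlm)), which makes the length:mid-depth ratio
  centre on 5 and correlate strongly negatively with mid-depth.

What the generator does **not** emulate: real radiographic texture
(muscle, feather superimposition), operator drawing bias (only isotropic
keypoint jitter is modelled in the reproducibility harness), inter-machine
calibration offsets beyond a mean shift, and any non-normal latent
structure. Passing tests therefore demonstrate the correctness of the
measurement and estimation machinery under the stated model, not the
field performance of the measurement protocol.

## Pipeline

`merge_clean` inner-joins measurements, scores and pelvic dimensions on
bird ID, rejects duplicate IDs, and (in strict mode) drops birds with any
missing required value, logging every exclusion with a reason. Analysis
is otherwise scoped per model (a bird missing only week-16 data still
enters week-42 models) via per-fit dropna. `run_all` is a pure function of
(input sheet, config, seed): outputs are byte-identical across repeated
runs, any stage failure removes partial outputs, and the manifest records
seed, input, retained/excluded counts and the files written.

## Problem sizes and numerical choices

Default verification scales: 50-phantom batches for measurement recovery;
n = 5,000–10,000 simulated birds for frequency and correlation recovery;
hundreds of replicates at n ≈ 300–1,000 for regression coverage — sizes at
which the targeted tolerances (2 % geometry, 1 % density, 0.03 on latent
correlations, 0.1 on the censored rate) sit several standard errors wide
of their Monte-Carlo noise. Optimisations use L-BFGS-B/BFGS with an atanh
transform for correlations and log-spacing transforms for thresholds;
likelihood cells are floored at 1e-300 before logs; 2-SE Wald coverage is
checked against its nominal ≈ 95.4 % rate (93–97 % band in unit tests).

## Limitations

The tibiotarsal density confounds mineralisation with bone width by
design; use the width-normalised variant when a width-free proxy is
needed. The polychoric SE is a curvature estimate and degrades near the
|ρ| boundary, where estimates are flagged instead. The censored-Poisson
model treats the "≥ four" category as exact right-censoring; heavier
truncation schemes are out of scope, as are mixed-effects models across
ages and proportional-odds regression for ordinal responses. An aluminum
step-wedge calibration converting optical density to aluminum equivalents
is recommended practice but outside this package's scope.
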