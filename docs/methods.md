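# Methods

This note records the statistical model behind `morphodisc`, the
conventions and numerical choices the implementation commits to, what the
synthetic generator does and does not emulate, and the known limitations.

## The comparison being made

The scientific question is whether apparent taxonomic separation in
morphometric data survives the removal of size. Linear measurement
protocols are compact but entangle size with shape (many measurements share
axes, so size is redundant and dominant); full landmark configurations are
high-dimensional but come with an explicit size/shape decomposition. The
package therefore evaluates every measurement scheme under three size
treatments — raw, isometry-free, allometry-free — with an identical
classification rule, so differences in performance are attributable to the
data representation, not the classifier.

## Superimposition

Generalized Procrustes analysis centres every configuration, optionally
rescales it to unit centroid size (CS = √Σ‖xᵢ − x̄‖²), and iteratively
rotates each specimen onto the consensus until the summed squared deviation
from the mean shape stops decreasing (relative tolerance 1e−10, max 100
iterations; typical convergence is 3–6 iterations). Conventions:

* **Partial vs. full.** `scale=False` (translation + rotation only) yields
  *form* — the raw landmark treatment. `scale=True` pre-scales specimens to
  unit CS; no scale factor is re-optimised inside the rotation step
  (fixed unit-size scaling, the dominant convention in the geometric
  morphometrics ecosystem). The choice is an explicit switch.
* **Reflections are never allowed** (the smallest singular value is
  sign-corrected): crania have fixed chirality.
* **Output orientation** is the consensus' principal axes. Axis signs are
  chosen so landmark loadings have positive skewness (fallback: first
  nonzero loading positive); the third axis is the cross product of the
  first two so the map stays a proper rotation. This makes results
  invariant to specimen order and to rigid motion of the input.
* `procrustes_ss` is measured against the mean shape (the quantity the
  iteration minimizes), not its unit-renormalized version; for two
  specimens it equals half the pairwise Procrustes residual exactly.
* Monotonicity of the SS is asserted every iteration at runtime.

New (unidentified) specimens are aligned to the *frozen* training
consensus; the training shape space is never re-estimated.

## Size treatments

Linear distances are measured on the original coordinates (rigid-motion
invariance makes alignment irrelevant and keeps distances independent of
superimposition settings). Bilateral averaging happens only where a
protocol explicitly declares a mirror index pair. Isometry-free linear
variables are Mosimann log-shape ratios log₁₀(x/GM); each row then sums to
zero and is invariant to per-specimen rescaling. The allometric regression
consumes isometry-free tables for both data types (shape on ln CS; ratios
on ln GM) — regressing raw distances instead would conflate isometric and
allometric size, and the landmark analogue (Procrustes shape on ln CS)
fixes the convention. The raw-distance option remains available by
constructing the fit by hand, but the pipeline default is deliberate.

## Allometry and its permutation test

The fit is ordinary least squares with a single covariate and a
multivariate response; sums of squares are pooled over variables.
Goodall's F uses df 1 and n − 2. The permutation test is residual
randomization under the reduced model; with an intercept-only reduced model
that is exactly a row permutation of the centred responses against the
covariate, which is how it is implemented (vectorized over permutations).
The p-value uses the add-one convention (1 + #{F* ≥ F}) / (1 + n_perm), so
p is never 0 and its floor at 1000 permutations is 1/1001 ≈ 0.001. A
perfect fit reports F = ∞ rather than dividing by zero. Allometry-free
tables are the residuals, with feature means added back for
interpretability (PCA re-centres, so downstream results are unchanged).

`permutation_null_check` builds its null replicates by re-permuting the
size covariate of a zero-allometry table — an exact null — and compares the
rejection rate at α to the central 99% binomial interval.

## Ordination and classification

PCA is an economy SVD of the centred (never correlation-standardized)
table; covariance uses the n − 1 denominator; components below 1e−12 of the
leading eigenvalue are treated as numerically null; signs follow the
largest-magnitude loading. Truncation keeps the smallest k whose cumulative
variance fraction reaches the threshold (default 0.95).

LDA uses class means with a pooled within-class covariance (divisor n − K,
matching the R MASS/klaR toolchain) and equal priors by default. Posteriors
come from Bayes' rule on the Gaussian discriminant; a near-singular pooled
covariance (condition number > 1e12) receives a ridge of 1e−8·trace/d with
a loud warning. Discriminant axes for plotting are eigenvectors of W⁻¹B
computed through the symmetric whitened form for stability.

Leave-one-out cross validation refits only the LDA per fold; **the PC space
is computed once on the full sample**. This mirrors standard practice in
morphometric LDA-on-PC-scores studies and keeps every fold in the same
coordinate system, but it leaks a small amount of information relative to
refitting the PCA per fold — honest out-of-sample error would be somewhat
worse, and the measures here should be read as comparative, not absolute.

The membership measures, for an n × K posterior matrix m, truths t and
assignments a = argmax (ties toward the lowest class index):

* CR = mean(aᵢ = tᵢ)
* AC = 1 − K/(K−1) · mean‖mᵢ − e_{tᵢ}‖²
* AS = 1 − K/(K−1) · mean‖mᵢ − e_{aᵢ}‖²
* CF = mean mᵢ[aᵢ], also averaged within each true class.

The K/(K−1) normalization pins a uniform-membership classifier at 0 and a
perfect one at 1. Note AC and AS can go negative for confidently wrong
memberships — that is informative, not a bug.

## Protocol coverage

Cross-protocol measurement identity is expert judgement, so
`protocol_overlap` takes an explicit synonym pair list rather than doing
string matching. Coverage of protocol B by protocol A is
100 · |B-measurements with an equivalent in A| / |B|. Pairs may be
many-to-many, which is what makes the coverage matrix genuinely
asymmetric beyond the denominator difference.

## Synthetic data

The generator emulates: a shared base mean shape (deterministic Fibonacci
sphere at unit CS — reproducible and non-degenerate); per-group unit-norm
offset directions (scaled by δ_g); one common allometric direction moving
shape by β per unit log size; group-specific log-normal sizes; iid Gaussian
noise per coordinate (σ_e); and uniform random rotation + translation of
each emitted configuration. Directions are orthogonalized against uniform
translations and recorded in a truth record together with the realized log
sizes and pre-motion shapes, so oracle computations (e.g. the generative
allometric R²) never touch the superimposition code. One RNG stream per
call; the motion draws are consumed even when rigid motion is disabled so
the same seed yields the same shapes either way.

`study_spec()` fixes the sample design at the motivating study's: three
groups of 68/30/38 identified specimens plus 32 unknowns, 412 landmarks.
Effect sizes are reported nowhere, so they were fixed once at plausible
values: mean log sizes 3.42/3.36/3.39 (centroid sizes ~29–31 units, a few
percent apart between groups), within-group size SD 0.05, offset scales
0.006–0.008 (a few times the landmark noise σ_e = 0.002, i.e. subtle),
β = 0.5 — which puts the allometric share of shape variance on the order of
a tenth, the regime the method is designed to probe.

What the generator does **not** emulate: spatially correlated landmark
noise and morphological integration. Real cranial variation concentrates in
a few directions, so real datasets need comparatively few PCs for 95%
variance; iid noise spreads variance across all dimensions, so the
synthetic landmark tables retain many more PCs and their LDA operates
closer to its degrees-of-freedom limit (lower CR) than a comparable real
sample. Passing tests therefore validate the machinery and its
calibration, not the absolute performance levels one would see on real
crania. Semilandmark sliding, measurement error models and sexual
dimorphism are likewise out of scope.

## Problem sizes used in the checks

The statistical test suite uses: 200 null replicates × 199 permutations for
type-I calibration; n = 150 balanced specimens for the chance-level LOOCV
band; 8 replicate datasets (120 specimens × 50 landmarks) for allometric-R²
recovery against the truth-record oracle; and one full grid at the
study-scale design (168 specimens × 412 landmarks, 199 permutations). The
acceptance script runs the same grid with 1000 permutations. These sizes
give stable Monte-Carlo bands while keeping a full run in seconds.

## Known limitations

* LOOCV leaves the PCA (and the allometric regression) fitted on the full
  sample — see above.
* The GPA tangent-space approximation is implicit: PCA operates on aligned
  coordinates, adequate for the small shape variation simulated here.
* No missing-landmark estimation, semilandmark sliding, weighted GPA, or
  group-specific allometric slopes (homogeneity of slopes is assumed, as
  the allometry-free treatment only removes a common slope).
* TPS support is 3D-only (`LM3=`); 2D files are rejected by design.
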