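# Methods

This note records the models, the generator's design, the numerical
choices, and the known limits of what the test suite demonstrates.

## Analysis chain

**Confound correction.** Every ROI density column is residualized by
ordinary least squares on an intercept plus the chosen covariates (default
age, gender as a 0/1 dummy with female as reference, and intracranial
volume; total GM volume is accepted as an alternative covariate set).
Residuals are exactly orthogonal to the numeric covariates and mean-zero
per ROI; residualizing twice changes nothing. Constant covariates are
dropped with a warning; exactly collinear pairs are an error naming both.
The total-volume group test is an extra-sum-of-squares ANCOVA (full model
with group dummies vs covariates only) with planned patient-vs-healthy
contrasts reported unadjusted (a Holm flag exists).

**Regional statistics.** One-way ANOVA per ROI on corrected densities;
family-wise error controlled by Holm's step-down procedure. An ROI with
zero within-group variance reports F = +∞, p = 0, with a warning rather
than failing the whole table. Discriminative-ROI selection is by an F
threshold (default 2.7) or top-k, descending F, ties broken by ROI order.
The chronicity median split assigns subjects exactly at the median to
"short" so the partition is reproducible.

**Covariance networks.** Structural covariance is the Pearson correlation
of corrected densities between ROI pairs across a group's subjects.
Distance fits regress the upper-triangle within-hemisphere pairs (left
hemisphere by default, signed correlations by default; absolute values are
an option) on centroid Euclidean distance; the fit R is reported as a
magnitude with the raw slope sign separate, since a decreasing relation is
conventionally quoted with positive R. Slopes are compared across groups
by a pooled regression with a group × distance interaction term. Distance
bins are half-open and lower-inclusive ([k·25, (k+1)·25) mm) so every pair
lands in exactly one bin; `n_bins=None` extends the bins to cover the
observed range (the synthetic whole-brain range exceeds the 150 mm that
six bins cover). Seed-ROI connection maps keep partners with r above a
threshold (default 0.6) and Holm-adjusted correlation-test p < 0.05 at the
group's n.

**Barcodes.** A profile's z-score uses its own across-ROI mean and SD
(ddof = 1); constant profiles are an error. Ternarization at ±θ maps
|z| = θ to 0. The threshold scan computes, per θ on a 0–2.5 grid (step
0.01), the sum of pairwise Pearson correlations between group barcodes
(sumR) and the joint Shannon entropy (bits) of the per-ROI group-symbol
tuples; θ* minimizes sumR among θ whose entropy is within 5 % of the
maximum (ties: higher entropy, then smaller θ). θ values that produce a
zero-variance barcode are excluded with a warning; if all groups'
barcodes are identical and non-degenerate, sumR is the pair count and the
entropy maximizer wins. Classification is by the highest Pearson
correlation of the subject barcode with the group barcodes, ties broken by
the fixed order healthy, CBP, CRPS, OA and flagged. Restricting to an ROI
subset reuses the whole-profile z-score by default (a renormalize flag
recomputes it on the subset). Subsample validation draws n ∈ {5, 10}
training subjects per group, builds anchors from their mean profiles
(θ fixed by default; optionally re-optimized on the training means), and
scores only held-out subjects, over 10 iterations.

**Embedding and chronicity.** Anchors sit at 90°, 210°, 330° on the unit
circle (CBP, CRPS, OA) with the healthy center at the origin — the
centroid of the equilateral triangle. Any similarity transform of the
frame gives an equivalent analysis, so the unit layout is canonical here.
A subject's position is the d-weighted mean of the anchors with
d = (r + 1)/2. Δd is the Euclidean distance from the mean location of the
embedded healthy subjects (the depth median is available as an option).
The bagplot computes exact 2-D Tukey halfspace depth by evaluating the
halfplane count just past every critical direction (perpendiculars of
point-to-point vectors); the median is the deepest point (centroid of the
deepest set on ties), the bag the convex hull of the deepest ⌈n/2⌉
points, the fence the bag inflated 3× about the median; collinear clouds
are flagged degenerate rather than given a sham polygon. The exponential
fit initializes τ on a 120-point log grid (solving the then-linear
(Δd₀, Δd₁) subproblem exactly at each τ), refines by bounded
Levenberg–Marquardt/TRF with τ > 0, takes standard errors from the fit
curvature, and reports fit R as the correlation of observed versus fitted
values plus an F-style comparison against a straight line — for durations
far below τ the two are indistinguishable by construction. Time constants
are compared by t = (τ_A − τ_B)/√(SE_A² + SE_B²) with Welch–Satterthwaite
degrees of freedom on (n − 3) per fit; this is offered as a pragmatic
test, not as the uniquely correct one.

## The synthetic cohort generator

The generator emulates the features the analyses consume; parameters and
defaults (see `SimulationConfig`):

* **Demographics.** Group sizes 46/36/28/20 (healthy/CBP/CRPS/OA; the OA
  size is configurable), group-specific age distributions (means 38.8 to
  53.5 yr) and female fractions, ICV ~ N(1450, 120) cm³.
* **Total volume.** 590 cm³ at age 40, declining at per-group slopes of
  −2.01 / −2.43 / −2.15 / −3.00 cm³/yr, with ICV coupling (0.15 cm³/cm³),
  an optional gender offset (default 0), and N(0, 20 cm³) noise.
* **Durations and scores.** Pain durations log-uniform on [0.25, 42] yr;
  pain intensity, BDI (capped at 19 — higher scores are an exclusion
  criterion), BAI and medication scores drawn independently of duration,
  so deviation–intensity correlations are genuinely null.
* **Density signatures.** Four dense pattern vectors with pairwise
  correlation −1/3 are built from three orthonormal mean-zero basis
  vectors and tetrahedron vertex weights. The centered group deviations
  are scaled inversely to group share, which makes the size-weighted
  grand-mean centering (what confound correction effectively applies)
  leave all six pairwise group-profile correlations at −1/3 in
  expectation — the mutually negative barcode regime the classifier
  assumes. Signature scale κ = 0.0045 density units.
* **Expression dynamics.** A patient's signature is expressed at
  offset + amplitude · (1 − exp(−t/τ)): offset 0.4 (deviation already
  present at short durations — the analogue of a nonzero Δd₀), amplitudes
  0.8 / 0.4 / 0.6 for CBP / CRPS / OA (CBP twice CRPS: reorganization
  twice as large and ~6× slower in CBP), τ = 11.72 / 1.71 / 6.0 yr. The
  OA τ is a chosen intermediate value: in the source regime OA is
  reported as between the other two, with exponential and linear fits
  indistinguishable. Signatures are normalized by the expected expression
  (computed by quadrature over the duration distribution) so the mean
  geometry holds at the cohort's mean chronicity.
* **Noise.** Per-ROI density noise SD 0.05 with exponential spatial
  correlation exp(−D/ℓ), ℓ = 15 mm, plus a constant shared factor with
  per-group gain (0 healthy, 0.5–0.6 patients) that lifts long-range
  (>100 mm) inter-ROI correlations in patients; the mixture is normalized
  to unit diagonal, and its exactness (PSD) is checked with an explicit
  error naming the offending parameters. Densities are clipped into
  (0, 1); clip events are counted and logged (rare at defaults).

The κ/noise/ℓ balance is deliberate: the ternary readout keeps amplitude
information only while per-ROI signatures are within roughly one noise SD —
stronger signal saturates the barcode, which would compress the apparent
time constant of Δd severalfold. The chosen scale keeps the expression
range inside the linear window at the cost of moderate per-subject
classification signal (mean sensitivity ≈ 90 % rather than ≈ 100 %).

**What the generator does not emulate:** spatially smooth signature
topographies (patterns are dense random vectors, not contiguous cortical
clusters), hemispheric asymmetries, heavy-tailed or subject-specific noise,
scanner/site effects, medication effects on GM, and any voxel-level
structure. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it targets, not that real cohorts carry that
structure.

## Test and acceptance problem sizes

Oracle-equivalence checks use ≥100 random small instances per operation at
1e−8. Calibration uses 500 null simulations for the ANOVA and ANCOVA
type-I error and 200 for the Holm family-wise error over 82 ROIs.
Structure recovery uses 50 healthy replicates (slope detection) and 20
two-group replicates (long-range bins). Classification and end-to-end
chronicity use 20 replicate cohorts in the test suite and 10 in the
acceptance script; direct-fit recovery uses 100 replicates per τ. These
sizes keep the default suite around two minutes while leaving the binomial
margins of the rate assertions comfortable.

## Known limitations

* End-to-end τ recovery through barcodes is noise-limited: a matched
  ideal estimator (linear readout, same Δd noise, same n, log-uniform
  durations) already shows an interquartile τ range of roughly half to
  double the truth at n = 36, and its median over 20 cohorts misses a
  ±25 % band in a substantial fraction of draws. The pipeline tracks this
  limit; medians typically land within 10–45 % of the generator values,
  and the corresponding suite assertion can legitimately fail on some
  seeds.
* The healthy distance-decay R is modest (~0.1–0.2) at the default
  ℓ = 15 mm; the decay is reliably *detected*, but the tight linear
  relation a long correlation length would produce was traded away for a
  less spatially correlated noise floor (which the barcode readout
  needs).
* Exact Tukey depth is O(n² log n)-ish per cloud via direction
  enumeration — fine for cohort-sized clouds (hundreds of points), not for
  tens of thousands.
* The slope-comparison and τ-comparison tests are pragmatic constructions
  (interaction term; SE-based Welch t); they are validated against their
  own definitions, not against an external standard.
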