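# Methods notes

## Imaging model and phantoms

A phantom is a 3D grid of 16-bit grey levels at isotropic spacing
(default 0.141 mm, the voxel pitch of the scanner setting the package's
conventions). Two grey populations are modelled: soil background (mean
2000) and tuber material (mean 3400), both with Gaussian noise (default
sd 50). Tubers are ellipsoids, optionally rotated about the vertical
axis; membership is decided at voxel centers with no partial-volume
weighting, deliberately matching the whole-voxel counting estimator the
package validates. Ground truth is recorded before degradation: the
label mask, the voxel-center count, and the closed-form volume
4/3·π·a·b·c·(Δx/10)³ cm³. The mean image is then blurred
(`blur_sigma`, emulating partial-volume mixing and detector blur) and
noise is added. Overlapping tubers are rejected rather than merged —
tubers are discrete organs and a merged ground truth would be ambiguous.

A per-slice parallel-beam simulator (`project_and_reconstruct`) computes
a sinogram at evenly spaced angles and reconstructs with ramp-filtered
back-projection. It exists to produce realistic reconstruction artifacts
(ringing, streaks) for robustness tests; it is not a cone-beam model and
makes no claim about scanner geometry.

What the phantoms do **not** emulate: beam hardening, scatter, soil
heterogeneity (stones, moisture gradients), roots and stolons touching
tubers, or grey-level drift between scans. Tests passing on phantoms
therefore demonstrate the correctness of the estimator chain, not
field-readiness on arbitrary soils.

## Segmentation and volumetry

Voxels inside the inclusive window [T_low, T_high] are foreground. The
default bounds 2938/3963 are the historical values for tubers in soil on
the 16-bit scale. Bounds are inclusive ("lower and upper threshold"
semantics); strictness was an open choice and inclusive keeps
`lower == upper` meaningful. Components are labelled with
26-connectivity (compact blobs; 6-connectivity available), and
components below `min_voxels` (default 64) are dropped as speckle.
Remaining errors are handled the way the original workflow handled them:
manual correction, here as ordered add/remove box or sphere `MaskEdit`s
with the component table recomputed afterwards. Touching tubers are not
split algorithmically; an edit separates them.

One subtlety matters for blurred data: a fixed window is unbiased only
when its lower bound sits at the half-maximum of the blurred edge. For
the default phantom populations that midpoint is 2700, not 2938; the
historical bounds encode the original scanner's histogram, not a
universal constant. The acceptance campaigns on blurred phantoms
therefore use a window with lower bound 2700 — the histogram-derived
analogue of how the original bounds were chosen — while noise-only tests
keep the defaults. With this, a 17-tuber campaign spanning 0.5–50 cm³
(blur 1 voxel, noise sd 50) reaches Pearson r ≈ 1.0 against analytic
truth with ~1% median volume error; the discretization error of
noise-free spheres with radius ≥ 15 voxels is well below 2%.

Volumes are whole-voxel counts times (spacing/10)³; units are fixed
project-wide as mm for spacing and cm³ for volumes. Tracking across
scans is greedy nearest-centroid matching under a displacement bound —
adequate for slowly growing, well-separated organs, and checked against
an exhaustive assignment oracle on two-object instances; it is not a
general multi-object tracker.

## Growth kinetics

Velocity is the OLS slope of volume on time (endpoint difference
available behind a flag; both coincide at two scans). No smoothing or
outlier rejection is applied — a bad scan should be visible, not
silently absorbed. "Growing" has no canonical numerical definition
("virtually stopped" is the qualitative notion), so the classifier uses
a dual rule, growing iff `v > 0.1 cm³/day` or `v > 0.01/day × mean
volume`, both thresholds surfaced in configuration. The OR-rule is
evaluated literally; a 0.05 cm³/day tuber of mean 10 cm³ is *not*
growing under the defaults (regression-tested edge).

## Expression pipeline

**Normalization.** (1) floor at 5, (2) per-chip division by the
post-floor 50th percentile, (3) per-feature division by the median
across the dataset of the run. "Dataset" scoping is per matrix passed
in; when experiments are analysed jointly the caller concatenates first,
and the provenance of every `NormalizedMatrix` records floor, percentile
and the sample set used. The output's per-feature median is 1 by
construction and the pipeline is invariant to positive per-chip scaling
whenever no value crosses the floor.

**Volcano selection.** Fold change is orientation-free
(`max(μ_A/μ_B, μ_B/μ_A)` of normalized means, so swapping the pair
changes nothing) and the p-value is a two-sided t-test on log₂ values.
The variance assumption deserves a note: at two replicates per
condition, Welch's Satterthwaite approximation can drop the degrees of
freedom toward 1, where the critical t exceeds 12 and no realistic
4-fold effect is detectable; the pooled-variance Student t (df =
n₁+n₂−2) is both the array-era volcano convention and the only usable
test at these sizes, so it is the default, with Welch available via
`equal_var=False`. Benjamini–Hochberg correction (statsmodels, verified
in tests against an exhaustive step-up oracle) is applied exactly when
the experiment's design carries ≥ 4 replicates per condition, encoding
the per-experiment correction policy as a property of the design rather
than a hidden switch. Multi-condition experiments need an explicit
contrast pair; an "extreme pair" convenience mode (max-mean vs min-mean
condition) exists and the chosen pair is recorded in the result
attributes.

**Intersection and clustering.** The Venn stage returns the exact
intersection plus all 2ⁿ−1 region cardinalities. Clustering z-scores
each feature row and runs Euclidean K-means (scikit-learn, seeded random
initialisation, best of 25 restarts); on z-scored rows squared Euclidean
distance is 2n(1−r), so this is K-means under Pearson correlation
distance and is exactly invariant to positive affine transforms of any
row and to sample order. k defaults to 5. Bit-level equivalence with any
particular historical implementation is not claimed — recovery is
asserted at the property level (planted sinusoid/ramp/step groups at
log₂ noise 0.2 are recovered with ARI ≥ 0.9 in ≥ 90% of seeds).

**Candidates.** Clusters are selected by marker content (any marker by
default, a minimum fraction configurable) and ranked by marker count;
transcription-factor-annotated members of the selected clusters are
ranked by Pearson correlation with the mean marker profile. Zero-variance
profiles are rejected by name rather than silently scored.

## Synthetic expression data

The generator reproduces the three-experiment layout of the study it
models: a diurnal leaf time course (4 time points × 2 replicates),
tuber induction (stolon vs swollen stolon × 2) and growing vs
non-growing tubers (× 4). Five planted co-expression groups (A–E) are
differentially expressed in every experiment — modelling the five
clusters the intersected feature set splits into, three of them
(B/C/D) with starch-biosynthesis-like patterns hosting the co-regulated
TFs (6% of members, the composition reported for such clusters) — plus
two half-size groups responding in a single experiment only, which must
fall out of the Venn intersection. Intensities follow
`baseline · 2^(feature offset) · 2^(effect·template) · 2^N(0, noise_sd)`
with a 4-fold default effect and log₂ noise 0.25; the per-feature
abundance offset (sd 1 log₂) models probe-to-probe brightness and is
removed by normalization step 3. Truth exposes per-(experiment,
condition) expected log₂ levels, so "truly differential" is evaluated
for the same contrast pair the pipeline tests.

Not emulated: dye or spatial artifacts, intensity-dependent variance,
probe cross-hybridisation, missing values. End-to-end results (mean
sensitivity ≈ 0.91 at the stated conditions, FDR ≈ 0, TF recovery
≥ 95% at log₂ noise 0.2) certify the selection chain's logic under a
clean noise model, not performance on raw scanner output.

## qPCR

The Pfaffl ratio `E_t^{ΔCt_t}/E_r^{ΔCt_r}` uses `ΔCt = Ct(control) −
Ct(sample)`, so induced targets give ratios > 1; swapping the groups
inverts the ratio exactly and E = 2 reduces to `2^{−ΔΔCt}`. Technical
replicates are averaged before exponentiation and their combined sd is
reported alongside (both the Ct-level and ratio-level spread, since
error-bar conventions differ between labs). Efficiencies are user
inputs in (1, 2]; estimating them from dilution series is out of scope.
The generator inverts the formula from chosen true ratios — at zero
jitter the round trip is exact to floating precision; at the default
0.1-cycle jitter with 3 technical replicates the log₂-ratio sd is
0.1·2/√3 ≈ 0.115, i.e. a typical relative error of ~8%.

## Numerical and testing choices

Problem sizes were picked to keep the full suite around twenty seconds
and the acceptance script under ten: phantoms of a few tens of voxels
per side, 1000-feature matrices, 20–100 seed replications for
stochastic claims. Determinism: every generator takes one spec seed
fanned into substreams (`numpy` `SeedSequence`); the pipeline derives
per-stage seeds by hashing the global seed with the stage name, so
stages can be rerun independently and a rerun of the same config is
byte-identical (hashed in the manifest). Degenerate inputs fail loudly:
empty volumes, non-increasing scan times, zero-variance measured
volumes or expression profiles, efficiencies outside (1, 2], windows
with lower > upper.

## Known limitations

No watershed splitting of touching tubers; no grey-level calibration to
physical density; no nonlinear (logistic/Gompertz) growth models; the
contrast pair for multi-condition experiments is an analysis choice the
user must own; K-means with correlation distance inherits K-means'
sensitivity to k and to heavily unbalanced clusters; feature counts on
real archived array data are not a reproduction target since the
original contrast pairs are not recorded.
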