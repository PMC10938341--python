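# Methods

This note documents the models, conventions and design choices behind
`surfqc`, in the order the pipeline runs.

## Geometry

**Coordinate conventions.** Voxel indices are 0-based; world coordinates are
millimetres; the 4×4 affine is the single source of voxel↔world truth.
Surfaces are assumed to live in the volume's world frame; when a FreeSurfer
surface file carries a volume-geometry block, its c_ras translation is added
at load, since ignoring it misplaces contours by the volume-centre offset.

**Slice placement.** Slice planes sit at fixed fractions of the per-subject
brain bounding box (the tightest world box around voxels brighter than 10%
of the maximum intensity). Defaults: axial and coronal at {0.30, 0.50, 0.70}
of the box extent, sagittal at {0.25, 0.40, 0.60, 0.75} — ten views, none
near the brain edge, no sagittal view on the interhemispheric midline, two
per hemisphere. Fractions of the subject's own bounding box (rather than
absolute coordinates) generalize across fields of view and head positions;
the fraction lists and per-view counts are configuration options, and
non-default counts fall back to evenly spaced fractions over the same
interior band (even sagittal counts stay off the midline).

**Contour extraction.** For each triangle whose vertices straddle the plane,
the intersection segment is obtained by linear interpolation of signed
vertex distances along the two crossing edges. Three numerical choices
matter:

* vertices within 1e-9 mm of the plane are nudged to +1e-9 mm
  (simulation-of-simplicity), eliminating degenerate zero-length segments at
  measure-zero cost;
* each mesh edge's intersection point is computed once, with the edge's
  endpoints taken in index order, so the two triangles sharing the edge get
  bit-identical endpoints; chaining then matches segments through shared
  edge identity — exact arithmetic, no fuzzy tolerance search (the nominal
  1e-6 mm chaining tolerance only guards the final closed-polyline check);
* consequently, for a closed mesh and a generic plane every returned
  polyline is provably closed, and chained total length equals the
  per-triangle enumeration to float round-off (the tests require 1e-9 mm).

**Slice sampling and rendering.** Slice images are nearest-neighbour lookups
in voxel space by default so raw-intensity artifacts (ringing) survive into
the rating image; trilinear interpolation is available. Rendering is a pure
function of its inputs (greyscale window at the 99.5th percentile, Bresenham
contour rasterization, PNG via PIL): repeated runs are byte-identical, which
the pipeline relies on for reproducibility checks.

**Anonymization.** Image hashes are MD5 of salt + original filename, with
the salt recorded in the manifest so re-runs cannot be linked without it;
collisions abort rather than merge. The shuffle is one seeded uniform
permutation over all images pooled across subjects and sites, and the
manifest stores the full bijection for de-anonymization.

## Scores and reliability

Categorical ratings map to 1–4 (good, minor error, visible motion, bad;
*bad* worse than *motion* because localized motion may leave the surface
usable). Scores average with equal weight per image, then per rater — no
reliability weighting. Deliberation times are filtered per rater at >5
median absolute deviations over that rater's full set of image times (the
filter targets breaks, not slow decisions); when MAD = 0 (at least half the
times identical) the rule would be vacuous or total, so the filter falls
back to removing only times above 5× the median. Medians are then taken
within participant and across participants.

The reliability statistic is the single-measure two-way random-effects
absolute-agreement ICC(A,1), computed from the two-way ANOVA mean squares.
Single-measure is the conservative choice when the unit of analysis is one
rater's score; ICC(A,k) is available for panels averaged before use.
Spearman p-values use the t approximation, with an exact permutation option
for n ≤ 10. Consensus flags use a strict inequality (discrepancy > 1.0), so
a disagreement of exactly one point is tolerated.

## Topology metrics

χ = V − E + F with E the unique unordered vertex pairs over faces;
components via connectivity of the edge graph. For a closed connected
orientable surface χ = 2 − 2g, so the defect index (2 − χ)/2 counts handles.
The subject-level Euler index is the **sum** of the two hemispheres' defect
counts, higher = worse, matching the positive defect-count scale; externally
supplied signed Euler columns can be harmonized by an absolute-value map,
which preserves the quality ordering that thresholding and rank statistics
use. (Whether a given external table summed or averaged hemispheres, and
from which surface, should be checked by the user; the mapping is
override-able.)

MAD thresholds are median + k·MAD with the **raw** MAD (scale constant 1.0;
1.4826 available) — defect-count distributions are heavily right-skewed and
the raw MAD keeps cutoffs on the natural scale. Threshold retention keeps
boundary values (quality strictly worse than the cutoff is excluded); a
strict mode flips this. Per-site thresholding computes the cutoff within
each site.

## Statistical battery

All models are linear mixed-effects with a single site random intercept,
fitted by REML via statsmodels MixedLM; with one site level the model
degrades to OLS with a logged warning, and a fit on the zero-variance
boundary (site variance → 0) is re-fitted by OLS and flagged singular,
since the mixed parameterisation leaves its standard errors undefined there.
Age is mean-centred before squaring to decorrelate the linear and quadratic
terms without changing the model space. Residual df = n − (number of
fixed-effect parameters).

Effect sizes:

* **partial r** = t / √(t² + df) for the quality term — on fixed-effects-only
  designs this equals the correlation of the doubly-residualized response
  and metric exactly, which the tests verify;
* **Cohen's d** = t·(n₁+n₂)/(√(n₁n₂)·√df) for binary terms (sex, diagnosis),
  the standard t-to-d conversion (it differs from the pooled-SD d by a
  √((n₁+n₂)/df) finite-sample factor).

Quality columns are harmonized to a higher-is-worse scale before fitting
(higher-is-better metrics are negated), so a positive partial r always means
"worse quality ↔ larger phenotype value" across metrics.

FDR is Benjamini–Hochberg across the regions of one
(analysis × phenotype × metric) family, never pooled across phenotypes;
significance is q < 0.05. Global quality–brain correlations (cGMV, sGMV,
TBV, WMV, ventricles, mean CT) use Spearman with Bonferroni 0.05/6.

Case-control strategies: *none* (quality ignored), *covariate* (quality as a
fixed effect), *threshold* (exclude poor quality at an absolute or MAD
cutoff), *hybrid* (threshold on one metric, covary another). A covariate
with zero variance is dropped with a warning rather than crashing a map;
a threshold that empties a diagnostic group is an error. Threshold sweeps
re-run the full regional analysis per cutoff and flag (without fitting) any
cutoff excluding more than 95% of rows.

The per-site fits behind each map can be exported for external
meta-analysis; meta-analytic pooling itself is out of scope.

## Synthetic data

**Phantom subjects.** Two ellipsoid hemispheres (default outer semi-axes
30×70×55 mm, centres at x = ±34 mm, inner white-like surface at 0.75 scale)
in a 80×96×80 grid of 2 mm voxels; CSF/GM/WM intensities 20/90/150 a.u.
The ripple option multiplies intensities by 1 + A·sin(2πf·x), emulating the
periodic modulation of motion artifact (default f = 0.1 cycles/mm);
Gaussian noise and per-hemisphere topological handles are available. The
generator returns analytic in-plane ellipse cross-sections for every default
slice plane, giving the contouring stage an exact oracle. The phantom is
deliberately not a brain: no gyrification, no bias field, no k-space
physics — it validates geometry and plumbing, not reconstruction realism.

**Cohorts.** Latent quality
q = β_age(age − mean age) + β_dx·dx + u_site + ε, with defaults n = 2000
participants, 10 sites, site SD 0.15, ages uniform on [6, 30] years,
case fraction 0.5, β_age = −0.02 per year (younger ⇒ worse), β_dx = 0.15,
noise SD 0.5. Observed scores: FSQC = clip(1.9 + q, 1, 4) and
Euler = round(exp(4.6 + 0.6q + ε)) — the log-linear link produces the heavy
right skew characteristic of defect counts (median ≈ 100, long upper tail).
Auxiliary metrics (two motion-type ratings and one reverse-coded certainty
score) and six global brain measures are linked to q weakly, for the
cross-metric and global analyses.

Region values respond to **observed FSQC** (not latent q), so the covariate
strategy analyses a correctly specified model and estimator properties can
be tested separately from misspecification; quality slopes can be given
directly, or as target partial correlations which are converted exactly:
the generator computes the residual second moments of FSQC (and of the
tail-hinge transform) against the analysis covariates on a large auxiliary
draw — clipping included — and solves λ = r/√(1−r²)·σ_res/σ_F. The exported
ground truth therefore carries the partial r the analysis model should
recover, which large-sample tests confirm to ±0.01. The default region set
is 360 (a Glasser-resolution table), reducible to 68 for a
Desikan-Killiany-like run; the default effect mixture is 45% negative
(U(−0.45, −0.05)), 35% null, 20% positive (U(0.05, 0.35)), mirroring the
expected predominance of negative quality–thickness associations with some
genuinely positive regions. The *tail* mode routes the quality effect
through max(FSQC − 2.5, 0), concentrating it in the worst images — the
scenario in which threshold sweeps show attenuation.

What passing tests on these cohorts show: the estimator recovers the
generative partial correlations, calibrates its FDR under the null, and
removes quality confounding by covariate adjustment *when the generative
and analysis models coincide*. They do not show robustness to nonlinear
quality effects (except the tail scenario), non-Gaussian residuals,
site-by-quality interactions, or measurement error in the QC metrics — all
present in real data.

## Problem sizes

The test suite and the acceptance script use cohorts of 1,200–2,000
participants with 12–100 regions, 100 random mesh/plane pairs for the
geometry oracle, and two replicate null cohorts of 100 regions for FDR
calibration; the full suite runs in about a minute on one CPU, the
acceptance script in about 20 seconds. Region counts were chosen so that
every statistical property is measured with adequate precision while the
whole battery stays interactive.

## Known limitations

* Slice placement is a fractional-bounding-box scheme, not a reproduction
  of any specific tool's absolute slice coordinates.
* The subject-level Euler index assumes per-hemisphere defect counts are
  summed; external tables using other conventions need the harmonization
  hook.
* The mixed model uses a single random intercept — no random slopes, no
  site-level meta-analysis, no harmonization (e.g. ComBat).
* The partial-r transform and df convention are one defensible choice among
  several; both are fixed and documented rather than configurable.
* The interactive rating session is a minimal local terminal tool with the
  same data contract as a hosted rating app, not a replacement for one.
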