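# Methods

`immunoscape` quantifies lymphocytic infiltration in tumour sections from
classified cell coordinates (cancer / lymphocyte / stromal, in μm).  This
note records the statistical model, the parameters that matter, the numerical
choices, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Cancer-density landscape and proximity to cancer

The cancer cells x₁…xₙ of a section define a kernel intensity surface

    f(p) = h⁻² Σᵢ K((p − xᵢ)/h),     K(u) = (3/π)(1 − ‖u‖²)²·1{‖u‖ ≤ 1},

with K the radially symmetric quartic (biweight) kernel, which integrates to
one over the plane.  A lymphocyte's *spatial proximity to cancer* is
sᵢ = f(yᵢ), evaluated exactly at its coordinates — never interpolated from a
grid; grids exist only for maps and contour plots.  Two consequences of this
normalization:

* f is an **intensity** (cells/μm²), not a probability density: there is no
  1/n factor, so s values remain comparable when lymphocytes are pooled
  across tumours whose cancer counts differ by orders of magnitude.
  Absolute s values therefore depend on the (unknowable) units of any other
  dataset; everything downstream of s is deliberately scale-free.
* Compact support makes evaluation a neighbour sum (k-d tree), exact to
  floating point against the double-loop definition.

**Bandwidth.** Default h = 50 μm, a few cell diameters, matching the scale at
which "inside a nest" differs from "at its edge"; the end-to-end recovery
analyses here use h = 80 μm, matched to the synthetic nest spread (σ = 60 μm).
When training maps are available, `select_bandwidth` minimizes the
least-squares cross-validation criterion for point-process intensity
estimation, M(h) = ∫f̂² − 2Σᵢ f̂₋ᵢ(xᵢ), averaged over up to 10 randomly
sampled maps; the integral uses a midpoint grid at 0.2·h over the window
inflated by h.  No edge correction is applied: sections are millimetres wide
while h is tens of μm, so the bias zone is a thin border.

## Lymphocyte classes

Pooled s values are modelled as a univariate Gaussian mixture fitted by EM,
with the component count K chosen by BIC in the higher-is-better convention
BIC = 2L − d·log N, d = 3K − 1.  EM details (all configurable): 10
quantile-spread initializations run briefly (30 iterations) and the best
polished to a relative log-likelihood tolerance of 1e-8, at most 1000
iterations; variance floor 1e-12·var(s); collapsed components trigger a
restart.  The short-run-then-polish scheme is the standard way to buy
multi-start robustness without multi-start cost; the fitted optimum matches
an independent EM implementation (scikit-learn) on separated data.  The inner
loop is JIT-compiled (numba) with a pure-numpy fallback.

Stability: repeated subsampling (without replacement — with ~10⁵-point pools
the distinction is immaterial, and without-replacement avoids
duplicate-weighting artifacts) re-runs the K selection; the modal K and the
spread of the sorted K = 3 means are reported.  The production model is a
deterministic fixed-seed fit at the modal K; the three-class system
(ITL/ATL/DTL, by decreasing mean proximity) is the defined classification, so
if BIC prefers another K the package classifies with a K = 3 fit and leaves
the discrepant selection visible in the model report.

**Assignment** uses the two crossing points of adjacent weighted component
densities, solved in closed form (a quadratic in s; the root strictly between
the two means).  Crossing-point thresholds give contiguous intervals on s
even with unequal variances, unlike raw max-posterior assignment, which is
available behind `method="posterior"`.  If a pathological fit has no crossing
between adjacent means, the midpoint is used with a warning.  Classification
is invariant to any common positive rescaling of s.

## Spatial arrangement

Two physical-distance descriptors per lymphocyte: d_min, the distance to the
nearest cancer cell; and d_centroid, the distance to the centroid of the
convex hull of its five nearest cancer cells, where the centroid is the
arithmetic mean of the hull **vertices** (extreme points) — a lymphocyte
surrounded by cancer sits near that centroid, one with cancer to one side
does not.  Degenerate neighbourhoods are defined exactly: duplicates are
removed before hull construction; a collinear set contributes its two
endpoints (centroid = midpoint); a single distinct point is its own centroid;
k-nearest ties break to the lowest cell index.  Class differences are tested
with Welch's t-test by default (class variances differ markedly; the pooled
test is available via `equal_var=True`), with per-class medians and IQRs
reported.

## Infiltration scores

ITLR = n_ITL / n_cancer, and analogously ATLR, DTLR; Lym is the
class-agnostic ratio, so ITLR + ATLR + DTLR = Lym identically.  Association
with ordered clinical categories (absent < mild < severe infiltration) uses
the Jonckheere–Terpstra trend test: exact by full enumeration for n ≤ 10,
otherwise a normal approximation with the standard tie-corrected variance.

## Survival stratification

Scores are dichotomized by scanning the 20th–80th score percentiles in steps
of 1.5 percentile points (41 candidates; the step is read in percentile
units — a value-unit reading would be scale-dependent) and keeping the
cut-off with the smallest log-rank p; ties go to the lower percentile.  The
scan minimizes over 41 tests and is therefore anti-conservative under the
null (documented by a calibration test); the guard is the
discovery/validation discipline: the percentile chosen in a named discovery
cohort is frozen and applied to the validation cohort.  Survival times are
administratively censored at 120 months on ingest (10-year disease-specific
survival).  Kaplan–Meier, log-rank and Cox models (Efron ties) are computed
with lifelines; the high-score group is coded 1, so HR < 1 means high scores
are protective.  Covariate encodings: node binary (any positive node), size
continuous in cm; both configurable.  α = 0.05 throughout.

Cut-off consistency across cohorts z-scales each cohort's signature and maps
its cut-off by the same affine transform before comparison.

**Bootstrap robustness** resamples patients with replacement and reports the
fraction of resamples in which the score term stays significant (univariate
and multivariate); failed fits count as non-significant and are tallied.  A
caveat documented by the tests: under a *null* effect this fraction is not
calibrated to α.  The bootstrap distribution of the Wald z recentres on the
original dataset's z, so the expected fraction is P(|z + z*| > 1.96) ≈ 0.17
with huge per-dataset spread.  The statistic is meaningful as a robustness
measure for an effect already observed, not as a test.

## Molecular correlates

Per-gene Pearson correlation with the score, two-sided p from the
t-transform, FDR control by Storey q-values with λ = 0.75: π₀ is estimated
from the fraction of p-values in the top quarter of [0, 1] (clipped to
(0, 1], floored at 1/m), and multiplies the BH step-up quantity — π₀ = 1
recovers Benjamini–Hochberg exactly.  A 25%-sample-split reading of the null
fit was considered and rejected as incompatible with standard q-value
practice.  Zero-variance genes are flagged and excluded from testing.

**Modules.**  Positively and negatively score-associated genes are clustered
separately (which keeps anticorrelated genes apart by construction).  The
gene–gene correlation matrix is clustered hierarchically and cut into 100
clusters; clusters with mean pairwise |r| > 0.75 and ≥ 6 members ("exceeding
five", read strictly) are the modules.  The default clusters each gene's
**correlation profile** (its row of the matrix, Euclidean distance, average
linkage): co-module genes have near-identical profiles while unrelated genes
concentrate at a common background distance, so a fixed 100-cluster cut
leaves modules pure.  The alternative of clustering the condensed 1 − r
distance matrix directly is retained (`features="distance"`) but not default:
at a fixed cluster-count cut, background genes attach to tight modules below
the cut height under single, average and complete linkage alike, diluting
mean |r| below the filter — planted-block experiments recover zero modules
that way and all modules exactly with profiles.

**Enrichment** of a hit list against GMT gene sets uses the upper-tail
hypergeometric test on the universe-intersected sets; BH-adjusted p across
sets is reported alongside the raw values.  Score-versus-gene comparisons fit
one Cox model per gene containing the dichotomized score and a rank-based
gene grouping (median halves, or 25/50/25 ordinal); collinear designs and
non-convergent fits are flagged per gene.

## Synthetic data: what it emulates, what it does not

`simulate_tumor` draws cancer cells from a Thomas-type parent–offspring
process (nest parents Poisson in the window; Gaussian offspring), giving the
nested "cancer landscape" with two interpretable knobs (nest rate, spread).
Lymphocyte regimes are **geometric** constructions — inside a nest, at a
fixed offset on a nest's outward side, far from every parent — not density
thresholds, so pipeline-recovery tests are non-circular.  Full-scale defaults
emulate a whole section (10×10 mm, ≈8×10⁴ cancer cells, 1.5×10⁴ lymphocytes
at the 32/47/21 ITL/ATL/DTL composition); tests and the acceptance script use
4×4 mm sections with the same geometry to keep runtimes in minutes.
`simulate_survival` draws Weibull proportional-hazards times with a planted
high-vs-low hazard ratio (HR < 1 ⇒ the low-score fifth fares worse, the
clinically observed direction), exponential censoring, administrative
censoring at 120 months; baseline scale 82 months ≈ 49% five-year survival in
the low group.  `simulate_expression` plants score-correlated genes at an
exact population correlation and latent-factor modules at an exact pairwise
correlation (`n_negative` plants the mirror-image pool at −r).

Not emulated: irregular section boundaries and tissue folds; anisotropic or
merging nests; spatially varying stromal architecture; lymphocyte clustering
independent of cancer (e.g. tertiary lymphoid structures); correlated
censoring; microarray normalization artifacts.  Passing tests demonstrate the
statistical machinery recovers planted structure under the stated geometry —
not that any particular biological cohort satisfies that geometry.

## Known limitations

* Absolute proximity values depend on the kernel normalization and input
  units; only scale-free downstream quantities (labels, ratios, cut-off
  percentiles) transfer across datasets.
* The class system is fixed at three components; if BIC prefers another K the
  package reports it but still classifies with K = 3.
* The cut-off scan's raw minimum p is optimistic by construction; only
  validated cut-offs should be interpreted.
* d_centroid uses the vertex mean, not the area centroid, of the hull.
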