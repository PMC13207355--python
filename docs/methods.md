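# Methods

This note documents the models, defaults and numerical choices behind
phenoscreen, and what the synthetic tests do and do not demonstrate about
real screening data.

## Processing chain

Field-level feature tables (up to 6 imaging fields per 384-well) move
through a fixed stage order, tracked on the table and enforced at run time:

1. **Field aggregation** — per-well median over available fields; fields
   flagged by image QC are excluded first. Median (not mean) because
   single out-of-focus or debris-laden fields are common.
2. **Image QC** — QC features are standardized, projected by PCA, and each
   field's robust squared score-space distance (per-component median/MAD)
   is compared to a χ² quantile (default 0.995). This replaces manual
   review of image-quality clusters with an algorithmic rule; the quantile
   is configurable and flagged fractions above 5% trigger a plate-review
   warning rather than silent removal.
3. **Redundancy filter** — one greedy pass in column order drops any
   feature with |Pearson r| > 0.99 against an earlier kept feature.
   Keeping the earlier column is an arbitrary but deterministic tie-break;
   the surviving set has no pair above the cutoff, and the result is
   invariant to row order.
4. **Normalization** — per plate and feature, values are centered on the
   reference median. The reference is the plate's DMSO wells by default
   (all sample wells available as a switch); DMSO-relative profiles are
   what the downstream hit thresholds assume. At least 8 reference wells
   per plate are required.
5. **Skewness-gated transform** — per feature, a D'Agostino skewness test
   on the pooled reference wells; when p < 10⁻⁴ the column is mapped
   through sign(x)·log1p(|x|/s), s the reference MAD. The test threshold
   is the conventional screening default; the transform itself is this
   package's choice (any odd, concave-for-positive map would serve) and is
   recorded per run.
6. **Robust Z scaling** — per plate and feature, z = (x − median_ref) /
   (1.4826·MAD_ref). The 1.4826 constant makes the MAD a consistent
   Gaussian σ estimator. Zero-MAD features are set to 0 on that plate and
   flagged rather than dropped, so feature sets stay aligned across
   plates. Rescaling an already-scaled table leaves reference medians at 0
   (idempotence at the fixed point).

## Phenotypic distance and the Poisson null

PCA is fit on the scaled well × feature matrix; the retained count is
m = max(20, smallest m′ with cumulative explained variance > 0.60), capped
at the available components. Component signs are fixed by making each
loading vector's largest-magnitude entry positive. (StratoMineR, the
commercial high-content platform whose processing conventions this chain
follows, uses a factor-analytic variant with oblique rotation and Ten
Berge scores; that proprietary rotation is not replicated — the
component-count rule and all distance rules are preserved on plain PCA,
and distances are invariant to orthogonal rotations of the score space.)

The per-well distance is Euclidean, in score space, to the same-plate DMSO
reference. The reference point is the component-wise **median** of the
plate's DMSO scores: a "distance to the controls" leaves the exact
reference open, and the median resists control-well outliers.

p-values come from a Poisson null: λ is the mean of the observed distance
distribution, and p = P(X ≥ d) is evaluated for continuous d by the
regularized lower incomplete gamma P_reg(d, λ) with p(0) ≡ 1 — the unique
smooth interpolant agreeing with the discrete tail at integers (verified
against PMF summation to 10⁻¹⁰). λ is estimated per plate for replicate
p-values (plates are processed separately to avoid mixing replicate
distributions); the treatment-level p uses the median replicate distance
under a pooled λ taken over the **full** observed distance distribution of
the analysis — every well, controls included (a flag restricts the pool to
DMSO wells). Treatment q-values use Benjamini–Hochberg by default;
Benjamini–Yekutieli is available.

This null is analytical, not resampled. On synthetic latent-Gaussian
screens it is close to nominal: across ten pure-null screens (10 plates,
300 features, ~1,600 treatments per screen) the fraction of treatments
with −log₁₀ p > 2 averages ≈ 4–5%. It is *not* a guarantee of type-I
control on real data, where distance distributions can be heavier-tailed
than any of the generator's settings.

## Hit selection and triage

Per compound × line, doses collapse to the most significant dose (max
−log₁₀ p; an "any dose passes" mode exists since the original multi-dose
collapse rule is not fully specified). A line is hit on the **disjunction**
survival Z < −3 OR −log₁₀ p > 2 — "changes in cell number and/or
morphology" — with strict inequalities at the printed boundaries; primary
hits require ≥ 2 lines. The hit set is monotone in both thresholds.
Triage de-prioritizes (never deletes) hits by MOA blocklist (defaults:
microtubule, topoisomerase, proteasome — overtly cytotoxic classes) or by
activity confined to the top tested concentration; unannotated compounds
stay untriaged.

Note the diversity-analysis subset uses the **conjunction** of the two
thresholds (both survival and morphology effects), matching how the
above-threshold compound set is defined for clustering.

## Dose response

Viability = nuclei count / plate DMSO median. nAUC is the equal-weight
trapezoid of viability over log₁₀ dose divided by the log-dose span, with
viability clipped to [0, 1] first, so nAUC ∈ [0, 1], 1 = fully viable,
0 = complete death, and stimulation above DMSO cannot push nAUC past 1.
nAUC depends only on log-spacing, hence is invariant to dose units. The
exact integration rule of the original deposited R script is not public;
the trapezoid is this package's documented choice, and clipping is
configurable.

The IC50 model is the two-parameter normalized variable-slope logistic
exactly as printed — top fixed at 100%, bottom at 0% — fit by nonlinear
least squares on percent viability with HillSlope bounded negative
(inhibition). Curves never dropping below 50% viability, or whose fitted
span across the tested range is under 10 percentage points, are reported
**inactive** with no IC50, as are non-convergent fits. The 95% CI for
LogIC50 is profile-likelihood: the SSR crossing of
SSR_min·(1 + F₀.₉₅(1, n−2)/(n−2)), bracketed geometrically and refined by
bisection. IC50 is reported in nM via IC50_nM = 10^(LogIC50 + 9) (X is
log₁₀ molar).

## Diversity diagnostics

k-means uses hand-written Lloyd iteration because the protocol is pinned:
k = 2–20, at most 10 iterations, best of 25 restarts each initialized at k
distinct dataset rows. Rows are put in canonical (lexicographic) order
before restart sampling so reported WSS does not depend on input row
order. WSS is the within-cluster sum of squared point-to-centroid
distances summed over clusters; the elbow is the k maximizing the second
difference of the WSS curve (the original assessment was visual).

The silhouette s(i) = (b(i) − a(i))/max{a(i), b(i)} uses the standard
b(i) — mean distance to the members of the nearest other cluster — by
default; the source description also admits a centroid-distance reading,
implemented behind a flag. Singleton clusters score 0. The default
matches scikit-learn's implementation to 10⁻¹⁰ (used as the independent
cross-check in tests). A screen whose maximum mean silhouette over the k
grid stays below 0.25 is reported as having "no noticeable cluster
structure"; the bound is configurable and deliberately lenient — genuine
cluster structure produces silhouettes several times higher.

## Similarity matrix

Spearman rank correlation (average ranks on ties — unavoidable with
six-line profiles) between each compound's IC50 profile and each protein's
basal expression profile, pairwise-complete, requiring ≥ 3 shared lines
per cell. Negative ρ means high expression accompanies low IC50 — a
candidate sensitivity biomarker; positive ρ suggests a resistance marker.
Compounds with no IC50 fit are right-censored at the top tested dose so
they still rank. Row/column orderings come from agglomerative clustering
with distance 1 − ρ (Spearman between rows of the matrix), complete
linkage, labels pre-sorted for deterministic tie-breaks. Per-row 0–1
rescaling of IC50s (display convention) is monotone per row and therefore
does not affect ρ.

## Synthetic screen generator

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed at the screening campaign's stated conditions: 384
wells with 48 DMSO wells (the stated range is 32–48), 16 staurosporine-like
positive-control wells, up to 320 sample wells, 6 fields per well, and
nuclei counts as negative-binomial draws with mean 110 per field (the
stated 75–150 range). Morphology is a latent-factor model: 10 latent
factors pushed through a block-structured loading matrix (300 features by
default; 1,006 available), so features are strongly collinear and PCA
recovers low-dimensional structure. Wells add per-plate offsets (additive,
the simplest structure per-plate normalization must remove), per-field
Gaussian noise, and exponentially transformed (right-skewed) noise on 20%
of features to exercise the skewness gate. Active compounds shift the
latent state by δ (in latent-sd units) along 1–3 random factors and/or
scale the nuclei-count mean by a viability multiplier v; DMSO and null
compounds are exchangeable by construction. Free parameters that the
source data do not constrain (noise 0.4, latent variability 1.0, plate
effect 0.5, block correlation 0.7) were set once to plausible
screening-like values.

What passing tests show: the pipeline removes plate effects, recovers
planted latent structure, calibrates the Poisson null on latent-Gaussian
distances, and recovers strong actives (δ ≥ 3 or v ≤ 0.3) with high
recall and precision. What they do not show: performance under real
cell-painting covariance, batch drift beyond additive offsets, spatial
plate artifacts (edge effects), or segmentation-driven feature errors —
none of which the generator models.

## Problem sizes and determinism

Default test and reproduction sizes are deliberately desk-scale: screens
of 2–10 plates × 300 features, panels of 6 simulated lines, 100 noisy
dose-response curves. Every stochastic step takes an explicit seed and
identical seeds reproduce byte-identical tables; the multi-line panel
derives per-line seeds from the base seed while sharing one compound
ground truth.

## Known limitations

- The factor-analytic rotation of the original processing platform is not
  reproduced; component counts and distances use plain PCA.
- The Poisson null is used as specified; on strongly non-Poisson distance
  distributions its p-values are approximate by design.
- Image QC here is a statistical outlier rule on QC features, not a
  learned image-quality model.
- The logistic model is the printed two-parameter form; four-parameter
  fits (floating top/bottom) are out of scope.
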