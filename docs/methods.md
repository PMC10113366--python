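# Methods

`fcbiomarker` implements a resting-state functional-connectivity (FC)
classification pipeline for subthreshold depression (StD): feature
extraction from ROI time series, two-stage sparse feature selection
(L1-regularised sparse CCA followed by ARD sparse logistic regression) under
nested leave-one-out cross-validation (LOOCV), permutation inference,
FC-importance ranking, independent-cohort generalisation, and post-hoc
clinical statistics. Because no subject-level data of this kind are openly
deposited, a first-class synthetic-cohort generator provides inputs with
known ground truth.

## Feature extraction

Per subject, the frames × regions signal matrix passes through:

1. **Band-pass** 0.008–0.1 Hz. The filter realisation is a second-order
   Butterworth applied forward-backward (`sosfiltfilt`), i.e. zero phase
   with the squared Butterworth magnitude response; the series is demeaned
   first. Band edges are validated against the Nyquist frequency 1/(2·TR).
2. **Nuisance regression**: ordinary least squares of every region on an
   intercept, the tissue signals (white matter, CSF, global) and the six
   rigid-body motion parameters; residuals are exactly orthogonal to the
   regressors. Rank-deficient designs fall back to the minimum-norm
   solution.
3. **Scrubbing**: framewise displacement FD(t) = Σ|Δtranslation| +
   50 mm·Σ|Δrotation| (Power-style; FD(1)=0), and every frame with
   FD strictly greater than 0.5 mm is censored. No neighbour augmentation by
   default (configurable); correlation is computed on the concatenated
   retained frames without interpolation.
4. **Correlation**: pairwise Pearson correlation over all region pairs.
   Edges are indexed canonically: strict upper triangle, row-major, 0-based;
   R regions give E = R(R−1)/2 edges (137 → 9316).
5. **Fisher transform** z = atanh(r), the scale on which the classifier and
   all group t tests operate. Group mean FCs in human-readable tables are
   reported on the r scale (matching how such tables are conventionally
   printed); the clinical-correlation stage defaults to z and can be
   switched to r.

At least 8 retained frames and nonzero variance in every region are required
for the correlation stage; violations raise errors naming the culprit.

## Sparse CCA feature selection

Stage one reduces the ~10⁴-dimensional edge space. With X the
(standardised) subject × edge matrix and Y the subject attributes
(diagnosis, age, sex — each column centred and scaled to unit variance so no
attribute dominates by scale), sparse canonical pairs maximise uᵀXᵀYv
subject to ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c_u and likewise for v — the penalised
matrix-decomposition form of sparse CCA. Updates alternate
soft-threshold-and-renormalise steps on M = XᵀY, with the threshold found by
bisection; initialisation is the leading singular pair of M (deterministic);
successive components deflate M by its rank-one fit. Exact magnitude ties
that make an L1 bound unreachable by thresholding resolve to the first
maximal coordinate.

Design choices that matter:

* **c_v = 1.0** makes the attribute side axis-aligned: every component
  associates with exactly one attribute, giving the cleanest reading of
  "related only to the diagnosis label". A permissive bound would leave
  nuisance weights small but nonzero, and the diagnosis-only rule (nuisance
  entries exactly zero at tolerance 1e−10) would never fire.
* **K = number of attribute columns** by default. Sparse rank-one deflation
  of the E × 3 cross-product removes little mass, so additional components
  only redistribute deflation residue and pull noise edges into the
  candidate set. K remains configurable.
* **Candidate set**: the union, over 5 stratified inner folds × a 5-point
  c_u grid (defaults 1.2, 1.6, 2.0, 2.5, 3.0), of the u-supports of
  diagnosis-only components, each fit on the fold's training portion with
  standardisation computed there. An empty union falls back (with a
  warning) to the least-sparse grid point on the full data.

## ARD sparse logistic regression

Stage two fits p(y=1|x) = σ(wᵀx) with per-weight Gaussian priors
w_j ~ N(0, 1/α_j), optimised through the Jaakkola–Jordan variational bound:
λ(ξ) = tanh(ξ/2)/(4ξ); S = (A + 2Σλ(ξ_n)x_nx_nᵀ)⁻¹; m = SΣ(y_n−½)x_n;
ξ_n² = x_nᵀ(S+mmᵀ)x_n; and the precision update. Features are standardised
on the training data (precisions are scale-sensitive); the transform is
stored in the model and reapplied at prediction. The bias is always active
with precision 1e−6 (effectively unpenalised — necessary under the 30/61
class imbalance). Constant feature columns are dropped up front. A fit that
exhausts `max_iter` (default 500) is returned flagged, not silently marked
converged.

Two precision rules are implemented, with prune thresholds matched to their
dynamics:

* **VB rule** (default): α_j ← 1/(m_j² + S_jj). For a useless feature the
  precision grows only linearly (≈ 2Σλx² per sweep), so the prune threshold
  defaults to 1e3 — reached by noise precisions within a few hundred
  sweeps, while informative features stabilise at α ≈ 1/m² ≪ 1e3. The VB
  rule shrinks smoothly and is the safer default when informative features
  are mutually correlated.
* **MacKay/evidence rule**: α_j ← γ_j/m_j², γ_j = 1 − α_jS_jj. Precisions
  of irrelevant features diverge geometrically, so the classical 1e8
  threshold applies. This rule behaves like greedy best-subset selection
  and will keep a single representative of a strongly collinear group.

Both rules drive the ARD mechanism — irrelevant features are deleted by the
data, not by a tuned hyperparameter. Note a structural property of ARD of
either flavour: among several *strongly* collinear informative features it
concentrates weight rather than spreading it; interpretation of the
surviving set should bear this in mind.

Two ξ-update rules are exposed: the posterior rule above, and a "mode" rule
ξ_n = |x_nᵀm| whose fixed point with fixed common precision is exactly the
ridge-penalised MAP — used to cross-check the optimiser against an
independent Newton solver in the tests.

Decisions threshold the predictive probability at 0.5 (equivalently the sign
of the weighted linear sum); an exact 0.5 is called HC (ties go negative).

## Nested LOOCV, inference, and the identified set

For each of N = n_subjects folds, the held-out subject is excluded from
candidate selection, standardisation and fitting; the held-out prediction
uses the fold's frozen model. Edge importance is the cumulative absolute
weight c^κ = Σᵢ|W_i^κ| over folds (zero when unselected), ranked descending
with ties broken by edge id. Performance uses StD as the positive class;
AUC is the rank (Mann–Whitney) statistic with half credit for ties, computed
on the pooled held-out probabilities.

The permutation test permutes labels over the whole cohort and re-runs the
entire nested procedure per permutation;
p = (1 + #{perm ≥ observed})/(n_perm + 1). The default statistic is
accuracy (AUC selectable); n_perm defaults to 100 at desk scale.

The deployable model refits ARD logistic regression on the full training
set restricted to the union of ever-selected candidates; the **identified
FC set** is the ARD-surviving features of that fit (an x%-of-folds
selection-frequency rule is available behind a config key). Per-FC
significance of the fold weights uses the two-sided Wilcoxon signed-rank
test with zeros dropped: exact null distribution up to 25 nonzero weights
and no ties, tie-corrected normal approximation otherwise; all-zero edges
report p = 1 flagged. Generalisation applies the frozen model — training
standardisation constants included — to an external cohort sharing the
canonical edge indexing, with no refitting.

## Post-hoc statistics

* Contribution index: (r̄_StD − r̄_HC) × weight, with group means on the r
  scale; antisymmetric under swapping groups.
* Mass-univariate screening: pooled-variance two-sample t per edge on
  Fisher-z values, Bonferroni threshold 0.05/E; zero-variance edges are
  flagged with p = 1.
* Demographics: two-tailed pooled t for age and BDI-II; Pearson chi-squared
  (df = 1, **no continuity correction** — this choice reproduces the printed
  cohort p-values 0.326/0.782 exactly) for sex.
* BDI-II anhedonic subscore: items #4, #12, #15, #21 (1-based), range 0–12.
* Clinical correlations: Shapiro–Wilk at α = 0.05 on both variables gates
  Pearson (both pass) vs Spearman; the significance level is
  Bonferroni-adjusted to 0.05/n_tests (0.006 for the eight identified FCs).
  The normality test is not named in the design source; Shapiro–Wilk is the
  most common gate matching the stated rule.

## Synthetic cohorts

`generate_cohort` draws metadata: BDI-II totals from group-banded normals
(StD: 16.8 ± 3.5 clipped to ≥ 13; HC: 3.0 ± 1.9 clipped to < 8), item
scores allocated unit-by-unit with anhedonic items (4, 12, 15, 21) given
2.5× weight in StD; age uniform on {18, 19}; sex Bernoulli at the printed
cohort ratios; EROS from a latent Gaussian coupled to the standardised
anhedonic subscore at correlation −0.5 (configurable), scaled to 10–40.

Edge structure: a shared baseline Fisher-z vector (sd 0.10) plus
group-specific offsets ±Δz/2 on the declared discriminative edges plus
per-unit covariate slopes on declared nuisance edges. Two routes produce
subject data:

* **Direct FC route**: z-vector = group mean + nuisance shifts + subject
  heterogeneity N(0, 0.2²) + Fisher-z sampling noise N(0, 1/(T−3)) for the
  spec'd frame count T. The heterogeneity default 0.2 is calibrated so that
  a printed-table-sized group gap (Δz ≈ 0.21) is a d ≈ 1 effect — the
  regime in which exactly one strong edge clears a 0.05/9316 Bonferroni
  t test at n ≈ 91, matching the arithmetic of the published cohort.
* **Time-series route**: the subject's target correlation matrix (inverse
  Fisher transform of the z-vector, SPD-projected by eigenvalue clipping
  with diagonal renormalisation, floor 1e−6) drives a stationary AR(1)
  Gaussian process (coefficient 0.3) via its Cholesky factor, identical
  temporal filtering in every region so cross-correlations are preserved.
  Tissue confound signals load on all regions at a configurable scale
  (default 0 = off). Head motion is a step process: zero except at
  Bernoulli-placed spike frames, where translation steps by the spike
  magnitude (so FD equals exactly that magnitude at the spike frame) and a
  burst artifact enters the signal.

What the generator does **not** emulate: image space and hemodynamics,
scanner drift, spatial autocorrelation between edges sharing a region,
heavy-tailed motion, site/protocol differences, and any dependence between
clinical scores and FC edges (clinical coupling exists only between EROS
and the anhedonic subscore). Passing recovery tests therefore demonstrate
the estimation machinery under the model's own assumptions, not performance
on real cohorts.

## Numerical choices and degenerate inputs

* Edge indexing is everywhere the row-major strict upper triangle, 0-based;
  human reports label FCs 1-based by descending contribution.
* SCCA: bisection runs 60 halvings; "nonzero" means |w| > 1e−10; objective
  convergence at relative 1e−8, max 100 alternations.
* SLR: convergence is max relative precision change (or max weight change
  when precisions are fixed) below 1e−6.
* SPD projection iterates clip-and-renormalise up to 100 times and errors
  if the floor cannot be met.
* |r| = 1 edges make the Fisher transform infinite and raise an error
  pointing at degenerate/duplicated inputs; correlations are clipped to
  [−1, 1] against floating-point overshoot before that check.
* Machine TSV files carry 17-significant-digit floats and are re-read with
  round-trip float parsing, so identical configurations reproduce
  byte-identical outputs.
* One master seed is split per stage by hashing (seed, stage-name); all
  derived seeds stay below 2³¹.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script exercise reduced cohorts chosen to
keep a full run at desk scale on one CPU: 30 ROIs (435 edges) with n = 60
for recovery and ranking checks, a 43-subject (16/27) independent cohort
for generalisation, 8-region cohorts with n = 12 for the permutation-null
calibration replicates (validity of the permutation p rests on
exchangeability and is size-independent), a 12-region n = 30 cohort for the
significance demonstration, and 200-subject cohorts for Monte-Carlo checks
of generator moments. These sizes are the package's own verification
conditions; the pipeline itself runs unchanged at the full 137-ROI scale.
The SLR sweep loop and the L1 projection have numba-compiled kernels that
mirror the reference implementations (the pure-python paths remain in place
and are exercised whenever the variational bound is being tracked).

## Known limitations

* ARD concentrates on one member of a strongly collinear informative group;
  the identified set is a minimal sufficient subset, not an exhaustive one.
* When the ever-selected candidate union exceeds the sample size, the final
  full-training-set fit sits at interpolation: the logistic curvature terms
  collapse, noise precisions grow too slowly to reach the prune threshold
  within the sweep budget, and the "identified" set stays close to the whole
  union with near-zero weights on the bulk. The weight ordering remains
  informative; a selection-frequency identification rule (features selected
  in at least a given fraction of folds) is available as an alternative.
* The permutation test re-runs the full nested pipeline and is O(n_perm ×
  LOOCV); large n_perm at full scale is expensive by construction.
* The direct-FC generator draws edges independently, so it understates the
  spatial dependence of real connectomes; the time-series route captures
  dependence only through the target correlation matrix itself.
* Wilcoxon p-values for identically-valued fold weights fall back to the
  tie-corrected normal approximation, which is anti-conservative below ~10
  nonzero folds; such edges are rare in practice and flagged by count.
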