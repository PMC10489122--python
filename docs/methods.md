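# Methods

This note documents the models, defaults and numerical choices behind
`cortigen`, and what the simulation results do and do not establish.

## Scientific setting

The package implements an analysis chain for asking whether common
genetic risk factors for Alzheimer's disease — carrying an *APOE* ε4
allele, or the A allele of *MAPT* rs242557 — leave a detectable imprint
on cortical morphology in young healthy adults. The unit of data is a
participant's regional morphometry vector: for each of the 68
Desikan–Killiany cortical regions, surface area, mean thickness, mean
curvature and folding index, plus 14 subcortical grey-matter volumes
(286 features). Curvature metrics derive from the principal curvatures
K1, K2 at each surface vertex: mean curvature H = (K1+K2)/2 and folding
index FI = |K1|·(|K1|−|K2|).

Two complementary analyses are implemented:

1. **Discriminative**: can a linear SVM classify carrier status from the
   286 features better than chance? Because single-feature effects are
   too subtle for mass-univariate tests in young cohorts, the
   multivariate classifier with permutation significance is the primary
   instrument, and its hyperplane weights provide an anatomical map of
   discriminative regions.
2. **Interaction**: do the two risk alleles interact synergistically?
   Classification cannot express an interaction, so the cortex is first
   clustered into morphological profiles (GHSOM over region profiles),
   and each participant's deviation from a cluster's typical morphology
   (intra-cluster distance) is tested for an APOE×MAPT interaction in a
   covariate-adjusted linear model.

## The folding-index sign convention

With K1 = max and K2 = min, |K1|−|K2| can be negative (a saddle with
K1 = 1, K2 = −2). `PrincipalCurvaturePair` therefore orders the pair by
absolute magnitude on construction, which makes FI ≥ 0 always and
matches the FreeSurfer convention. Mean curvature is symmetric in its
arguments and is unaffected.

## Synthetic cohorts

No suitable cohort is publicly deposited, so the generator in
`cortigen.simulate` is first-class, tested code. It emulates:

* **Design**: four genotype cells with default sizes 83/11/34/16
  (neither allele / APOE only / MAPT only / both; n = 144), ages drawn
  from a normal (20.6 ± 0.9 y) truncated to [18, 24], sex coded 1 = male
  with P(male) = 0.41, education in {12, 13, 14} years (mean ≈ 12.4),
  total intracranial volume ~ N(1.45 × 10⁶, 1.2 × 10⁵) mm³.
* **Feature model**: each feature is its region's archetype baseline b
  plus `b·noise_sd·(covariate terms + genotype shifts + ε)`, ε ~ N(0,1)
  i.i.d. All planted shifts are in residual-sd units (Cohen's d), so
  power is independent of the metrics' physical scales. `noise_sd` is a
  coefficient of variation, default 0.05.
* **Archetypes**: the 34 bilateral parcels belong to four morphological
  archetypes — medium/thick/smooth (temporal, insular, mid-frontal
  regions), large/thin/smooth, small/thick/convoluted, and
  medium/thin/convoluted — giving the clustering stage recoverable
  structure. Baselines are realistic orders of magnitude (areas
  1300–4200 mm², thickness 2.3–2.9 mm, curvature 0.115–0.158 mm⁻¹).
* **Planted effects** (defaults): carriers have thinner cortex
  (−0.3 sd APOE, −0.2 sd MAPT) and higher curvature and folding index
  (+0.3/+0.2 sd); double carriers additionally gain +0.5 sd curvature
  and folding index, but only in the medium/thick/smooth archetype's
  regions. Effect magnitudes are conventions — the literature reports
  directions, not sizes, for this age group.
* **Volumes** scale linearly with TIV, which is why the univariate scan
  adds TIV as a covariate for volume features.

What the generator does **not** emulate: spatial covariance between
regions (features are conditionally independent given the design;
an obvious gap relative to real cortex, where neighbouring regions
co-vary), measurement artefacts, site/scanner effects, and any
genotype structure beyond two carrier flags. Passing tests therefore
show the pipeline is correct and calibrated under the stated model, not
that real data would yield the same power.

## Screening and leakage control

Within each cross-validation fold every feature is regressed on the
genotype flag plus age, sex, education (ordinary linear model, identity
link); features with a group-term p < 0.05 (uncorrected — this is a
within-fold screen, not an inference) are kept, and both splits are
z-scored with the training split's mean/sd. The screen and constants are
computed from training rows only; `benchmarks.leakage_probe` verifies
bit-identity under held-out label shuffling. The screen's p-values are
computed by a vectorised least-squares t-test (one 5-column solve for
all 286 features), which the tests pin against normal-equations and
statsmodels oracles to 1e-10; the vectorisation is what makes
permutation calibration studies feasible on one CPU.

## Classification and permutation inference

Stratified 5-fold CV (fold sizes and per-fold positive counts within 1),
linear SVC with C = 1, no class weighting. Held-out predictions and
decision values are pooled over folds into one confusion matrix before
computing accuracy, sensitivity, specificity, PPV, NPV, F-score and AUC
(Mann–Whitney rank form, midranks for ties). Ratios with zero
denominators are reported as 0 and flagged. With unbalanced classes the
majority-class collapse (sensitivity 0, specificity 1) is expected for
weak feature sets and is visible, not hidden.

Permutation p-values re-run the *entire* pipeline — fold split,
screening, normalisation, SVM — per label permutation. The default rule
is the literal one (proportion of null draws strictly exceeding the
observed value), which can return exactly 0 and is anti-conservative
under heavy ties; `tie_rule="plus_one"` gives the standard
(r+1)/(n_perm+1) correction. Calibration at the study's n = 144 with 99
permutations is nominal for all seven metrics (5% ± 2% over 500 null
cohorts, re-verified by the acceptance suite).

Per-fold hyperplanes are re-expanded to full feature space (zeros for
screened-out features) and averaged; region importance is the sum of
absolute averaged coefficients over a region's metrics, and per-metric
direction is summarised by separate positive and negative coefficient
sums.

## GHSOM clustering

Regions are clustered on 4-dimensional profiles (area, thickness,
curvature, folding index). Z-scoring uses one mean/sd per metric pooled
over participants × regions: pooling is what lets region means differ
after standardisation, so the cohort-mean profiles retain archetype
structure. (A per-(region, metric) policy is available; it produces
deviation profiles whose cohort means are identically zero, useless for
training but meaningful for distances.) Subcortical volumes are excluded
— clusters are cortical profiles.

The map starts at 2×2 and is trained by batch SOM (Gaussian
neighbourhood shrinking linearly from half the grid size to 0.3 over 200
epochs) followed by neighbourhood-free Lloyd iterations to convergence,
with empty prototypes reseeded at the worst-quantised point. Breadth
growth inserts an interpolated row/column between the highest-error node
and its most dissimilar grid neighbour until map MQE < tau1 × parent
error (default tau1 = 0.6); a step that fails to lower the converged MQE
is rejected and growth stops, which (with insertion preserving existing
prototypes) makes the accepted MQE sequence strictly decreasing. Nodes
with error > tau2 × root error (tau2 = 0.1) expand into child maps, kept
for inspection only: clusters are defined by the non-empty top-layer
nodes. Assignment is nearest-centroid (Euclidean), ties to the lowest
index; empty clusters are dropped and indices compacted. Everything is
deterministic given `random_state`.

The intra-cluster distance of participant i to cluster c is the mean
Euclidean distance between i's z-scored 4-vectors for c's regions and
c's centroid — a per-participant scalar of "deviation from that
morphological profile" suitable as a GLM outcome.

Because tau1/tau2, schedules and epochs have no empirical anchors, the
validated claim is cluster-recovery on planted archetypes (ARI ≥ 0.9
over 20 seeds at 4-sd separation), not any particular partition of real
cortex.

## Interaction statistics

Per cluster: `distance ~ apoe + mapt + apoe:mapt + age + sex +
education`, OLS with homoscedastic errors, genotype flags 0/1 and a
product interaction, two-sided tests, Bonferroni over the number of
clusters. Follow-up models replace the distance by the per-participant
mean of one metric over the cluster's regions. Degenerate outcomes
(zero variance) are flagged and their t/p forced to 0/1. At the design's
group sizes (83/11/34/16) a 1-residual-sd double-carrier plant in one
cluster yields simulated power around 0.4 at the Bonferroni-corrected
0.05 level — the small double-carrier cell (n = 16) is the binding
constraint — with family-wise error ≤ 0.07 under the null.

## Problem sizes and numerical choices

* Permutation calibration: 500 null cohorts × 99 permutations in the
  acceptance suite; the acceptance script reports the same study at 200
  cohorts alongside its other computations.
* Interaction operating characteristics: 500 simulations each for power
  and null FWER.
* GHSOM recovery: 20 seeds, 68 profiles, 4 archetypes at 4-sd
  separation.
* Reported tables round half-up to 2 decimals (`round_half_up`), the
  convention used when reconstructing integer confusion matrices from
  printed rates.
* Oracle tolerances: metric identities and multiplicity corrections to
  1e-12, GLM t/p to 1e-8–1e-10, distances to 1e-12.

## Known limitations

* No spatial covariance in the generator (see above).
* The GHSOM's deeper layers are not validated beyond construction; only
  the top layer is scientifically interpreted.
* The strict permutation rule is anti-conservative under ties; the
  conservative variant exists but is not the default, to preserve the
  literal definition.
* OLS interaction models assume homoscedastic errors; no robust
  standard errors are offered.
* FreeSurfer ingestion covers the aparc/aseg regional-statistics dialect
  only, not surface reconstruction or vertex-level data.
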