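# cortigen

Tools for studying how common genetic risk factors for Alzheimer's
disease shape cortical morphology decades before any pathology —
specifically, whether carrying *APOE* ε4 or the *MAPT* rs242557 A allele
is detectable in the regional morphometry of young healthy adults, and
whether the two alleles interact.

The package is aimed at imaging-genetics researchers who have (or want
to simulate) per-participant regional morphometry: for each of the 68
Desikan–Killiany cortical regions the surface area, mean thickness, mean
curvature H = (K1+K2)/2 and folding index FI = |K1|·(|K1|−|K2|), plus 14
subcortical volumes — 286 features per participant, ingestible directly
from FreeSurfer `?h.aparc.stats` / `aseg.stats` files or from a
tab-separated table.

Two analyses are implemented end to end:

* **Genotype classification.** Stratified 5-fold cross-validation; in
  each fold a covariate-adjusted screen (feature ~ group + age + sex +
  education, keep p < 0.05) and z-scoring are fitted on training rows
  only, a linear SVM (C = 1) is trained, and held-out predictions are
  pooled into one confusion matrix. Metrics (accuracy, sensitivity,
  specificity, AUC, PPV, NPV, F = 2·PPV·sens/(PPV+sens)) get
  permutation p-values by re-running the whole pipeline under label
  permutation. Hyperplane coefficients are summarised into per-region
  importance maps.
* **Gene–gene interaction.** A growing hierarchical self-organizing map
  clusters the 68 regions by their z-scored (area, thickness, curvature,
  folding-index) profiles; each participant's *intra-cluster distance*
  (mean distance of their region vectors from a cluster's centroid) is
  tested per cluster with `distance ~ APOE + MAPT + APOE:MAPT + age +
  sex + education`, Bonferroni-corrected over clusters.

Because no such cohort is publicly deposited, `cortigen.simulate`
generates cohorts with the matching design (genotype cells 83/11/34/16,
ages 18–24) and configurable planted effects, making every stage
testable. See `docs/methods.md` for the models and defaults.

## Worked example

```sh
cortigen simulate --out demo.tsv --seed 7
cortigen cluster  --table demo.tsv --seed 7
cortigen interact --distances cluster_distances.tsv --cohort demo.tsv
cortigen classify --table demo.tsv --target apoe --n-perm 99 --seed 7
```

prints

```
wrote 144 participants x 286 features to demo.tsv
4 clusters; sizes: {0: 14, 1: 18, 2: 18, 3: 18}
cluster_0: interaction t=+2.589, p=0.0107, Bonferroni p=0.0426 *
cluster_1: interaction t=+0.901, p=0.3693, Bonferroni p=1.0000
cluster_2: interaction t=+1.734, p=0.0852, Bonferroni p=0.3409
cluster_3: interaction t=+3.718, p=0.0003, Bonferroni p=0.0012 *
accuracy     0.92  (permutation p = 0.000)
sensitivity  0.67  (permutation p = 0.000)
...
auc          0.93  (permutation p = 0.000)
```

Reading this: the map recovered the four planted morphological
archetypes (4 clusters covering all 68 regions); the strongest
interaction (t = +3.72, Bonferroni p = 0.001) is in the cluster holding
the regions where the double-carrier effect was planted — double
carriers sit further from that cluster's typical morphology than the
main effects alone would predict. The classifier separates simulated
ε4 carriers from non-carriers well above chance (AUC 0.93), and every
metric beats all 99 label permutations (p = 0.000 under the strict
rule; a `(r+1)/(n+1)` tie rule is available).

The same steps are available as library calls
(`generate_cohort`/`generate_features`, `cv_classify`,
`permutation_test`, `zscore_profiles`, `GHSOM(...).fit`,
`assign_regions`, `intra_cluster_distances`, `interaction_glm`), with
scikit-learn-style estimators (`FeatureScreener`, `ScreenedLinearSVM`,
`GHSOM`) underneath.

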