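# carstim

Cytometry-driven modelling of CAR-T cell manufacturing: how the phenotype of
a T-cell blood sample and the anti-CD3/anti-CD28 stimulation dose applied
during activation shape the phenotype and cytotoxic function of the
resulting CAR-T product.

The package is aimed at computational immunologists and cell-therapy process
engineers who want to quantify — and eventually personalise — the
stimulation step of CAR-T production.  It provides:

* **A synthetic cohort generator** emulating a two-stratum study (healthy
  donors vs ALL/CLL-patient samples): 12-marker single-cell event matrices
  for blood samples and CAR-T products across a stimulation-dose range
  (0.02–0.3 mol% biotin on APC-mimetic scaffolds, optionally Dynabead
  conditions), plus luminescence killing-assay readings — all with full
  ground truth for validating every downstream stage.
* **Gating and features**: threshold gating into the standard subpopulation
  frequencies (%CD3, %CD4/%CD8, CD45RA×CCR7 and PD1×TIM3 quadrants,
  CD25/CD137/CD95 positivity, CD4:CD8 ratio, %CAR), z-scoring, and the
  70/30 splitter (ceiling convention: 35 of 49 and 40 of 56 training rows).
* **Killing-assay math**: percent cytotoxicity from luminescence triplets,

      % cytotoxicity = 100 · (1 − (sample − max-lysis) / (target-only − max-lysis)),

  assembled into E:T dose-response curves (the 1.25:1 point feeds
  attribution).
* **Single-cell cytotoxicity attribution**: each product's % cytotoxicity is
  broadcast onto its CD8⁺CAR⁺ events; pooled events are k-means clustered
  over a sweep of k (2…320); for each k a random-forest regression predicts
  cluster-mean cytotoxicity from cluster-mean marker profiles and the k with
  the highest out-of-sample explained variance is kept; cluster
  cytotoxicities are z-scored and thresholded at ±1 SD into high / moderate /
  low cytotoxic-potential classes.
* **Product-phenotype classification**: products are clustered into k = 5
  broad phenotypes; random-forest, MLP, decision-tree, naive-Bayes and
  k-nearest-neighbour classifiers predict a product's cluster from its
  donor's blood features plus the stimulation dose (pg/cell), with grid
  search, stratified tenfold CV, feature importances and a dose-only
  ablation.  A separate forest identifies healthy- vs patient-derived
  products from phenotype alone.
* **Dose prediction**: a random-forest regression maps (blood phenotype,
  desired product phenotype) → stimulation dose in pg/cell, validated
  leave-one-donor-out (LODO): per held-out donor, R² between predicted and
  actual doses over that donor's dose series, averaged across donors.

## Worked example

```python
import numpy as np
import carstim as cs

cohort = cs.generate_cohort(cs.GenerationConfig(seed=1))          # 16 donors x 6 doses
table = cs.gate_table(list(cohort.samples.values()),
                      cs.GatingStrategy(), metadata=cohort.manifest)

result = cs.attribute_stratum(
    cohort, "patient",
    cs.AttributionConfig(k_grid=cs.geometric_k_grid(2, 320, 16), seed=1))
truth = np.array([cohort.ground_truth[s].class_fractions["high"]
                  for s in result.product_fractions.index])
print(result.selected_k)                                           # 30
print(round(np.corrcoef(truth, result.product_fractions["high"])[0, 1], 3))
# 0.925
```

The selected k (30 here) is the cluster number whose cluster-mean phenotype
best explains cluster-mean cytotoxicity out of sample; 0.925 is the Pearson
correlation between the attributed per-product high-cytotoxicity fraction
and the generator's planted truth — the attribution stage recovers which
products carry cytotoxic cells, not just their average killing.

The same cohort drives the prediction side:

```python
from carstim.gating import is_feature_column
fcols = [c for c in table.columns if is_feature_column(c)]
blood = table[(table.stage == "blood") & (table.status == "patient")]
prods = table[(table.stage == "product") & (table.status == "patient")]
rows = cs.build_regression_rows(blood.reset_index(drop=True),
                                prods.reset_index(drop=True), fcols)
report = cs.leave_one_donor_out(rows, cs.DoseRegressorConfig(seed=1))
print(round(report.mean_r2, 3))                                    # 0.982
```

i.e. holding out each patient donor in turn, the forest predicts their
stimulation doses from phenotype with a mean R² of 0.982 on this synthetic
cohort (real-world values are lower; the synthetic dose laws are strong by
construction).

A `carstim` command line mirrors the library:
`carstim simulate | gate | assay | attribute | classify | predict | report`,
all seeded, exchanging CSV/JSON artifacts.

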