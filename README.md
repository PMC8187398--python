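# phenoclust

Latent-space sub-phenotyping of heterogeneous (ICU-style) patient cohorts.

The package implements a complete, reproducible analysis pipeline:

1. **Synthetic cohorts** (`phenoclust.synth`) — seeded generation of patient
   records with latent cluster structure: statics, irregular laboratory
   time-series (truncated-Poisson measurement counts, uniform times over an
   exponential length of stay), per-patient-variable missingness, optional
   heavy-tailed lab distributions, and cluster-conditional survival/AKI
   outcomes (exponential event times, administrative censoring at 90 days).
2. **Preprocessing** (`phenoclust.preprocess`) — 10% missing-variable screen,
   rolling-mean imputation on a daily grid with cohort-mean cold start,
   chained-equation (OLS) imputation for statics, per-variable mean+variance
   feature extraction, standardization, and PCA reduction.
3. **Clustering** —
   - `phenoclust.baselines`: k-means (k-means++/Lloyd with inertia trace,
     best-of-restarts), agglomerative hierarchical clustering, and
     hierarchical clustering on per-variable-averaged dynamic-time-warping
     distances;
   - `phenoclust.dec`: deep embedded clustering — a NumPy MLP autoencoder
     (hand-written backprop, SGD+momentum), k-means-initialized centroids,
     Student's-t soft assignment, squared-and-frequency-normalized target
     distribution, KL-divergence self-training (default max 8000 iterations,
     0.01 label-change tolerance), and a seeded multi-run ensemble.
4. **Validity & stability** (`phenoclust.validity`) — silhouette, cluster-size
   balance and entropy, and cluster-wise bootstrap Jaccard stability with
   stability-based selection of the number of clusters.
5. **Characterization** (`phenoclust.characterize`) — stratified
   cross-validated gradient-boosted classification of cluster membership
   (pooled out-of-fold confusion, sensitivity/specificity), best-run
   selection, and **exact interventional Shapley attributions** for tree
   ensembles (closed-form leaf decomposition, verified against brute-force
   coalition enumeration) with a seeded permutation-sampling fallback, plus
   signed per-cluster feature rankings.
6. **Outcome contrasts** (`phenoclust.outcomes`) — Kaplan–Meier curves,
   two-group log-rank tests, per-cluster O/E hazard ratios with 95% CIs
   against the cluster complement, and ANOVA / chi-squared feature tests.
7. **Pipeline & I/O** (`phenoclust.pipeline`, `phenoclust.io`,
   `phenoclust.cli`) — three-CSV cohort layout (statics/labs/outcomes),
   an end-to-end driver with a checksummed run manifest, and a Typer CLI.

Everything runs on one CPU; there is no deep-learning framework dependency.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence,
DEC normalization invariants, cluster recovery, the imbalance dissociation
between centroid methods and DEC, statistical calibration of log-rank/HR,
Shapley correctness, screening exactness, and end-to-end determinism).

## CLI

```bash
phenoclust synth out/cohort --n-patients 600 --seed 1      # write a cohort
phenoclust run out/run1 --seed 1 --fast                    # full pipeline
phenoclust cluster out/cohort --algorithm kmeans --k 6
phenoclust stability out/cohort --k-min 3 --k-max 8 --B 50
phenoclust characterize out/cohort out/run1/clusters_dec.csv
phenoclust outcomes out/cohort out/run1/clusters_dec.csv --horizon 90
```

`phenoclust run` writes features, per-algorithm cluster labels, validity and
stability reports, classifier and Shapley rankings, KM curves, hazard tables,
between-cluster tests, and a `manifest.json` with SHA-256 checksums; reruns
with the same master seed are byte-identical.

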