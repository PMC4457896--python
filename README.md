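# spotstrat

Patient stratification from two-dimensional gel electrophoresis (2-DE) spot
quantification profiles. The package implements, as a tested reusable
pipeline:

1. **%Vol normalization & replicate QC** (`spotstrat.qc`) — per-gel spot
   volumes normalized to percent of total matched volume; replicate
   agreement scored as mean %SD; best-two replicate selection with a
   configurable acceptance threshold; per-patient mean ± SD profiles;
   representative-spot selection by presence fraction.
2. **UPGMA clustering** (`spotstrat.cluster`) — average-linkage hierarchical
   clustering on Euclidean distances between patient profiles, with
   deterministic extraction of *k* main clusters plus small-branch outliers.
   The same engine serves full-profile, two-marker-spot and
   three-marker-spot stratifications.
3. **Differential statistics** (`spotstrat.stats`) — exact (enumerated)
   Mann-Whitney U for small samples, fold change with direction,
   union-rule differential-spot selection (p < 0.05 OR fold change ≥ 1.5),
   mid-rank Spearman correlation, Pearson chi-square independence test, and
   the phospho-stain ratio call (D/S < 0.08 ⇒ not phosphorylated).
4. **Linear discriminant classification** (`spotstrat.discriminant`) —
   two-group classification functions on pooled within-group covariance,
   plus a bundled published two-function model over marker spots 288/289.
5. **Clinical evaluation** (`spotstrat.clinical`) — aggressiveness classes
   (H/M/L) from treatment-line rules, cluster × class cross-tabulation,
   within-cluster and prevalence-weighted predictive values, chi-square
   association.
6. **Synthetic cohorts** (`spotstrat.synthetic`) — a generative model with
   planted ground truth: anti-correlated two-isoform marker spots driven by
   a latent modification fraction, a class-shifted third marker, log-normal
   background spots, multiplicative replicate noise with configurable CV,
   and per-patient random substreams for reproducibility.

Reference fixtures (clinical metadata, cluster memberships, published
differential means and discriminant coefficients for a 24-patient cohort)
ship under `spotstrat/data/` and are exposed via `spotstrat.datasets`.

## CLI

```sh
# generate a synthetic cohort (deterministic per seed)
spotstrat simulate --seed 7 --out-dir cohort/

# run the full pipeline; stages can be gated (qc,cluster,diff,discriminant,evaluate)
spotstrat run --spots cohort/spots.tsv --clinical cohort/clinical.tsv \
    --out-dir report/ --stages qc,cluster,diff,discriminant,evaluate

# cross-tabulate an existing cluster assignment against clinical classes
spotstrat evaluate --clusters clusters.tsv --clinical clinical.tsv
```

All inputs and outputs are tab-separated UTF-8 text with header rows; the
report directory contains `qc.tsv`, `clusters.tsv`, `differential.tsv`,
`crosstabs.tsv`, `predictive_values.tsv`, a `summary.json` with the config
echo and stage counts, and a `manifest.json` with output digests. Every
threshold is a config key (`--config run.yaml`) with the reference
defaults.

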