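# crcmb

Paired tumor/normal microbiome survival analysis, as a tested, reusable
pipeline. The package implements the analysis chain used in paired-biopsy
16S studies of colorectal-cancer survival:

* **core_io** — feature-table (TSV / BIOM-JSON) and metadata I/O, paired-cohort
  validation (depth filtering, whole-pair exclusion with a logged reason), and
  the pipeline driver.
* **synthetic_cohort** — generative paired cohorts with per-subject random
  intercepts, a tissue effect on a designated feature subset, a
  survival×tissue interaction on another, negative-binomial counts and
  log-normal sequencing depth — plus the ground truth for recovery tests.
* **preprocess** — the three feature-filter rules (prevalence/total for CTF,
  fraction/total for rPCA, relative-abundance prevalence for differential
  ranking), seeded rarefaction, and the rCLR / CLR transforms.
* **beta_diversity** — Bray-Curtis, binary Jaccard and Aitchison distances,
  paired tumor–normal distance extraction, and the intra- vs inter-individual
  permutation comparison.
* **ordination** — robust Aitchison PCA (masked alternating least squares over
  the observed rCLR entries) with held-out automatic rank selection, and a
  CP-style compositional tensor factorization for paired samples with
  subject-space distances and per-subject ΔPC extraction.
* **perm_stats** — sign-flip paired t, permutation Welch t, PERMANOVA, and
  Cohen's d; all p-values use the (b+1)/(m+1) estimator.
* **diff_ranking** — Bayesian negative-binomial differential ranking with a
  per-subject random intercept (tissue or tissue×survival design), via a fast
  vectorized MAP/Laplace mode or blocked Metropolis-within-Gibbs MCMC, plus
  the greedy extreme-feature cover selection.
* **survival_models** — ALR indices (pooled cover-based and rPCA
  communality/quartile-based), linear mixed-effects ALR models, crude/adjusted
  logistic survival regression, and score stratification
  (median/tertiles/quadrants).

## CLI

```bash
# generate a synthetic paired cohort (table.tsv, metadata.tsv, truth.tsv)
crcmb simulate --out fixtures/ --seed 7 --n-subjects 101 --n-short 50 --n-features 250

# run pipeline stages from a flat TOML config
crcmb validate  --config config.toml
crcmb model     --config config.toml --seed 7 --out results/
```

A minimal config:

```toml
table = "fixtures/table.tsv"
metadata = "fixtures/metadata.tsv"
out_dir = "results"
seed = 7
```

Stages (`validate`, `preprocess`, `betadiv`, `ordinate`, `dr`, `index`,
`model`) run in dependency order; every output file header records the seed
and filter parameters, and identical configs produce byte-identical outputs.

## Notes

* The MAP mode of `fit_differentials` pins the subject-intercept prior scale
  (the joint mode over intercepts and their scale is degenerate); MCMC keeps
  the hierarchical half-normal scale prior.
* The differential-ranking prior ("0- to 5-fold change") is translated as
  Normal(0, (ln 5 / 2)²) on the log fold change; the SD is configurable.
* Rarefaction derives per-sample substreams from one global seed keyed by
  sample ID, so results do not depend on sample order.
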