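# twinherit

Twin-based heritability analysis of gene expression, as a reusable, tested
pipeline. Given a probe × sample expression matrix from a classical twin
design (MZ/DZ pairs), it estimates per-probe and per-gene heritability with
ACE/AE/CE/E variance-component models, and provides downstream enrichment and
cross-cohort comparison. A synthetic-data generator with known ground truth
makes the whole pipeline exercisable without external data.

## What it does

- **simulate** — synthetic twin expression studies: per-probe additive-genetic
  (A), shared- (C) and unique-environment (E) variance fractions, MZ/DZ
  covariance structure (DZ genetic correlation 0.5), linear covariate effects
  (age, sex, batch, RIN, WBC), a 1–5 probes-per-gene map, detection p-values,
  and optional planted gene lists with a target enrichment odds ratio.
- **scan** — per probe: detection filter (p < 0.05 in ≥ 3 samples, strict
  inequality), OLS residualization on covariates, Blom rank inverse-normal
  transform, maximum-likelihood fits of the bivariate-normal twin models
  (ACE, AE, CE, E), AIC model selection, AE-vs-E likelihood-ratio
  heritability p-values, profile-likelihood CIs (percentile bootstrap CIs
  optional), Benjamini–Hochberg FDR, gene-level aggregation (max-h² probe
  with a fresh BH pass) and a per-chromosome summary.
- **enrich** — Fisher's exact test of FDR-significant genes against gene
  lists (conditional-ML odds ratio with exact CI, as in R's `fisher.test`),
  plus Pearson correlations of gene h² with GC content and gene length.
- **compare** — harmonizes ≥ 2 per-gene cohort summaries by version-stripped
  Ensembl id, recomputes BH-FDR within the common gene set, and reports Venn
  overlap counts, pairwise h² correlations and the top genes significant in
  every cohort.

## CLI

Each subcommand takes `--config` (YAML key/value file; unknown keys are
errors), `--seed` and `--out`, and writes a provenance log (seed, config
hash, per-stage counts). Exit codes: 0 success, 2 validation failure, 3
numerical failure.

```sh
# synthetic study: 71 MZ + 52 DZ pairs, truth table + planted gene list
twinherit simulate --config sim.yaml --seed 1 --out study/

# per-probe + per-gene heritability
twinherit scan --study-dir study/ --seed 1 --out scan/

# gene-list enrichment + h2/feature correlations
twinherit enrich --gene-results scan/gene_results.tsv \
    --annotation study/annotation.tsv \
    --gene-list study/planted_gene_list.txt --seed 1 --out enrich/

# cross-cohort comparison (summaries: ensembl_id, h2, pvalue)
twinherit compare --summary a.tsv --summary b.tsv --summary c.tsv \
    --seed 1 --out cmp/
```

All files are UTF-8 tab-separated tables with a header row; gene lists are
one symbol per line.

## Library use

```python
import numpy as np
from twinherit import TwinPairSet, heritability_test, bootstrap_ci

mz = np.array([[ 0.1,  0.3], [ 1.2,  0.9], ...])  # (n_mz, 2)
dz = np.array([[-0.5,  0.7], [ 0.2, -0.1], ...])  # (n_dz, 2)
ht = heritability_test(TwinPairSet(mz, dz))
print(ht.h2, ht.pvalue, (ht.ci_lo, ht.ci_hi))
print(bootstrap_ci(TwinPairSet(mz, dz), B=1000, seed=0))
```

Model: each pair is bivariate normal with common mean and covariance
`[[v, r·v], [r·v, v]]`, where `v = a² + c² + e²`, `r·v = a² + c²` for MZ and
`a²/2 + c²` for DZ pairs; `h² = a²/v`. Models are compared by AIC and nested
likelihood-ratio tests (central χ², df = parameter difference).
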