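# chp — candidate-SNP validation for cold–heat pattern traits

Cold–heat pattern (C-HP) is a Traditional Korean Medicine classification of
constitutional thermal sensitivity: a cold pattern (CP, chills, low energy
metabolism) and a heat pattern (HP, flushing, heat intolerance), scored by a
15-item questionnaire. No well-powered GWAS of C-HP exists, so a practical
route to genetic markers is to take SNPs reported for proxy traits —
cold/heat responses and thyroid hormone levels — and test whether they
replicate against CP/HP scores in a small, directly phenotyped cohort.

This package implements that validation pipeline as a tested library plus a
`chp` command-line tool, for statistical geneticists and traditional-medicine
researchers who want to rerun, audit or extend the analysis:

* **catalog filtering** — drop X-chromosome and duplicate reported SNPs,
  keep those present in the genotype panel;
* **association** — per SNP, OLS of the score on
  `intercept + age + sex + PC1..PC5 + dosage`, with significance from
  **Freedman–Lane residual permutation**: permute reduced-model residuals,
  add back the covariate fit, refit, and compare |t| of the dosage term;
  p = (1 + #{|t*| ≥ |t_obs|})/(B + 1), default B = 10,000, cutoff p < 0.05;
* **LD pruning** (50 kb windows, step 5, r² < 0.2) feeding PCA of the
  variance-standardized genetic relationship matrix XXᵀ/m, and **LD
  clumping** (p ≤ 1, r² ≥ 0.2, 250 kb) to keep one SNP per signal;
* **enrichment** — SNP→gene mapping, hypergeometric over-representation
  against a GMT library, combined score c = −ln(p)·z with Monte-Carlo rank
  calibration, top-5 pathways, and a **Jaccard ≥ 0.3 pathway-similarity
  network**, with a control-trait specificity comparison;
* **synthetic data** — block-LD genotype simulation (Gaussian copula),
  Balding–Nichols structured panels emulating the five continental
  reference groups, and planted-effect phenotypes, so the full pipeline is
  testable without the private cohort.

The two published candidate tables (20 HP SNPs, 19 CP SNPs) ship with the
package as TSV fixtures, transcribed verbatim.

## Worked example

Count the published candidates through the significance filter:

```python
from chp.io_formats import load_candidate_fixture
from chp.pipeline_cli import count_candidates

hp = load_candidate_fixture("HP")
print("HP candidates:", count_candidates(hp, "HP"))
print("HP thyroid:   ", count_candidates(hp, "HP", "thyroid"))
r = next(x for x in hp if x.snp == "rs12409301")
print(f"{r.snp}: gene={r.gene} beta={r.beta} se={r.se} perm_p={r.permutation_p}")
```

prints

```
HP candidates: 20
HP thyroid:    18
rs12409301: gene=CAPZB beta=2.312 se=0.976 perm_p=0.0205
```

i.e. 20 heat-pattern candidates (18 of them thyroid-hormone SNPs), and the
strongest TSH signal (rs12409301 near *CAPZB*) replicates with a 2.3-point
score increase per alt allele and permutation p ≈ 0.02.

Run the whole pipeline on a synthetic cohort at study scale (n = 90, 550
SNPs, 5 planted effects):

```sh
chp validate --seed 11 --permutations 1000 --out demo_run
```

```
run complete: demo_run
note: no multiple-testing correction is applied across SNPs
```

`demo_run/manifest.json` then records the per-stage counts, e.g. for seed
11: 550 SNPs selected and tested per score, 32 CP / 42 HP SNPs significant
at permutation p < 0.05, and 19 CP / 25 HP candidates after clumping —
around 27 of the ~550 would be expected by chance alone at α = 0.05, which
is why the planted SNPs are judged by their ranking and the control-trait
comparison exists. The run directory also contains the candidate tables
(`candidates_cp.tsv`, mirroring the published table layout), clump reports,
enrichment tables, network edge lists and PCA coordinates; `chp report
demo_run` prints a readable summary.

Other subcommands: `chp simulate`, `chp prune`, `chp pca`, `chp enrich`,
`chp network`, `chp fixture-count`.

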