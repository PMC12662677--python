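# Methods

## Problem and scope

Cold–heat pattern (C-HP) is a Traditional Korean Medicine classification of
constitutional thermal sensitivity into a cold pattern (CP) and a heat
pattern (HP). Both are scored with a 15-item questionnaire (8 CP items, 7 HP
items), and twin studies suggest the trait is substantially heritable. There
is no well-powered GWAS of C-HP itself, so a practical strategy is to take
SNPs already reported for proxy traits — cold/heat responses and thyroid
hormone levels (thyroid hormone drives thermogenesis) — and test whether they
replicate against CP/HP scores in a small, directly phenotyped cohort.

This package implements that validation pipeline end to end:

1. catalog filtering of reported SNPs,
2. per-SNP covariate-adjusted linear regression with residual-permutation
   significance,
3. LD pruning (for PCA) and LD clumping (for independent signals),
4. SNP→gene mapping and gene-set over-representation with combined scores,
5. Jaccard pathway-similarity networks and a control-trait specificity
   comparison,
6. genotype PCA for both covariate PCs and population-structure
   visualization.

The original cohort (N = 90) is private, so a first-class synthetic-data
module generates inputs with the same statistical structure; the two
published candidate tables ship with the package as TSV fixtures.

## Statistical model

For each SNP j and score y ∈ {CP, HP} we fit by ordinary least squares

    y = β0 + β_age·age + β_sex·sex + Σ_k γ_k·PC_k + β_j·g_j + ε,

where g_j is the alt-allele dosage (0/1/2) and PC_1..PC_5 are principal
components of the LD-pruned, variance-standardized genotype matrix.
Standard errors are classical (σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−k)); the
asymptotic p comes from t(n−k).

### Residual permutation (Freedman–Lane)

At n = 90 the asymptotic null is not trusted, so significance uses the
Freedman–Lane scheme: fit the reduced model y ~ Z (covariates only), keep
its fitted values and residuals, and for each of B permutations π form
y* = ŷ_Z + π(r_Z), refit y* ~ Z + g, and record |t*| of the genotype term.
The permutation p is add-one corrected,

    p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1),

so p ≥ 1/(B+1) and is never exactly zero. Freedman–Lane permutes residuals
of the *reduced* model and adds back the covariate fit, which preserves the
covariate structure under the null; it is the standard covariate-respecting
permutation scheme, adopted here because the source procedure names only
"residual permutation" without further detail. The implementation projects
through an orthonormal basis of Z (QR) and uses Frisch–Waugh algebra so all
B refits reduce to vectorized matrix products; results are identical to
naive refitting.

Default B = 10,000; the calibration and power checks in the test suite use
B = 1,000 to keep runtimes at desk scale, which changes only the granularity
of the p-values (1/1001 vs 1/10001).

Missing genotypes are handled per SNP by complete-case analysis (samples
with a missing call at that SNP are dropped for that SNP only), and MAF is
computed on the analyzed samples. No multiple-testing correction is applied
across SNPs — the published procedure used a raw permutation p < 0.05
cutoff (strict inequality) — and the CLI prints a warning to that effect.

### Catalog filtering

Reported-SNP records are filtered in this order: X-chromosome records
removed; duplicate rsIDs collapsed to the record with the smallest reported
p (tie: first in file order); records absent from the genotype panel
removed. Every exclusion is logged with a machine-readable reason
(`x_chromosome`, `duplicate`, `not_genotyped`).

### LD, pruning, clumping

LD is the squared Pearson correlation of dosages over pairwise-complete
samples (composite r²) — the appropriate unphased measure. Pruning uses
50 kb windows advanced by 5 markers with r² < 0.2: within a window, while
any surviving pair violates the threshold, the lower-MAF member is removed
(tie: larger position). The removal rule is pinned down here because the
upstream tool flag leaves it to the implementation; sweeps repeat until no
within-window violation survives, making the operation idempotent.

Clumping is greedy on p-value order (ties: smaller position, then id):
the best unassigned SNP indexes a clump and captures every unassigned SNP
with p ≤ 1, within 250 kb, on the same chromosome, and r² ≥ 0.2 *to the
index* (no transitive chaining). The pipeline clumps the
permutation-significant set by default and orders by permutation p; a
config switch (`clump_before_filter`) supports the other stage order, since
the published description is ambiguous on whether clumping preceded the
significance filter.

### PCA

Genotypes are variance-standardized per variant, x = (g − 2p̂)/√(2p̂(1−p̂)),
with missing entries set to 0 after centering and monomorphic or
zero-variance variants dropped. The GRM is XXᵀ/m; eigendecomposition is
exact (`numpy.linalg.eigh` — at cohort and reference-panel scale there is
no need for randomized solvers). Coordinates are unit-norm eigenvectors
(optionally scaled by √λ), with each component's sign fixed so its
largest-magnitude entry is positive, making plots and tests stable.

### Enrichment and networks

Over-representation uses the upper hypergeometric tail P(X ≥ k) with the
library's gene universe as background (an explicit background can be
supplied); enrichment is one-sided by construction, so no two-sided Fisher
variant is offered. Odds ratios use a Haldane 0.5 correction when a cell of
the 2×2 table is zero. The combined score is c = −ln(p)·z, where z is a
rank-deviation score calibrated by Monte Carlo: R random gene lists of the
query size are ranked by p, giving each term an expected rank and rank SD;
z = (expected − observed)/SD (z := 0 when SD = 0). The published scores came
from an external enrichment service whose exact calibration and library
version are not recomputable locally; this score is a documented
reconstruction of that family of statistics, and the package does not claim
to reproduce the published combined-score values.

The top-5 pathways (smallest p; ties by larger c, then name) per score feed
a similarity network with an edge wherever the Jaccard coefficient of two
pathways' gene sets is ≥ 0.3. The control-trait comparison reruns the same
machinery per trait and tabulates tested/significant counts, ratios, top
pathways and network density side by side.

SNP→gene mapping is a static one-gene-per-SNP annotation table (the
published mapping used a live variant-to-gene API; candidate tables report
exactly one gene per SNP, so multi-gene mappings are out of scope).

## Synthetic data: what it emulates and what it does not

* **Unstructured cohort genotypes** — Gaussian-copula thresholding: latent
  AR(1) Gaussians (correlation ρ, default 0.8, within blocks of 10 variants,
  independent across blocks) cut at Hardy–Weinberg quantiles of a target
  alt frequency drawn from the MAF range (default 0.05–0.5). This gives
  controllable r² decay with distance but no recombination-map realism, no
  mutation/demography, and LD that is blockwise by construction.
* **Structured panel** — Balding–Nichols: per-variant ancestral frequency p,
  population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
  Binomial(2, p_pop). Default sizes mirror the five continental reference
  groups (EUR 533, EAS 539, AMR 373, SAS 544, AFR 719) with F = 0.1. The
  model's F is verified against the Hudson Fst estimator in the tests. All
  populations diverge symmetrically from one ancestor — there is no
  admixture or population tree, so the "most diverged pair" in PC space is a
  property of the realization, not of history.
* **Phenotypes** — score = intercept + Σ β·dosage + β_age·age + β_sex·sex +
  N(0, σ). Age ~ Normal(50, 10) truncated to [19, 80]; sex ~ Bernoulli(0.5)
  (both unstated in the source and configurable). Scores are continuous;
  item-level questionnaire simulation is not attempted, and the association
  machinery is scale-agnostic. Default σ = 4 gives planted effects of
  |β| ≈ 2–4 with SE ≈ 1 at n = 90, matching the magnitude of the published
  candidate-table estimates; power and recovery checks use σ = 1, the
  condition under which a β = 3 effect is reliably detectable at n = 90.
* **Catalogs and gene sets** — category-weighted trait assignment with
  configurable injected chrX/duplicate rows (to exercise the filters), and
  random gene sets over synthetic symbols with an optional planted enriched
  term.

Defaults n = 90 and m = 550 mirror the study scale. Because the synthetic
generator is the only available stand-in for the private cohort, passing
tests demonstrate that the *procedure* is correct and calibrated under its
stated assumptions — not that the published per-SNP estimates would
reproduce on real data.

## Numerical choices

* Permutation p uses the add-one estimator; permuted |t*| are compared with
  |t_obs| − 1e−12 to make ties count conservatively.
* OLS is solved by `lstsq`; rank deficiency and n ≤ k are hard errors, not
  warnings. The statsmodels OLS implementation serves as a cross-check in
  the tests, not as the fitting path (the permutation loop needs the
  vectorized Frisch–Waugh form).
* Master seed → per-stage seeds by CRC32 hashing of the stage name (kept
  below 2³¹), so each stage is independently reproducible.
* Eigenvalues are clipped at −1e−8 from below only for the optional
  √λ scaling; the reported spectrum is unclipped.
* Coordinates are 1-based; window and clump distances are inclusive
  differences of POS values.
* Multi-allelic VCF records are rejected by default (flag to split); the
  candidate SNP set is biallelic.

## Problem sizes used in the checks

Calibration: 500 null SNPs, n = 90, B = 1,000. Power: 10 replicates,
n = 90, B = 1,000, unit noise. Recovery: n = 2,000. Structured panel:
2,708 samples × 500 variants. Full-pipeline signal check: 5 planted SNPs
among 500, 10 replicates. These sizes make the whole suite runnable on a
laptop in well under half an hour.

## Known limitations

* No kinship/mixed-model correction: the cohort is assumed unrelated.
* The combined score is a reconstruction (see above); its absolute values
  are not comparable to the published ones.
* One gene per SNP; no GO-DAG propagation or term hierarchy.
* The effect allele is taken to be the VCF alt allele; published effect
  alleles for the same rsID can differ across studies and ancestries, and
  the candidate-table fixtures store the printed allele columns verbatim
  without reinterpretation (some printed "MAF" values appear to be
  effect-allele frequencies; they are stored under the printed column name).
* Strict-inequality filtering at α and no FDR control mirror the published
  procedure; with ~550 tests per score the expected false-positive count
  under the global null is ≈ 27, which is why the control-trait comparison
  and permutation calibration exist.
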