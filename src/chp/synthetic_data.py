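"""Synthetic genotype/phenotype/catalog/gene-set generators.

The study cohort (90 Korean patients with CHPIQ-derived cold-pattern and
heat-pattern scores, genotyped at ~550 GWAS-reported SNPs) is not public, so
every downstream stage of the pipeline is exercised on synthetic data with
the same statistical structure:

* genotypes with block linkage disequilibrium via a Gaussian copula whose
  latent variables follow an AR(1) correlation within blocks, thresholded at
  Hardy-Weinberg genotype quantiles for the target allele frequency;
* a structured multi-population panel under the Balding-Nichols model
  (population allele frequencies Beta-distributed around an ancestral
  frequency with divergence parameter Fst), emulating the five continental
  reference groups;
* continuous phenotype scores driven by age, sex, a handful of planted SNP
  effects and Gaussian noise;
* reported-SNP catalogs with deliberately injected chrX and duplicate rows
  so the selection filters have something to remove;
* gene-set libraries with an optional planted enriched term.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import (
    CatalogRecord,
    GeneSetLibrary,
    GenotypeMatrix,
    VariantMeta,
)
import pandas as pd

#: Default study scale: sample and variant counts matching the validation cohort.
DEFAULT_N_SAMPLES = 90
DEFAULT_N_VARIANTS = 550

#: Continental panel sizes of the phase-3 reference populations.
REFERENCE_POPULATIONS = {"EUR": 533, "EAS": 539, "AMR": 373, "SAS": 544, "AFR": 719}


@dataclass(frozen=True)
class LDBlockSpec:
    """Within-block latent AR(1) correlation structure for simulated LD."""

    block_size: int = 10
    rho: float = 0.8
    spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.spacing_bp < 1:
            raise ValueError("spacing_bp must be >= 1")


@dataclass(frozen=True)
class PopulationSpec:
    """Labels, sizes and Balding-Nichols divergence for a structured panel."""

    sizes: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_POPULATIONS)
    )
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        for label, n in self.sizes.items():
            if n < 2:
                raise ValueError(f"population {label} must have >= 2 samples")


@dataclass(frozen=True)
class PhenoModelSpec:
    """Linear phenotype model: score = intercept + SNP effects + age + sex + noise.

    Effect sizes are per alt-allele dosage in score units; the default noise
    scale gives planted effects of |beta| around 2-4 with standard errors
    near 1 at n = 90, the magnitude seen in the published candidate tables.
    """

    causal_effects: dict[str, float] = field(default_factory=dict)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    intercept: float = 20.0
    noise_sd: float = 4.0
    score_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _hwe_thresholds(p_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-normal cut points putting HWE mass on dosages 0/1/2."""
    q0 = (1.0 - p_alt) ** 2
    q1 = 2.0 * p_alt * (1.0 - p_alt)
    t0 = stats.norm.ppf(np.clip(q0, 1e-12, 1 - 1e-12))
    t1 = stats.norm.ppf(np.clip(q0 + q1, 1e-12, 1 - 1e-12))
    return t0, t1


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld: LDBlockSpec | None = None,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Simulate an unstructured cohort with block-LD genotypes.

    Latent per-sample Gaussians follow an AR(1) process with correlation
    ``ld.rho`` between adjacent variants inside a block and independence
    across blocks; each latent value is thresholded at the Hardy-Weinberg
    quantiles of a per-variant target alt-allele frequency drawn uniformly
    from ``maf_range``.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 samples and m >= 1 variants")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    ld = ld or LDBlockSpec()
    rng = np.random.default_rng(seed)

    p_alt = rng.uniform(lo, hi, size=m)
    # AR(1) latent field: z_j = rho * z_{j-1} + sqrt(1-rho^2) * eps at block
    # interiors, fresh draw at block starts.
    eps = rng.standard_normal((n, m))
    z = np.empty((n, m))
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        if j % ld.block_size == 0:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = ld.rho * z[:, j - 1] + np.sqrt(1 - ld.rho**2) * eps[:, j]

    t0, t1 = _hwe_thresholds(p_alt)
    dosages = (z > t0).astype(float) + (z > t1)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan

    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])
    variants = [
        VariantMeta(
            id=f"rsS{j + 1}",
            chrom=chrom,
            pos=start_pos + j * ld.spacing_bp,
            ref=ref[j],
            alt=alt[j],
        )
        for j in range(m)
    ]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def simulate_structured_genotypes(
    spec: PopulationSpec,
    m: int,
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 100_000,
) -> tuple[GenotypeMatrix, list[str]]:
    """Simulate a multi-population panel under the Balding-Nichols model.

    Each variant has an ancestral alt frequency p drawn from ``maf_range``;
    every population draws its own frequency from
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` and genotypes are ``Binomial(2, p_pop)``.

    Returns the genotype matrix and the per-sample population labels.
    """
    rng = np.random.default_rng(seed)
    F = spec.fst
    lo, hi = spec.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    samples: list[str] = []
    for pop, size in spec.sizes.items():
        p_pop = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        blocks.append(rng.binomial(2, p_pop, size=(size, m)).astype(float))
        labels.extend([pop] * size)
        samples.extend(f"{pop}_{i + 1:04d}" for i in range(size))

    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([x for x in bases if x != r]) for r in ref])
    variants = [
        VariantMeta(
            id=f"rsP{j + 1}", chrom=chrom, pos=1_000_000 + j * spacing_bp,
            ref=ref[j], alt=alt[j],
        )
        for j in range(m)
    ]
    gm = GenotypeMatrix(
        samples=samples, variants=variants, dosages=np.vstack(blocks)
    )
    return gm, labels


def simulate_phenotypes(
    gm: GenotypeMatrix,
    spec: PhenoModelSpec | None = None,
    seed: int = 0,
    score: str = "both",
) -> pd.DataFrame:
    """Simulate CP/HP scores from genotypes under the linear phenotype model.

    Age is Normal(50, 10) truncated to [19, 80]; sex is Bernoulli(0.5).
    ``score`` selects which score carries the genetic signal ("cp", "hp" or
    "both"); the other score is pure covariates + noise.
    """
    spec = spec or PhenoModelSpec()
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    for snp in spec.causal_effects:
        if snp not in gm:
            raise KeyError(f"causal SNP {snp!r} not in genotype matrix")

    age = stats.truncnorm.rvs(
        (19 - 50) / 10, (80 - 50) / 10, loc=50, scale=10, size=n, random_state=rng
    )
    sex = rng.integers(0, 2, size=n).astype(float)

    genetic = np.zeros(n)
    for snp, beta in spec.causal_effects.items():
        dose = np.nan_to_num(gm.column(snp), nan=0.0)
        genetic = genetic + beta * dose
    covar = spec.intercept + spec.age_effect * age + spec.sex_effect * sex

    def draw(with_signal: bool) -> np.ndarray:
        y = covar + (genetic if with_signal else 0.0)
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.score_bounds is not None:
            y = np.clip(y, *spec.score_bounds)
        return y

    cp = draw(score in ("cp", "both"))
    hp = draw(score in ("hp", "both"))
    return pd.DataFrame(
        {
            "sample": gm.samples,
            "cp_score": cp,
            "hp_score": hp,
            "age": age,
            "sex": sex.astype(int),
        }
    )


DEFAULT_TRAITS = {
    "thyroid": ["Thyroid-stimulating hormone", "Thyroxine", "Triiodothyronine"],
    "cold_heat": ["Response to cold", "Cold sensitivity", "Cold-induced vasodilation"],
    "control": ["Body height", "Hair color", "Myopia"],
}


def simulate_catalog(
    gm: GenotypeMatrix,
    categories: dict[str, float] | None = None,
    seed: int = 0,
    chrx_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
) -> list[CatalogRecord]:
    """Assign each variant a reported trait/category; optionally inject chrX
    and duplicate rows so the selection filters are exercised.

    ``categories`` maps category name to sampling weight (default: thyroid-
    dominated, mirroring the composition of the reported-SNP pool).
    """
    categories = categories or {"thyroid": 0.8, "cold_heat": 0.2}
    if not categories:
        raise ValueError("categories must be non-empty")
    rng = np.random.default_rng(seed)
    names = list(categories)
    weights = np.array([categories[c] for c in names], dtype=float)
    weights /= weights.sum()

    records: list[CatalogRecord] = []
    for v in gm.variants:
        cat = names[rng.choice(len(names), p=weights)]
        trait = DEFAULT_TRAITS.get(cat, [cat])[rng.integers(0, len(DEFAULT_TRAITS.get(cat, [cat])))]
        records.append(
            CatalogRecord(
                snp=v.id,
                chrom=v.chrom,
                pos=v.pos,
                trait=trait,
                category=cat,
                effect_allele=v.alt,
                reported_beta=float(np.round(rng.normal(0, 0.05), 4)),
                reported_p=float(10.0 ** -rng.uniform(6, 30)),
            )
        )

    n_x = int(round(chrx_fraction * gm.n_variants))
    for i in range(n_x):
        cat = names[rng.choice(len(names), p=weights)]
        records.append(
            CatalogRecord(
                snp=f"rsX{i + 1}",
                chrom="X",
                pos=int(rng.integers(1_000_000, 100_000_000)),
                trait=DEFAULT_TRAITS.get(cat, [cat])[0],
                category=cat,
                effect_allele="A",
                reported_beta=None,
                reported_p=float(10.0 ** -rng.uniform(6, 30)),
            )
        )

    n_dup = int(round(duplicate_fraction * gm.n_variants))
    if n_dup:
        picks = rng.choice(len(records), size=n_dup, replace=False)
        for i in picks:
            r = records[i]
            records.append(
                CatalogRecord(
                    snp=r.snp,
                    chrom=r.chrom,
                    pos=r.pos,
                    trait=r.trait,
                    category=r.category,
                    effect_allele=r.effect_allele,
                    reported_beta=r.reported_beta,
                    reported_p=min(1.0, r.reported_p * 10.0),
                )
            )
    return records


def simulate_gene_sets(
    n_terms: int,
    size_range: tuple[int, int] = (5, 50),
    background_size: int = 500,
    planted_overlap: float = 0.0,
    planted_genes: list[str] | None = None,
    seed: int = 0,
) -> GeneSetLibrary:
    """Simulate a gene-set library over synthetic gene symbols.

    With ``planted_overlap`` > 0 and a ``planted_genes`` list, the library
    gains a term ``PLANTED`` containing ``round(overlap * len(planted_genes))``
    of the planted genes (padded with random background genes up to the
    minimum term size).
    """
    lo, hi = size_range
    if hi > background_size:
        raise ValueError("size_range max must be <= background_size")
    rng = np.random.default_rng(seed)
    background = [f"G{i + 1:05d}" for i in range(background_size)]
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(background, size=size, replace=False)
        name = f"TERM_{t + 1:04d}"
        terms[name] = frozenset(genes.tolist())
        descriptions[name] = "synthetic gene set"

    full_background = set(background)
    if planted_genes:
        full_background |= set(planted_genes)
        n_overlap = int(round(planted_overlap * len(planted_genes)))
        if n_overlap > len(planted_genes):
            raise ValueError("planted overlap exceeds planted gene list")
        chosen = list(planted_genes[:n_overlap])
        pad = max(lo - len(chosen), 0)
        if pad:
            extra = rng.choice(
                [g for g in background if g not in chosen], size=pad, replace=False
            )
            chosen.extend(extra.tolist())
        if chosen:
            terms["PLANTED"] = frozenset(chosen)
            descriptions["PLANTED"] = "synthetic planted enriched term"

    return GeneSetLibrary(
        terms=terms,
        descriptions=descriptions,
        background=frozenset(full_background),
    )


def simulate_annotation(
    gm: GenotypeMatrix, seed: int = 0, gene_pool: list[str] | None = None
) -> dict[str, str]:
    """One synthetic gene symbol per variant (the SNP-to-gene annotation)."""
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        return {v.id: f"G{j + 1:05d}" for j, v in enumerate(gm.variants)}
    picks = rng.choice(gene_pool, size=gm.n_variants, replace=True)
    return {v.id: g for v, g in zip(gm.variants, picks)}
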