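"""Per-SNP covariate-adjusted linear association with residual-permutation
significance, plus the catalog-selection filters and the significant-SNP
ratio used for control-trait specificity.

The regression model for each SNP is

    score ~ intercept + age + sex + PC1..PC5 + dosage

fitted by ordinary least squares. With only 90 samples the asymptotic
t-distribution of the dosage coefficient is unreliable, so significance is
assessed by Freedman-Lane residual permutation: the reduced model (covariates
only) is fitted once, its residuals are permuted and added back to the
reduced fit, the full model is refitted on each permuted response, and the
permutation p-value is the add-one-corrected fraction of permuted |t|
statistics at least as large as the observed one. This preserves the
covariate structure under the null and never returns an exact zero
(p >= 1/(B+1)).

No multiple-testing correction is applied across SNPs; the published
procedure used a raw 0.05 cutoff on permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CatalogRecord, GenotypeMatrix
from . import ld_pca

logger = logging.getLogger(__name__)


@dataclass
class OLSFit:
    """Ordinary least-squares fit: coefficients, classical SEs, t, p."""

    coefficients: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    df_resid: int


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP association summary mirroring the candidate-table columns."""

    snp: str
    a1: str  # effect (alt) allele
    a2: str
    alt_freq: float
    maf: float
    beta: float
    se: float
    t: float
    p_asymptotic: float
    permutation_p: float
    n_analyzed: int


@dataclass(frozen=True)
class PermutationSpec:
    """Residual-permutation settings: iteration count and seed.

    The permuted statistic is the absolute t of the genotype term.
    """

    B: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def select_reported_snps(
    catalog: list[CatalogRecord], gm: GenotypeMatrix
) -> tuple[list[CatalogRecord], list[tuple[str, str]]]:
    """Apply the reported-SNP selection filters.

    Drops X-chromosome records, collapses duplicate rsIDs to the record with
    the smallest reported p (ties: first in file order), and drops records
    absent from the genotype panel. Returns (retained records, filter log of
    (snp, reason) pairs).
    """
    log: list[tuple[str, str]] = []
    autosomal = []
    for rec in catalog:
        if rec.chrom == "X":
            log.append((rec.snp, "x_chromosome"))
        else:
            autosomal.append(rec)

    best: dict[str, CatalogRecord] = {}
    for rec in autosomal:
        prev = best.get(rec.snp)
        if prev is None:
            best[rec.snp] = rec
        elif rec.reported_p < prev.reported_p:
            log.append((prev.snp, "duplicate"))
            best[rec.snp] = rec
        else:
            log.append((rec.snp, "duplicate"))

    kept = []
    for rec in best.values():
        if rec.snp in gm:
            kept.append(rec)
        else:
            log.append((rec.snp, "not_genotyped"))
    return kept, log


def compute_maf(dosage: np.ndarray) -> tuple[float, float]:
    """Alt-allele frequency over non-missing entries and MAF = min(f, 1-f)."""
    dosage = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(dosage)
    if not ok.any():
        raise ValueError("all genotypes missing")
    f = float(dosage[ok].mean() / 2.0)
    return f, min(f, 1.0 - f)


def fit_linear(y: np.ndarray, X: np.ndarray) -> OLSFit:
    """OLS with classical covariance: SE from sigma^2 (X'X)^-1, p from t(n-k)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(
        coefficients=beta, se=se, t=t, p=p, residuals=resid, fitted=fitted,
        df_resid=df,
    )


def residual_permutation(
    y: np.ndarray,
    Z: np.ndarray,
    g: np.ndarray,
    spec: PermutationSpec | None = None,
) -> float:
    """Freedman-Lane permutation p-value for the genotype term.

    Fits the reduced model y ~ Z, permutes its residuals B times, adds back
    the reduced fit, refits y* ~ Z + g, and compares |t*| of g with the
    observed |t|. Returns (1 + #{|t*| >= |t_obs|}) / (B + 1).

    ``Z`` must include the intercept column; ``g`` must be polymorphic.
    """
    spec = spec or PermutationSpec()
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.shape[0]
    if np.ptp(g) == 0:
        raise ValueError("no_variation: genotype is constant among analyzed samples")

    # Orthonormal basis of the covariate space; all projections go through it.
    Q, _ = np.linalg.qr(Z)
    k_full = Z.shape[1] + 1
    df = n - k_full
    if df <= 0:
        raise ValueError("not enough samples for the full model")

    g_perp = g - Q @ (Q.T @ g)
    gg = float(g_perp @ g_perp)
    if gg <= 1e-12:
        raise ValueError("no_variation: genotype is collinear with covariates")

    def t_of(y_vec_perp: np.ndarray) -> float:
        # y_vec_perp = M_Z y; t of g via Frisch-Waugh on the residualized pair.
        num = float(g_perp @ y_vec_perp)
        rss = float(y_vec_perp @ y_vec_perp) - num * num / gg
        sigma2 = rss / df
        return num / np.sqrt(gg * max(sigma2, 1e-300))

    y_perp = y - Q @ (Q.T @ y)
    t_obs = abs(t_of(y_perp))

    # Permuted responses are fit_reduced + perm(resid_reduced); after
    # projecting out Z the fitted part vanishes, so only the permuted
    # residual vector matters.
    r_red = y_perp  # residuals of the reduced model
    rng = np.random.default_rng(spec.seed)
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (spec.B, n)).copy(), axis=1
    )
    R = r_red[perms]  # B x n permuted residuals
    MR = R - (R @ Q) @ Q.T  # project out covariates
    num = MR @ g_perp
    rss = np.einsum("ij,ij->i", MR, MR) - num * num / gg
    sigma2 = np.maximum(rss / df, 1e-300)
    t_star = np.abs(num / np.sqrt(gg * sigma2))
    count = int((t_star >= t_obs - 1e-12).sum())
    return (1 + count) / (spec.B + 1)


def _design(pheno: pd.DataFrame, pcs: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(pheno)), pheno["age"].to_numpy(float), pheno["sex"].to_numpy(float)]
    if pcs is not None and pcs.shape[1] > 0:
        cols.extend(pcs[:, c] for c in range(pcs.shape[1]))
    return np.column_stack(cols)


def run_association(
    gm: GenotypeMatrix,
    pheno: pd.DataFrame,
    score: str,
    n_pcs: int = 5,
    spec: PermutationSpec | None = None,
    pcs: np.ndarray | None = None,
    prune_spec: "ld_pca.PruneSpec | None" = None,
) -> list[AssocResult]:
    """Covariate-adjusted association of every variant with one score.

    ``score`` is "CP" or "HP". The design is intercept + age + sex + the top
    ``n_pcs`` principal components of the LD-pruned standardized genotype
    matrix + dosage. Samples with a missing genotype at a SNP are dropped for
    that SNP only (complete-case per SNP); MAF is computed on the analyzed
    samples. SNPs that cannot be tested (monomorphic, collinear) are logged
    and skipped.
    """
    spec = spec or PermutationSpec()
    score = score.upper()
    if score not in ("CP", "HP"):
        raise ValueError("score must be 'CP' or 'HP'")
    if list(pheno["sample"]) != list(gm.samples):
        pheno = pheno.set_index("sample").loc[gm.samples].reset_index()
    y_all = pheno[f"{score.lower()}_score"].to_numpy(float)

    if pcs is None and n_pcs > 0:
        pcs = ld_pca.pca(
            gm, k=n_pcs, prune_first=prune_spec or ld_pca.PruneSpec()
        ).coordinates
    elif pcs is not None:
        pcs = pcs[:, :n_pcs]

    results: list[AssocResult] = []
    ss = np.random.SeedSequence(spec.seed)
    snp_seeds = ss.generate_state(gm.n_variants)
    for j, v in enumerate(gm.variants):
        g = gm.dosages[:, j]
        ok = ~np.isnan(g)
        y = y_all[ok]
        gv = g[ok]
        Z = _design(pheno, pcs)[ok]
        try:
            f, maf = compute_maf(gv)
            fit = fit_linear(y, np.column_stack([Z, gv]))
            perm_p = residual_permutation(
                y, Z, gv, PermutationSpec(B=spec.B, seed=int(snp_seeds[j]) % (2**31))
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", v.id, exc)
            continue
        results.append(
            AssocResult(
                snp=v.id,
                a1=v.alt,
                a2=v.ref,
                alt_freq=f,
                maf=maf,
                beta=float(fit.coefficients[-1]),
                se=float(fit.se[-1]),
                t=float(fit.t[-1]),
                p_asymptotic=float(fit.p[-1]),
                permutation_p=perm_p,
                n_analyzed=int(ok.sum()),
            )
        )
    return results


def filter_significant(
    results: list[AssocResult], alpha: float = 0.05
) -> list[AssocResult]:
    """Retain results with permutation p strictly below alpha."""
    return [r for r in results if r.permutation_p < alpha]


def significant_ratio(
    results_by_category: dict[str, list[AssocResult]], alpha: float = 0.05
) -> dict[str, float]:
    """Significant-SNP ratio per category plus the combined ratio.

    The combined ratio pools all listed categories: total significant over
    total tested.
    """
    out: dict[str, float] = {}
    total_sig = total_n = 0
    for cat, results in results_by_category.items():
        if not results:
            raise ValueError(f"category {cat!r} has no tested SNPs")
        sig = len(filter_significant(results, alpha))
        out[cat] = sig / len(results)
        total_sig += sig
        total_n += len(results)
    out["combined"] = total_sig / total_n
    return out
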