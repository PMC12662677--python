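"""Linkage disequilibrium (r-squared), window pruning, p-value clumping, and
genotype PCA on the variance-standardized genetic relationship matrix.

LD is the squared Pearson correlation of unphased alt-allele dosages over
pairwise-complete samples (composite r-squared) — the appropriate measure
when phase is unknown. Pruning removes variants greedily until no pair
inside a sliding window exceeds the r-squared threshold; clumping groups
association results around p-value-ordered index SNPs within a distance and
r-squared gate, keeping one representative per signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneSpec:
    """Sliding-window pruning parameters (window in kb, step in markers)."""

    window_kb: float = 50.0
    step_markers: int = 5
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.window_kb <= 0 or self.step_markers <= 0 or self.r2_threshold <= 0:
            raise ValueError("all pruning parameters must be positive")


@dataclass(frozen=True)
class ClumpSpec:
    """Greedy clumping parameters: membership p ceiling, r2 gate, kb radius."""

    p2: float = 1.0
    r2: float = 0.2
    kb: float = 250.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p2 <= 1.0):
            raise ValueError("p2 must be in (0, 1]")
        if not (0.0 < self.r2 <= 1.0):
            raise ValueError("r2 must be in (0, 1]")
        if self.kb <= 0:
            raise ValueError("kb must be > 0")


@dataclass
class Clump:
    """One independent signal: an index SNP and its LD-linked members."""

    index_snp: str
    index_p: float
    members: list[tuple[str, float]]  # (snp id, p), index included


@dataclass
class PCAResult:
    """Eigenvalues (descending) and per-sample coordinates for top-k PCs."""

    eigenvalues: np.ndarray
    coordinates: np.ndarray  # n_samples x k
    variant_ids: list[str]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    x, y = g1[ok], g2[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("ld_r2 requires two polymorphic vectors on shared samples")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _alt_freqs(dosages: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosages, axis=0) / 2.0


def prune(gm: GenotypeMatrix, spec: PruneSpec | None = None) -> list[str]:
    """Greedy window-based LD pruning; returns the surviving variant ids.

    Windows span ``window_kb`` from each start marker and advance by
    ``step_markers``; while any kept pair within a window has r-squared at or
    above the threshold, the member with the lower MAF is removed (tie: the
    one at the larger position). After completion no within-window pair of
    survivors violates the threshold.
    """
    spec = spec or PruneSpec()
    order = sorted(range(gm.n_variants), key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos))
    for chrom in {v.chrom for v in gm.variants}:
        pos = [gm.variants[j].pos for j in order if gm.variants[j].chrom == chrom]
        if pos != sorted(pos):  # cannot happen after sort; guards future edits
            raise ValueError("variants must be position-sorted per chromosome")

    freqs = _alt_freqs(gm.dosages)
    maf = np.minimum(freqs, 1 - freqs)
    kept = set(range(gm.n_variants))
    window_bp = spec.window_kb * 1000.0

    by_chrom: dict[str, list[int]] = {}
    for j in order:
        by_chrom.setdefault(gm.variants[j].chrom, []).append(j)

    def sweep() -> bool:
        removed_any = False
        for chrom_idx in by_chrom.values():
            for s in range(0, len(chrom_idx), spec.step_markers):
                start = chrom_idx[s]
                window = [
                    j for j in chrom_idx[s:]
                    if gm.variants[j].pos - gm.variants[start].pos <= window_bp
                ]
                active = [j for j in window if j in kept]
                changed = True
                while changed:
                    changed = False
                    for a in range(len(active)):
                        for b in range(a + 1, len(active)):
                            i, j = active[a], active[b]
                            try:
                                r2 = ld_r2(gm.dosages[:, i], gm.dosages[:, j])
                            except ValueError:
                                continue  # monomorphic columns carry no LD
                            if r2 >= spec.r2_threshold:
                                drop = _prune_victim(gm, maf, i, j)
                                kept.discard(drop)
                                active.remove(drop)
                                removed_any = changed = True
                                break
                        if changed:
                            break
        return removed_any

    # Repeat sweeps until stable so the post-condition holds across window
    # overlaps, not only within a single pass.
    while sweep():
        pass
    return [gm.variants[j].id for j in order if j in kept]


def _prune_victim(gm: GenotypeMatrix, maf: np.ndarray, i: int, j: int) -> int:
    if maf[i] < maf[j]:
        return i
    if maf[j] < maf[i]:
        return j
    return i if gm.variants[i].pos > gm.variants[j].pos else j


def clump(
    results,
    gm: GenotypeMatrix,
    spec: ClumpSpec | None = None,
    p_attr: str = "permutation_p",
) -> list[Clump]:
    """Greedy p-value-ordered LD clumping of association results.

    Results are sorted by p ascending (ties: smaller position, then id); the
    best unassigned SNP becomes an index, and every unassigned SNP with
    p <= p2, on the same chromosome within ``kb`` of the index, and with
    r-squared to the index at or above ``r2``, joins its clump. Membership is
    assessed against the index only (no transitive chaining).
    """
    spec = spec or ClumpSpec()
    entries = []
    for res in results:
        snp = getattr(res, "snp", None) or getattr(res, "id")
        if snp not in gm:
            raise KeyError(f"result SNP {snp!r} has no genotype column")
        v = gm.variant(snp)
        entries.append((float(getattr(res, p_attr)), v.pos, snp, v.chrom))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    assigned: set[str] = set()
    clumps: list[Clump] = []
    for p, pos, snp, chrom in entries:
        if snp in assigned:
            continue
        members: list[tuple[str, float]] = [(snp, p)]
        assigned.add(snp)
        g_index = gm.column(snp)
        for p2, pos2, snp2, chrom2 in entries:
            if snp2 in assigned or chrom2 != chrom:
                continue
            if p2 > spec.p2 or abs(pos2 - pos) > spec.kb * 1000.0:
                continue
            try:
                r2 = ld_r2(g_index, gm.column(snp2))
            except ValueError:
                continue
            if r2 >= spec.r2:
                members.append((snp2, p2))
                assigned.add(snp2)
        clumps.append(Clump(index_snp=snp, index_p=p, members=members))
    return clumps


def standardize(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Variance-standardize dosages: x = (g - 2p) / sqrt(2p(1-p)).

    Allele frequencies are computed on non-missing entries; missing values
    become 0 after centering (mean imputation on the standardized scale).
    Monomorphic variants are dropped with a log entry. Returns the n x m'
    standardized matrix and the ids of the variants used.
    """
    freqs = _alt_freqs(gm.dosages)
    with np.errstate(invalid="ignore"):
        spread = np.nanstd(gm.dosages, axis=0)
    poly = (freqs > 0) & (freqs < 1) & (spread > 0) & ~np.isnan(freqs)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("standardize: dropped %d monomorphic variants", n_dropped)
    X = gm.dosages[:, poly].copy()
    p = freqs[poly]
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    X[np.isnan(X)] = 0.0
    ids = [v.id for v, keep in zip(gm.variants, poly) if keep]
    return X, ids


def pca(
    gm: GenotypeMatrix,
    k: int = 5,
    prune_first: PruneSpec | None = None,
    scale_by_eigenvalue: bool = False,
) -> PCAResult:
    """PCA of the genetic relationship matrix GRM = X X^T / m on standardized
    genotypes, optionally after LD pruning.

    Coordinates are unit-norm eigenvectors (or scaled by sqrt(eigenvalue));
    the sign of each component is fixed so its largest-magnitude entry is
    positive.
    """
    if k >= gm.n_samples:
        raise ValueError(f"k = {k} must be < n_samples = {gm.n_samples}")
    work = gm
    if prune_first is not None:
        kept = prune(gm, prune_first)
        work = gm.subset_variants(kept)
    X, ids = standardize(work)
    if not ids:
        raise ValueError("no polymorphic variants available for PCA")
    grm = X @ X.T / len(ids)
    evals, evecs = np.linalg.eigh(grm)
    idx = np.argsort(evals)[::-1][:k]
    evals, evecs = evals[idx], evecs[:, idx]
    for c in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] = -evecs[:, c]
    coords = evecs * np.sqrt(np.maximum(evals, 0.0)) if scale_by_eigenvalue else evecs
    return PCAResult(eigenvalues=evals, coordinates=coords, variant_ids=ids)
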