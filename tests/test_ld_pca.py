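"""LD r2 properties, pruning post-condition/idempotence, clumping against a
brute-force oracle, standardization arithmetic, and GRM-based PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chp import synthetic_data as sd
from chp.io_formats import GenotypeMatrix, VariantMeta
from chp.ld_pca import (
    Clump,
    ClumpSpec,
    PruneSpec,
    clump,
    ld_r2,
    pca,
    prune,
    standardize,
)


def make_gm(columns, positions, chrom="1"):
    cols = np.array(columns, dtype=float).T
    variants = [
        VariantMeta(id=f"v{j}", chrom=chrom, pos=int(p), ref="A", alt="G")
        for j, p in enumerate(positions)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(cols.shape[0])],
        variants=variants,
        dosages=cols,
    )


class TestLDr2:
    def test_self_correlation_is_one(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 3, 50).astype(float), rng.integers(0, 3, 50).astype(float)
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a))

    def test_independent_variants_have_negligible_r2(self):
        gm = sd.simulate_genotypes(5000, 2, ld=sd.LDBlockSpec(rho=0.0, block_size=1),
                                   seed=1)
        assert ld_r2(gm.dosages[:, 0], gm.dosages[:, 1]) < 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(10), np.arange(10) % 3)

    def test_pairwise_complete_handling(self):
        g1 = np.array([0, 1, 2, np.nan, 1])
        g2 = np.array([0, 1, 2, 0, np.nan])
        assert ld_r2(g1, g2) == pytest.approx(1.0)


def no_violating_pair(gm, kept, spec):
    """Exhaustive post-scan: no surviving pair within any window has
    r2 >= threshold."""
    kept_idx = [j for j, v in enumerate(gm.variants) if v.id in set(kept)]
    for a in range(len(kept_idx)):
        for b in range(a + 1, len(kept_idx)):
            i, j = kept_idx[a], kept_idx[b]
            vi, vj = gm.variants[i], gm.variants[j]
            if vi.chrom != vj.chrom:
                continue
            if abs(vi.pos - vj.pos) > spec.window_kb * 1000:
                continue
            try:
                r2 = ld_r2(gm.dosages[:, i], gm.dosages[:, j])
            except ValueError:
                continue
            if r2 >= spec.r2_threshold:
                return False
    return True


class TestPrune:
    def test_duplicated_variant_pair_loses_one(self):
        g = [0, 1, 2, 1, 0, 1, 2, 0]
        gm = make_gm([g, g], [1000, 2000])
        assert len(prune(gm)) == 1

    def test_uncorrelated_variants_all_survive(self):
        gm = sd.simulate_genotypes(500, 10, ld=sd.LDBlockSpec(rho=0.0, block_size=1),
                                   seed=2)
        assert len(prune(gm)) == 10

    def test_post_condition_on_random_instances(self):
        spec = PruneSpec()
        for seed in range(5):
            gm = sd.simulate_genotypes(
                120, 50, ld=sd.LDBlockSpec(block_size=8, rho=0.85), seed=seed
            )
            kept = prune(gm, spec)
            assert no_violating_pair(gm, kept, spec)

    def test_idempotent(self):
        gm = sd.simulate_genotypes(100, 40, ld=sd.LDBlockSpec(block_size=8, rho=0.9),
                                   seed=3)
        kept = prune(gm)
        gm2 = gm.subset_variants(kept)
        assert prune(gm2) == kept

    def test_lower_maf_member_removed(self):
        rng = np.random.default_rng(4)
        common = rng.binomial(2, 0.5, 200).astype(float)
        rare = common.copy()
        rare[common == 1] = rng.binomial(1, 0.2, (common == 1).sum()) * 2.0
        # rare is correlated with common but has lower MAF
        gm = make_gm([common, rare], [1000, 2000])
        kept = prune(gm)
        from chp.association import compute_maf

        if ld_r2(common, rare) >= 0.2:
            mafs = {"v0": compute_maf(common)[1], "v1": compute_maf(rare)[1]}
            assert kept == [min(mafs, key=mafs.get) == "v0" and "v1" or "v0"]


def brute_force_clump(entries, r2_lookup, spec):
    """Naive restatement of the clumping rule, independent of the
    implementation: p-ordered greedy assignment against the index only."""
    entries = sorted(entries, key=lambda e: (e["p"], e["pos"], e["snp"]))
    assigned, clumps = set(), []
    for e in entries:
        if e["snp"] in assigned:
            continue
        members = [(e["snp"], e["p"])]
        assigned.add(e["snp"])
        for o in entries:
            if o["snp"] in assigned or o["chrom"] != e["chrom"]:
                continue
            if o["p"] > spec.p2 or abs(o["pos"] - e["pos"]) > spec.kb * 1000:
                continue
            if r2_lookup[frozenset((e["snp"], o["snp"]))] >= spec.r2:
                members.append((o["snp"], o["p"]))
                assigned.add(o["snp"])
        clumps.append((e["snp"], members))
    return clumps


class FakeResult:
    def __init__(self, snp, p):
        self.snp, self.permutation_p = snp, p


class TestClump:
    def _random_instance(self, seed, m):
        rng = np.random.default_rng(seed)
        gm = sd.simulate_genotypes(
            80, m, ld=sd.LDBlockSpec(block_size=4, rho=0.9, spacing_bp=100_000),
            seed=seed,
        )
        results = [FakeResult(v.id, float(rng.uniform(0, 0.3))) for v in gm.variants]
        return gm, results

    def test_one_clump_when_all_linked(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        gm = make_gm([g, g, g], [100_000, 150_000, 200_000])
        results = [FakeResult("v0", 1e-8), FakeResult("v1", 1e-4), FakeResult("v2", 0.03)]
        clumps = clump(results, gm)
        assert len(clumps) == 1 and clumps[0].index_snp == "v0"
        assert len(clumps[0].members) == 3

    def test_distance_gate(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        gm = make_gm([g, g], [100_000, 400_000])  # 300 kb apart, r2 = 1
        clumps = clump([FakeResult("v0", 1e-4), FakeResult("v1", 1e-3)], gm)
        assert len(clumps) == 2

    def test_r2_gate(self):
        gm = sd.simulate_genotypes(3000, 2, ld=sd.LDBlockSpec(rho=0.1, block_size=2),
                                   seed=6)
        r2 = ld_r2(gm.dosages[:, 0], gm.dosages[:, 1])
        assert r2 < 0.2  # rho=0.1 latent correlation keeps dosage r2 low
        ids = gm.variant_ids
        clumps = clump([FakeResult(ids[0], 1e-4), FakeResult(ids[1], 1e-3)], gm)
        assert len(clumps) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(2, 12))
    def test_matches_brute_force_on_small_instances(self, seed, m):
        gm, results = self._random_instance(seed, m)
        spec = ClumpSpec()
        got = clump(results, gm, spec)
        r2_lookup = {}
        for a in range(m):
            for b in range(a + 1, m):
                try:
                    r2 = ld_r2(gm.dosages[:, a], gm.dosages[:, b])
                except ValueError:
                    r2 = 0.0
                r2_lookup[frozenset((gm.variant_ids[a], gm.variant_ids[b]))] = r2
        entries = [
            {"snp": r.snp, "p": r.permutation_p,
             "pos": gm.variant(r.snp).pos, "chrom": gm.variant(r.snp).chrom}
            for r in results
        ]
        expected = brute_force_clump(entries, r2_lookup, spec)
        assert [(c.index_snp, sorted(c.members)) for c in got] == [
            (i, sorted(m_)) for i, m_ in expected
        ]

    def test_missing_genotype_column_rejected(self, tiny_gm):
        with pytest.raises(KeyError):
            clump([FakeResult("rs_nope", 0.01)], tiny_gm)


class TestStandardize:
    def test_hand_evaluated_column(self):
        gm = make_gm([[0, 1, 2, 1]], [1000])
        X, ids = standardize(gm)
        # p = 0.5: (g - 1) / sqrt(0.5)
        np.testing.assert_allclose(X[:, 0], [-1.41421356, 0, 1.41421356, 0])
        assert ids == ["v0"]

    def test_monomorphic_dropped(self):
        gm = make_gm([[1, 1, 1, 1], [0, 1, 2, 1]], [1000, 2000])
        X, ids = standardize(gm)
        assert ids == ["v1"] and X.shape == (4, 1)

    def test_columns_centered(self, cohort_gm):
        X, _ = standardize(cohort_gm)
        assert np.abs(X.mean(axis=0)).max() < 1e-10

    def test_missing_becomes_zero(self):
        gm = make_gm([[0, 1, 2, np.nan]], [1000])
        X, _ = standardize(gm)
        assert X[3, 0] == 0.0


class TestPCA:
    def test_grm_diagonal_near_one_for_unstructured_data(self):
        gm = sd.simulate_genotypes(200, 500, ld=sd.LDBlockSpec(rho=0.0, block_size=1),
                                   seed=7)
        X, ids = standardize(gm)
        grm = X @ X.T / len(ids)
        np.testing.assert_allclose(grm, grm.T)
        assert 0.8 < np.trace(grm) / 200 < 1.2

    def test_eigenvalue_sum_matches_trace(self):
        gm = sd.simulate_genotypes(40, 80, seed=8)
        res = pca(gm, k=39)  # all non-trivial components of a 40-sample GRM
        X, ids = standardize(gm)
        grm = X @ X.T / len(ids)
        # the one excluded eigenvalue is bounded by the smallest retained one
        assert res.eigenvalues.sum() <= np.trace(grm) + 1e-6
        full = np.linalg.eigvalsh(grm)
        np.testing.assert_allclose(res.eigenvalues.sum() + full[0], np.trace(grm),
                                   atol=1e-6)

    def test_coordinates_orthogonal_and_eigenvalues_descending(self, cohort_gm):
        res = pca(cohort_gm, k=5)
        gram = res.coordinates.T @ res.coordinates
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-6)
        assert np.all(np.diff(res.eigenvalues) <= 1e-8)
        assert np.all(res.eigenvalues >= -1e-8)

    def test_sign_convention_largest_loading_positive(self, cohort_gm):
        res = pca(cohort_gm, k=3)
        for c in range(3):
            col = res.coordinates[:, c]
            assert col[np.argmax(np.abs(col))] > 0

    def test_two_population_separation(self):
        spec = sd.PopulationSpec(sizes={"A": 150, "B": 150}, fst=0.25)
        gm, labels = sd.simulate_structured_genotypes(spec, 500, seed=9)
        res = pca(gm, k=2)
        lab = np.array(labels)
        pc1 = res.coordinates[:, 0]
        within = np.sqrt((pc1[lab == "A"].var() + pc1[lab == "B"].var()) / 2)
        gap = abs(pc1[lab == "A"].mean() - pc1[lab == "B"].mean()) / within
        assert gap > 2

    def test_k_must_be_less_than_n(self, tiny_gm):
        with pytest.raises(ValueError):
            pca(tiny_gm, k=4)
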