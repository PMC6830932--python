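"""Kinship (PI_HAT), related-sample exclusion, MDS, density outliers."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from panelassoc import (
    CONTROL,
    MDSCoordinates,
    estimate_kinship,
    exclude_related,
    kinship_matrix,
    mds_components,
    outlier_filter,
)
from panelassoc.simulate import (
    SyntheticConfig,
    planted_duplicate_pairs,
    planted_outlier_indices,
    planted_relative_pairs,
    simulate_genotypes,
)

from conftest import make_matrix


@pytest.fixture(scope="module")
def related_panel():
    cfg = SyntheticConfig(n_cases=40, n_controls=40, n_variants=1000,
                          maf_range=(0.1, 0.5), missing_rate=0.0,
                          n_duplicates=2, n_relative_pairs=3, seed=21)
    return cfg, simulate_genotypes(cfg)


class TestKinship:
    def test_planted_duplicates_pi_hat_near_one(self, related_panel):
        cfg, g = related_panel
        pi, _, _ = kinship_matrix(g)
        for a, b in planted_duplicate_pairs(cfg):
            assert abs(pi[a, b] - 1.0) < 0.02

    def test_planted_relatives_pi_hat_near_half(self, related_panel):
        cfg, g = related_panel
        pi, _, _ = kinship_matrix(g)
        for a, b in planted_relative_pairs(cfg):
            assert abs(pi[a, b] - 0.5) < 0.1

    def test_unrelated_pairs_near_zero(self):
        # PI_HAT noise scales as 1/sqrt(variants); at a few thousand variants
        # independent HWE samples estimate within 0.1 of zero
        cfg = SyntheticConfig(n_cases=6, n_controls=6, n_variants=4000,
                              maf_range=(0.1, 0.5), missing_rate=0.0, seed=30)
        g = simulate_genotypes(cfg)
        pi, _, _ = kinship_matrix(g)
        vals = [pi[i, j] for i in range(g.n_samples)
                for j in range(i + 1, g.n_samples)]
        assert max(vals) < 0.1

    def test_pairwise_estimate_symmetric(self, related_panel):
        _, g = related_panel
        a, b = g.samples[0].id, g.samples[1].id
        e_ab = estimate_kinship(g, (a, b))
        e_ba = estimate_kinship(g, (b, a))
        assert e_ab.pi_hat == pytest.approx(e_ba.pi_hat, abs=1e-12)
        assert e_ab.ibs_distance == pytest.approx(e_ba.ibs_distance, abs=1e-12)

    def test_ibd_probs_clamped_and_normalized(self, related_panel):
        _, g = related_panel
        e = estimate_kinship(g, (g.samples[0].id, g.samples[1].id))
        for p in (e.p_ibd0, e.p_ibd1, e.p_ibd2):
            assert 0 <= p <= 1
        assert e.p_ibd0 + e.p_ibd1 + e.p_ibd2 == pytest.approx(1.0, abs=1e-9)
        assert e.pi_hat == pytest.approx(e.p_ibd1 / 2 + e.p_ibd2, abs=1e-12)

    def test_too_few_variants_is_domain_error(self):
        g = make_matrix([[0], [1]], phenotypes=[CONTROL] * 2)
        with pytest.raises(ValueError):
            estimate_kinship(g, ("s0", "s1"))


class TestExcludeRelated:
    def test_planted_duplicate_removes_exactly_one(self):
        cfg = SyntheticConfig(n_cases=20, n_controls=20, n_variants=600,
                              maf_range=(0.1, 0.5), missing_rate=0.0,
                              n_duplicates=1, seed=22)
        g = simulate_genotypes(cfg)
        out, excluded = exclude_related(g)
        assert len(excluded) == 1
        (a, b), = planted_duplicate_pairs(cfg)
        assert excluded[0] in {g.samples[a].id, g.samples[b].id}
        assert out.n_samples == g.n_samples - 1

    def test_no_flagged_pairs_is_identity(self):
        cfg = SyntheticConfig(n_cases=15, n_controls=15, n_variants=500,
                              maf_range=(0.1, 0.5), missing_rate=0.0, seed=23)
        g = simulate_genotypes(cfg)
        out, excluded = exclude_related(g)
        assert excluded == []
        assert out.n_samples == g.n_samples

    def test_chain_resolved_and_recheck_passes(self):
        # A ~ B ~ C chain via genotype copies: B duplicates A, C duplicates B
        rng = np.random.default_rng(24)
        base = rng.binomial(2, rng.uniform(0.1, 0.5, 500), (1, 500))[0]
        others = rng.binomial(2, rng.uniform(0.1, 0.5, 500), (5, 500))
        codes = np.vstack([base, base, base, others])
        g = make_matrix(codes, phenotypes=[CONTROL] * 8)
        out, excluded = exclude_related(g)
        pi, _, _ = kinship_matrix(out)
        iu = np.triu_indices(out.n_samples, k=1)
        assert (pi[iu] <= 0.25).all()
        assert len(excluded) == 2  # minimal vertex cover of the triangle


class TestMDS:
    def test_planted_ancestry_clusters_separate_on_c1(self):
        cfg = SyntheticConfig(n_cases=60, n_controls=60, n_variants=300,
                              maf_range=(0.1, 0.4), missing_rate=0.0,
                              n_ancestry_outliers=30, outlier_shift=0.3, seed=25)
        g = simulate_genotypes(cfg)
        coords = mds_components(g, k=4)
        c1 = coords.component(1)
        shifted = np.array(planted_outlier_indices(cfg))
        main = np.setdiff1d(np.arange(g.n_samples), shifted)
        assert (c1[shifted].min() > c1[main].max()
                or c1[shifted].max() < c1[main].min())

    def test_embedding_recovered_up_to_rotation(self):
        # classical MDS of distances from known 2-D points: Procrustes error ~ 0
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(20, 2))
        pts -= pts.mean(axis=0)
        d = squareform(pdist(pts))
        # feed the distance matrix through the same double-centering code path
        from panelassoc import relatedness as rel

        n = len(pts)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(-evals)
        coords = evecs[:, order[:2]] * np.sqrt(np.clip(evals[order[:2]], 0, None))
        r, _ = orthogonal_procrustes(coords, pts)
        assert np.abs(coords @ r - pts).max() < 1e-6

    def test_regular_simplex_equal_eigenvalues_stable_order(self):
        # 4 mutually equidistant samples: one-hot-like genotypes give equal
        # pairwise distances; eigenvalues of the centered matrix are equal
        codes = 2 * np.eye(4, dtype=np.int8)
        g = make_matrix(codes, phenotypes=[CONTROL] * 4)
        coords = mds_components(g, k=3)
        ev = coords.eigenvalues
        assert np.allclose(ev, ev[0], rtol=1e-9)
        coords2 = mds_components(g, k=3)
        assert np.array_equal(coords.coords, coords2.coords)

    def test_degenerate_identical_samples_rejected(self):
        g = make_matrix(np.ones((5, 10), dtype=np.int8), phenotypes=[CONTROL] * 5)
        with pytest.raises(ValueError):
            mds_components(g, k=2)

    def test_sign_convention_reproducible(self):
        cfg = SyntheticConfig(n_cases=20, n_controls=20, n_variants=200,
                              missing_rate=0.0, seed=27)
        g = simulate_genotypes(cfg)
        c_a = mds_components(g, k=4)
        c_b = mds_components(g, k=4)
        assert np.array_equal(c_a.coords, c_b.coords)
        for c in range(4):
            col = c_a.coords[:, c]
            assert col[np.argmax(np.abs(col))] >= 0


class TestOutlierFilter:
    def _coords(self, n_cloud=200, outliers=5, seed=28):
        rng = np.random.default_rng(seed)
        cloud = rng.normal(0, 1, size=(n_cloud, 2))
        far = rng.normal(8, 0.5, size=(outliers, 2))
        xy = np.vstack([cloud, far])
        coords = np.column_stack([xy[:, 0], np.zeros(len(xy)), xy[:, 1],
                                  np.zeros(len(xy))])
        ids = tuple(f"s{i}" for i in range(len(xy)))
        return MDSCoordinates(sample_ids=ids, coords=coords,
                              eigenvalues=np.array([4.0, 3.0, 2.0, 1.0]))

    def test_planted_distant_points_exactly_recovered(self):
        coords = self._coords()
        n = len(coords.sample_ids)
        kept, removed = outlier_filter(coords, which=(1, 3),
                                       density_quantile=5 / n,
                                       transform="identity")
        assert set(removed) == {f"s{i}" for i in range(200, 205)}

    def test_normal_score_transform_still_targets_planted_points(self):
        # rank transformation compresses extreme values, so exact recovery is
        # not guaranteed; the removed set should still be dominated by the plant
        coords = self._coords()
        n = len(coords.sample_ids)
        _, removed = outlier_filter(coords, which=(1, 3), density_quantile=5 / n)
        planted = {f"s{i}" for i in range(200, 205)}
        assert len(planted & set(removed)) >= 3

    def test_quantile_zero_removes_nothing(self):
        coords = self._coords()
        kept, removed = outlier_filter(coords, which=(1, 3), density_quantile=0.0)
        assert removed == []
        assert len(kept) == len(coords.sample_ids)

    def test_removal_monotone_in_quantile(self):
        coords = self._coords()
        counts = [len(outlier_filter(coords, which=(1, 3), density_quantile=q)[1])
                  for q in (0.0, 0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_identity_transform_option(self):
        coords = self._coords()
        n = len(coords.sample_ids)
        _, removed = outlier_filter(coords, which=(1, 3),
                                    density_quantile=5 / n, transform="identity")
        assert set(removed) == {f"s{i}" for i in range(200, 205)}

    def test_singular_covariance_rejected(self):
        coords = MDSCoordinates(
            sample_ids=("a", "b", "c"),
            coords=np.column_stack([np.arange(3.0), np.zeros(3),
                                    np.arange(3.0), np.zeros(3)]),
            eigenvalues=np.ones(4))
        with pytest.raises(ValueError):
            outlier_filter(coords, which=(1, 3), transform="identity")
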