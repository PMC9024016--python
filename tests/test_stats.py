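"""Correlation statistics: Pearson/partial oracles, BH-FDR, region summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import disconnectome as dc

SHAPE = (5, 5, 4)  # 100 voxels


def grid():
    return dc.VolumeGrid(SHAPE, np.eye(4))


def maps_from_matrix(X):
    """Turn an (n_subjects, n_voxels) matrix into ScalarVolumes."""
    g = grid()
    return [dc.ScalarVolume(g, x.reshape(SHAPE)) for x in X]


def full_mask():
    return dc.BinaryMask(grid(), np.ones(SHAPE, dtype=np.uint8))


def brute_force_pearson(x, y):
    r = np.corrcoef(x, y)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def brute_force_partial(x, y, c):
    """Residualize-then-correlate oracle with polyfit residuals."""
    Z = np.column_stack([np.ones(len(c)), c])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 3)
    return r, p


def brute_force_bh(p, alpha):
    """BH by definition: q_i = min_{j>=i} m p_(j) / j, reject q < alpha."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


class TestVoxelwiseCorrelation:
    def test_perfect_positive_linear(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 100))
        res = dc.voxelwise_correlation(maps_from_matrix(X),
                                       maps_from_matrix(2 * X + 3), full_mask())
        assert np.allclose(res.r, 1.0)

    def test_perfect_negative(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 100))
        res = dc.voxelwise_correlation(maps_from_matrix(X),
                                       maps_from_matrix(-X), full_mask())
        assert np.allclose(res.r, -1.0)

    def test_hand_computed_small_case(self):
        """n=5 worked example against the closed-form Pearson formula."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        X = np.tile(x[:, None], (1, 100))
        Y = np.tile(y[:, None], (1, 100))
        res = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                       full_mask())
        r_ref, p_ref = brute_force_pearson(x, y)
        assert abs(res.r.ravel()[0] - r_ref) < 1e-12
        assert abs(res.p.ravel()[0] - p_ref) < 1e-12

    def test_matches_brute_force_per_voxel(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 100))
        Y = rng.normal(size=(6, 100))
        res = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                       full_mask())
        for v in range(0, 100, 7):
            r_ref, p_ref = brute_force_pearson(X[:, v], Y[:, v])
            assert abs(res.r.ravel()[v] - r_ref) < 1e-12
            assert abs(res.p.ravel()[v] - p_ref) < 1e-12

    def test_zero_variance_voxels_flagged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 100))
        X[:, 0] = 1.0  # constant x at voxel 0
        Y = rng.normal(size=(6, 100))
        res = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                       full_mask())
        assert res.r.ravel()[0] == 0.0
        assert res.p.ravel()[0] == 1.0
        assert res.degenerate.ravel()[0]

    def test_affine_rescaling_invariance_and_sign_flip(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 100))
        Y = rng.normal(size=(8, 100))
        base = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                        full_mask())
        scaled = dc.voxelwise_correlation(maps_from_matrix(3.2 * X + 1),
                                          maps_from_matrix(Y), full_mask())
        flipped = dc.voxelwise_correlation(maps_from_matrix(-2.0 * X),
                                           maps_from_matrix(Y), full_mask())
        assert np.allclose(scaled.r, base.r, atol=1e-12)
        assert np.allclose(flipped.r, -base.r, atol=1e-12)

    def test_unpaired_collections_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 100))
        with pytest.raises(ValueError, match="unpaired"):
            dc.voxelwise_correlation(maps_from_matrix(X),
                                     maps_from_matrix(X[:5]), full_mask())

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3, 100))
        with pytest.raises(ValueError, match=">= 4"):
            dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(X),
                                     full_mask())


class TestPartialCorrelation:
    def test_x_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(8)
        c = rng.normal(size=10)
        X = np.tile(c[:, None], (1, 100))
        Y = rng.normal(size=(10, 100))
        res = dc.voxelwise_partial_correlation(maps_from_matrix(X),
                                               maps_from_matrix(Y), c, full_mask())
        assert np.max(np.abs(res.r)) < 1e-9

    def test_small_case_matches_brute_force(self):
        """n=6 worked case against the residualize-then-correlate oracle."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 100))
        Y = rng.normal(size=(6, 100))
        c = rng.normal(size=6)
        res = dc.voxelwise_partial_correlation(maps_from_matrix(X),
                                               maps_from_matrix(Y), c, full_mask())
        for v in range(0, 100, 11):
            r_ref, p_ref = brute_force_partial(X[:, v], Y[:, v], c)
            assert abs(res.r.ravel()[v] - r_ref) < 1e-12
            assert abs(res.p.ravel()[v] - p_ref) < 1e-12

    def test_independent_covariate_approximates_plain_r(self):
        """With a covariate independent of both maps and large n, the
        partial correlation is close to the plain correlation."""
        rng = np.random.default_rng(10)
        n = 200
        X = rng.normal(size=(n, 100))
        Y = 0.5 * X + rng.normal(size=(n, 100))
        c = rng.normal(size=n)
        plain = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                         full_mask())
        partial = dc.voxelwise_partial_correlation(
            maps_from_matrix(X), maps_from_matrix(Y), c, full_mask())
        assert np.max(np.abs(plain.r - partial.r)) <= 0.05

    def test_constant_covariate_warns_and_reduces_to_plain(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 100))
        Y = rng.normal(size=(8, 100))
        plain = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                         full_mask())
        with pytest.warns(UserWarning, match="constant"):
            partial = dc.voxelwise_partial_correlation(
                maps_from_matrix(X), maps_from_matrix(Y), np.ones(8), full_mask())
        assert np.allclose(partial.r, plain.r, atol=1e-12)


class TestFdrCorrect:
    def test_worked_example(self):
        q, rej = dc.fdr_correct(np.array([0.01, 0.02, 0.03, 0.5]), 0.05)
        assert rej.tolist() == [True, True, True, False]

    def test_all_ones_nothing_rejected(self):
        q, rej = dc.fdr_correct(np.ones(10), 0.05)
        assert not rej.any() and np.all(q == 1.0)

    def test_single_p_m_equals_one(self):
        q, rej = dc.fdr_correct(np.array([0.04]), 0.05)
        assert rej[0] and abs(q[0] - 0.04) < 1e-15

    def test_empty_input(self):
        q, rej = dc.fdr_correct(np.array([]), 0.05)
        assert len(q) == 0 and len(rej) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dc.fdr_correct(np.array([0.0, 0.5]), 0.05)

    def test_matches_brute_force_definition_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1.0, m)
            q, rej = dc.fdr_correct(p, 0.05)
            q_ref, rej_ref = brute_force_bh(p, 0.05)
            assert np.max(np.abs(q - q_ref)) < 1e-12
            assert np.array_equal(rej, rej_ref)

    def test_q_geq_p_and_downward_closed_rejections(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, 500)
        q, rej = dc.fdr_correct(p, 0.05)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        flags = rej[order]
        # once a sorted p is not rejected, none after it is
        if flags.any():
            last = np.max(np.nonzero(flags))
            assert flags[: last + 1].all()

    def test_null_rejection_proportion_controlled(self):
        """Global null: realized BH rejection fraction stays within
        alpha + 3 binomial SE across 20 replicate seeds."""
        n, v, alpha = 50, 2000, 0.05
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(n, v))
            Y = rng.normal(size=(n, v))
            xc = X - X.mean(0)
            yc = Y - Y.mean(0)
            r = (xc * yc).sum(0) / np.sqrt((xc**2).sum(0) * (yc**2).sum(0))
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * sps.t.sf(np.abs(t), n - 2)
            _, rej = dc.fdr_correct(p, alpha)
            fracs.append(rej.mean())
        se = np.sqrt(alpha * (1 - alpha) / v)
        assert np.mean(fracs) <= alpha + 3 * se


class TestResultInvariants:
    def test_q_geq_p_and_sig_subset_of_mask(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 100))
        Y = 0.6 * X + rng.normal(size=(20, 100))
        mask_data = np.zeros(SHAPE, dtype=np.uint8)
        mask_data.ravel()[:60] = 1
        mask = dc.BinaryMask(grid(), mask_data)
        res = dc.voxelwise_correlation(maps_from_matrix(X), maps_from_matrix(Y),
                                       mask)
        inmask = mask.data > 0
        assert np.all(res.q[inmask] >= res.p[inmask] - 1e-15)
        assert np.all(res.sig.data[~inmask] == 0)
        assert np.all(np.abs(res.r[inmask]) <= 1)
        assert res.r[~inmask].max() == 0  # outside mask untouched


class TestRegionMax:
    def test_constant_region_fully_significant(self):
        g = grid()
        labels = np.zeros(SHAPE, dtype=int)
        labels[:2] = 1
        r_map = dc.ScalarVolume(g, np.full(SHAPE, 0.3))
        sig = dc.BinaryMask(g, (labels > 0).astype(np.uint8))
        table = dc.region_max(r_map, sig, labels, {1: "left_blob"})
        row = table.iloc[0]
        assert row["max_r"] == pytest.approx(0.3)
        assert row["name"] == "left_blob"
        assert row["n_sig_voxels"] == int((labels == 1).sum())

    def test_region_without_significant_voxels_marked(self):
        g = grid()
        labels = np.ones(SHAPE, dtype=int)
        r_map = dc.ScalarVolume(g, np.full(SHAPE, 0.5))
        sig = dc.BinaryMask(g, np.zeros(SHAPE, dtype=np.uint8))
        table = dc.region_max(r_map, sig, labels, {1: "blob"})
        assert not table.iloc[0]["significant"]
        assert np.isnan(table.iloc[0]["max_r"])

    def test_two_regions_match_exhaustive_scan(self):
        g = grid()
        rng = np.random.default_rng(15)
        labels = rng.integers(0, 3, SHAPE)
        r_data = rng.uniform(-1, 1, SHAPE)
        sig_data = rng.integers(0, 2, SHAPE).astype(np.uint8)
        table = dc.region_max(dc.ScalarVolume(g, r_data),
                              dc.BinaryMask(g, sig_data), labels, {1: "a", 2: "b"})
        for _, row in table.iterrows():
            sel = (labels == row["label"]) & (sig_data > 0)
            if sel.any():
                assert row["max_r"] == pytest.approx(r_data[sel].max())
            else:
                assert np.isnan(row["max_r"])

    def test_unknown_label_named_unknown(self):
        g = grid()
        labels = np.full(SHAPE, 7, dtype=int)
        r_map = dc.ScalarVolume(g, np.zeros(SHAPE))
        sig = dc.BinaryMask(g, np.ones(SHAPE, dtype=np.uint8))
        table = dc.region_max(r_map, sig, labels, {1: "known"})
        assert table.iloc[0]["name"] == "unknown"


class TestCohortMean:
    def test_single_map_identity(self):
        g = grid()
        rng = np.random.default_rng(16)
        m = dc.ScalarVolume(g, rng.normal(size=SHAPE))
        assert np.array_equal(dc.cohort_mean_map([m]).data, m.data)

    def test_map_plus_negation_is_zero(self):
        g = grid()
        rng = np.random.default_rng(17)
        m = dc.ScalarVolume(g, rng.normal(size=SHAPE))
        neg = dc.ScalarVolume(g, -m.data)
        assert np.allclose(dc.cohort_mean_map([m, neg]).data, 0.0)

    def test_ten_maps_match_brute_force(self):
        g = grid()
        rng = np.random.default_rng(18)
        maps = [dc.ScalarVolume(g, rng.normal(size=SHAPE)) for _ in range(10)]
        out = dc.cohort_mean_map(maps)
        brute = sum(m.data for m in maps) / 10
        assert np.max(np.abs(out.data - brute)) < 1e-12
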