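import numpy as np
import pytest

from enose_sais import (
    DomainDataset,
    InvalidParameterError,
    RankError,
    ShapeMismatchError,
    Subspace,
    alignment_matrix,
    bregman_divergence,
    pca_subspace,
    sais_transform,
    zscore_standardize,
)
from conftest import random_orthonormal


def standardized(X):
    out, _, _ = zscore_standardize(DomainDataset(np.asarray(X, float)))
    return out


class TestPcaSubspace:
    def test_basis_is_orthonormal(self, rng):
        ds = standardized(rng.standard_normal((50, 10)))
        sub = pca_subspace(ds, 4)
        np.testing.assert_allclose(sub.basis.T @ sub.basis, np.eye(4), atol=1e-10)

    def test_single_varying_axis_recovers_it(self):
        X = np.zeros((4, 3))
        X[:, 1] = [-3.0, -1.0, 1.0, 3.0]
        X[:, 0] = [1e-9, -1e-9, 1e-9, -1e-9]  # avoid zero-variance columns
        X[:, 2] = [-1e-9, 1e-9, 1e-9, -1e-9]
        sub = pca_subspace(DomainDataset(X), 1)
        np.testing.assert_allclose(np.abs(sub.basis[:, 0]), [0, 1, 0], atol=1e-6)
        assert sub.basis[1, 0] > 0  # largest-entry-positive sign convention

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.standard_normal((50, 10))
        ds = standardized(X)
        sub = pca_subspace(ds, 3)
        cov = np.cov(ds.features, rowvar=False)  # brute-force oracle
        top = np.sort(np.linalg.eigvalsh(cov))[::-1][:3]
        np.testing.assert_allclose(sub.eigenvalues, top, atol=1e-8)

    def test_rank_error_reports_achievable_maximum(self, rng):
        lat = rng.standard_normal((20, 2))
        X = lat @ rng.standard_normal((2, 6))  # rank 2
        with pytest.raises(RankError) as err:
            pca_subspace(DomainDataset(X), 5)
        assert err.value.achievable == 2

    def test_d_out_of_range(self, rng):
        ds = standardized(rng.standard_normal((10, 4)))
        with pytest.raises(InvalidParameterError):
            pca_subspace(ds, 0)
        with pytest.raises(InvalidParameterError):
            pca_subspace(ds, 5)


class TestBregmanDivergence:
    def test_equal_subspaces_identity_map_is_zero(self, rng):
        basis = random_orthonormal(6, 3, rng)
        sub = Subspace(basis, np.ones(3))
        assert bregman_divergence(sub, sub, np.eye(3)) == pytest.approx(0.0)

    def test_zero_map_gives_subspace_dimension(self, rng):
        s = Subspace(random_orthonormal(8, 4, rng), np.ones(4))
        t = Subspace(random_orthonormal(8, 4, rng), np.ones(4), "target")
        assert bregman_divergence(s, t, np.zeros((4, 4))) == pytest.approx(4.0)

    def test_matches_naive_double_loop(self, rng):
        s = Subspace(random_orthonormal(7, 3, rng), np.ones(3))
        t = Subspace(random_orthonormal(7, 3, rng), np.ones(3), "target")
        M = rng.standard_normal((3, 3))
        diff = s.basis - t.basis @ M
        naive = 0.0
        for i in range(diff.shape[0]):          # independent elementwise oracle
            for j in range(diff.shape[1]):
                naive += diff[i, j] ** 2
        assert bregman_divergence(s, t, M) == pytest.approx(naive, abs=1e-12)

    def test_shape_mismatch(self, rng):
        s = Subspace(random_orthonormal(7, 3, rng), np.ones(3))
        t = Subspace(random_orthonormal(7, 2, rng), np.ones(2), "target")
        with pytest.raises(ShapeMismatchError):
            bregman_divergence(s, t, np.eye(2))


class TestAlignmentMatrix:
    def test_identical_subspaces_give_identity(self, rng):
        basis = random_orthonormal(10, 4, rng)
        sub = Subspace(basis, np.arange(4, 0, -1.0))
        res = alignment_matrix(sub, sub)
        np.testing.assert_allclose(res.m_star, np.eye(4), atol=1e-10)
        assert res.residual < 1e-18

    def test_orthogonal_one_dimensional_subspaces(self):
        s = Subspace(np.array([[1.0], [0.0]]), np.ones(1))
        t = Subspace(np.array([[0.0], [1.0]]), np.ones(1), "target")
        res = alignment_matrix(s, t)
        assert res.m_star == pytest.approx(np.zeros((1, 1)))
        assert res.residual == pytest.approx(1.0)

    def test_global_minimizer_matches_least_squares_oracle(self, rng):
        s = Subspace(random_orthonormal(6, 2, rng), np.ones(2))
        t = Subspace(random_orthonormal(6, 2, rng), np.ones(2), "target")
        res = alignment_matrix(s, t)
        oracle, *_ = np.linalg.lstsq(t.basis, s.basis, rcond=None)
        np.testing.assert_allclose(res.m_star, oracle, atol=1e-6)
        f_star = bregman_divergence(s, t, res.m_star)
        for _ in range(2000):
            assert f_star <= bregman_divergence(s, t, rng.standard_normal((2, 2))) + 1e-12

    def test_residual_identity(self, rng):
        for _ in range(10):
            s = Subspace(random_orthonormal(12, 5, rng), np.ones(5))
            t = Subspace(random_orthonormal(12, 5, rng), np.ones(5), "target")
            res = alignment_matrix(s, t)
            expected = 5 - np.linalg.norm(t.basis.T @ s.basis, "fro") ** 2
            assert res.residual == pytest.approx(expected, abs=1e-9)

    def test_aligned_basis_construction(self, rng):
        s = Subspace(random_orthonormal(9, 3, rng), np.ones(3))
        t = Subspace(random_orthonormal(9, 3, rng), np.ones(3), "target")
        res = alignment_matrix(s, t)
        np.testing.assert_array_equal(res.aligned_basis, t.basis @ res.m_star)


class TestSaisTransform:
    def test_identical_domains_project_identically(self, default_pair):
        source, _ = default_pair
        twin = DomainDataset(source.features.copy(), labels=source.labels, domain_tag="target")
        ps, pt, res = sais_transform(source, twin, D=10)
        np.testing.assert_allclose(ps, pt, atol=1e-9)
        np.testing.assert_allclose(res.m_star, np.eye(10), atol=1e-9)

    def test_projected_target_invariant_to_basis_rotation(self, rng, default_pair):
        # X_T S_T S_T' S_S depends on the target basis only through its projector
        source, target = default_pair
        zs, _, _ = zscore_standardize(source)
        zt, _, _ = zscore_standardize(target)
        s_sub = pca_subspace(zs, 8)
        t_sub = pca_subspace(zt, 8)
        reference = zt.features @ alignment_matrix(s_sub, t_sub).aligned_basis
        for _ in range(5):
            q, r = np.linalg.qr(rng.standard_normal((8, 8)))
            q *= np.sign(np.diag(r))
            rotated = Subspace(t_sub.basis @ q, np.ones(8), "target")
            projected = zt.features @ alignment_matrix(s_sub, rotated).aligned_basis
            np.testing.assert_allclose(projected, reference, atol=1e-9)

    def test_rank_capping_warns_and_caps(self, default_pair):
        source, target = default_pair
        with pytest.warns(UserWarning, match="capped"):
            ps, pt, _ = sais_transform(
                source, target, D=25, n_target_for_subspace=5,
                rng=np.random.default_rng(0),
            )
        assert ps.shape[1] == pt.shape[1] == 24  # 25 subset samples -> rank 24

    def test_small_subset_rejected(self, default_pair):
        source, target = default_pair
        with pytest.raises(InvalidParameterError):
            sais_transform(source, target, D=5, n_target_for_subspace=1)

    def test_mismatched_sensor_dimension(self, rng):
        a = DomainDataset(rng.standard_normal((20, 5)), labels=np.repeat([1, 2], 10))
        b = DomainDataset(rng.standard_normal((20, 6)), domain_tag="target")
        with pytest.raises(ShapeMismatchError):
            sais_transform(a, b, D=2)


class TestSubspaceType:
    def test_non_orthonormal_basis_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            Subspace(rng.standard_normal((6, 3)), np.ones(3))

    def test_eigenvalue_ordering_enforced(self, rng):
        basis = random_orthonormal(6, 3, rng)
        with pytest.raises(InvalidParameterError):
            Subspace(basis, np.array([1.0, 3.0, 2.0]))

    def test_csv_dump_parses(self, tmp_path, rng):
        sub = Subspace(random_orthonormal(5, 2, rng), np.array([2.0, 1.0]))
        path = tmp_path / "subspace.csv"
        sub.save_csv(path)
        back = np.loadtxt(path, delimiter=",")
        np.testing.assert_allclose(back, sub.basis)
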