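import numpy as np
import pytest
from scipy.stats import ortho_group

from vesselrom import CommonBasePOD, assemble


def matrix_with_spectrum(sigma, m, n, seed=0):
    """Build an m x n matrix whose singular values are exactly `sigma`."""
    rng = np.random.default_rng(seed)
    u = ortho_group.rvs(m, random_state=rng)[:, : len(sigma)]
    v = ortho_group.rvs(n, random_state=rng)[:, : len(sigma)]
    return u @ np.diag(sigma) @ v.T


class TestAssemble:
    def test_row_order_and_values(self, small_sols):
        A = assemble(small_sols[:3], "pressure")
        assert A.shape == (3, small_sols[0].pressure.size)
        assert np.array_equal(A[0], small_sols[0].pressure)

    def test_field_routing(self, small_sols, small_geoms):
        Ap = assemble(small_sols, "pressure")
        Aw = assemble(small_sols, "wss")
        assert Ap.shape[1] == small_geoms[0].n_volume
        assert Aw.shape[1] == small_geoms[0].n_surface

    def test_topology_mismatch_rejected(self, small_sols):
        from dataclasses import replace

        bad = replace(small_sols[1], pressure=small_sols[1].pressure[:-1])
        with pytest.raises(ValueError, match="topology|nodes"):
            assemble([small_sols[0], bad], "pressure")
        with pytest.raises(ValueError):
            assemble(small_sols[:1], "pressure")
        with pytest.raises(ValueError):
            assemble(small_sols, "velocity")


class TestDecompose:
    def test_rank_one_matrix(self):
        u = np.array([1.0, 2.0, -1.0])
        v = np.array([0.5, 1.0, 0.0, -2.0, 1.5])
        pod = CommonBasePOD(method="direct").fit(np.outer(u, v))
        assert pod.singular_values_.size == 1
        # mode 1 proportional to v (up to the sign convention)
        mode = pod.components_[0]
        assert np.allclose(np.abs(mode), np.abs(v) / np.linalg.norm(v), atol=1e-10)

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 11))
        pod = CommonBasePOD().fit(A)
        rec = pod.reconstruct_training()
        assert np.linalg.norm(rec - A) / np.linalg.norm(A) < 1e-8

    def test_singular_values_match_eig_oracle(self):
        # sigma^2 must equal the eigenvalues of A A^T from an independent solver
        rng = np.random.default_rng(7)
        A = rng.normal(size=(5, 8))
        pod = CommonBasePOD(method="direct").fit(A)
        evals = np.sort(np.linalg.eigvalsh(A @ A.T))[::-1]
        assert np.allclose(pod.singular_values_**2, evals, atol=1e-8)

    def test_snapshot_equals_direct(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(7, 300))
        d = CommonBasePOD(method="direct").fit(A)
        s = CommonBasePOD(method="snapshot").fit(A)
        assert np.allclose(d.singular_values_, s.singular_values_, atol=1e-8)
        assert np.allclose(d.coefficients_, s.coefficients_, atol=1e-8)
        assert np.allclose(d.components_, s.components_, atol=1e-8)

    def test_modes_orthonormal_and_sigma_sorted(self, small_sols):
        pod = CommonBasePOD().fit(assemble(small_sols, "wss"))
        V = pod.components_
        assert np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-10)
        assert np.all(np.diff(pod.singular_values_) <= 1e-12)

    def test_sign_convention(self, small_sols):
        pod = CommonBasePOD().fit(assemble(small_sols, "pressure"))
        for mode in pod.components_:
            assert mode[np.argmax(np.abs(mode))] >= 0


class TestEnergyAndTruncation:
    def test_prescribed_spectrum_fraction(self):
        A = matrix_with_spectrum([4.0, 3.0, 2.0, 1.0], 6, 9)
        pod = CommonBasePOD().fit(A)
        assert pod.energy_fraction(2) == pytest.approx(0.7, abs=1e-10)
        assert pod.energy_fraction(4) == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_sum_oracle_every_k(self):
        rng = np.random.default_rng(19)
        pod = CommonBasePOD().fit(rng.normal(size=(8, 30)))
        sigma = pod.singular_values_
        for k in range(1, sigma.size + 1):
            assert pod.energy_fraction(k) == pytest.approx(
                sigma[:k].sum() / sigma.sum(), abs=1e-12
            )

    def test_threshold_truncation(self):
        A = matrix_with_spectrum([4.0, 3.0, 2.0, 1.0], 6, 9)
        pod = CommonBasePOD().fit(A)
        assert pod.truncate(energy_threshold=0.7).n_modes_ == 2
        assert pod.truncate(energy_threshold=1.0).n_modes_ == 4
        rank1 = CommonBasePOD(energy_threshold=0.95).fit(np.outer([1, 2.0], [3, 4.0, 5]))
        assert rank1.n_modes_ == 1

    def test_invalid_arguments(self):
        pod = CommonBasePOD().fit(np.eye(3))
        with pytest.raises(ValueError):
            pod.energy_fraction(0)
        with pytest.raises(ValueError):
            pod.truncate(energy_threshold=1.5)

    def test_truncation_error_monotone_in_k(self, small_sols):
        A = assemble(small_sols, "pressure")
        pod = CommonBasePOD().fit(A)
        errs = []
        for k in range(1, 8):
            t = pod.truncate(n_modes=k)
            errs.append(np.linalg.norm(t.reconstruct_training() - A))
        assert np.all(np.diff(errs) <= 1e-9)


class TestProjectReconstruct:
    def test_mode_projects_to_unit_vector(self, small_sols):
        pod = CommonBasePOD(n_modes=5).fit(assemble(small_sols, "wss"))
        c = pod.transform(pod.components_[0][None, :])[0]
        expected = np.zeros(5)
        expected[0] = 1.0
        assert np.allclose(c, expected, atol=1e-10)

    def test_training_row_projects_to_its_coefficients(self, small_sols):
        A = assemble(small_sols, "pressure")
        pod = CommonBasePOD(n_modes=6).fit(A)
        c = pod.transform(A[4][None, :])[0]
        assert np.allclose(c, pod.coefficients_[4, :6], atol=1e-8 * abs(c).max())

    def test_projection_residual_orthogonal_to_modes(self, small_sols):
        rng = np.random.default_rng(23)
        pod = CommonBasePOD(n_modes=4).fit(assemble(small_sols, "wss"))
        f = rng.normal(size=pod.n_features_in_)
        rec = pod.inverse_transform(pod.transform(f[None, :]))[0]
        residual = f - rec
        inner = pod.components_[:4] @ residual
        assert np.allclose(inner, 0.0, atol=1e-8 * np.linalg.norm(f))

    def test_zero_coefficients_give_zero_field(self, small_sols):
        pod = CommonBasePOD(n_modes=3).fit(assemble(small_sols, "pressure"))
        assert np.array_equal(pod.inverse_transform(np.zeros((1, 3)))[0],
                              np.zeros(pod.n_features_in_))

    def test_length_mismatch_rejected(self, small_sols):
        pod = CommonBasePOD(n_modes=3).fit(assemble(small_sols, "pressure"))
        with pytest.raises(ValueError):
            pod.transform(np.ones((1, 7)))
        with pytest.raises(ValueError):
            pod.inverse_transform(np.ones((1, 5)))
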