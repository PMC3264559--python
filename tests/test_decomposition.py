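"""Correctness of the paired decomposition and its interpretive scalars."""

import numpy as np
import pytest
from scipy.linalg import eigh

from gsvdcna import (
    PairedGSVD,
    PairedMatrices,
    angular_distances,
    compute_gsvd,
    generalized_entropy,
)


def random_pair(seed, shape1=(9, 4), shape2=(7, 4)):
    rng = np.random.default_rng(seed)
    return rng.normal(size=shape1), rng.normal(size=shape2)


class TestComputeGSVD:
    def test_identical_datasets_are_fully_common(self):
        fact = compute_gsvd((np.eye(2), np.eye(2)))
        assert np.allclose(fact.tumor_weights_, fact.normal_weights_)
        assert np.allclose(fact.angular_distances_, 0.0, atol=1e-12)

    def test_diagonal_pair_closed_form(self):
        fact = compute_gsvd((np.diag([2.0, 1.0]), np.eye(2)))
        assert np.allclose(sorted(fact.generalized_singular_values()), [1, 2])
        expected = sorted([np.arctan(2) - np.pi / 4, 0.0], reverse=True)
        assert np.allclose(fact.angular_distances_, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_and_orthonormality(self, seed):
        d1, d2 = random_pair(seed)
        fact = compute_gsvd((d1, d2))
        n = d1.shape[1]
        assert np.linalg.norm(fact.reconstruct("tumor") - d1) < 1e-10 * np.linalg.norm(d1)
        assert np.linalg.norm(fact.reconstruct("normal") - d2) < 1e-10 * np.linalg.norm(d2)
        assert np.abs(fact.tumor_arraylets_.T @ fact.tumor_arraylets_ - np.eye(n)).max() < 1e-10
        assert np.abs(fact.normal_arraylets_.T @ fact.normal_arraylets_ - np.eye(n)).max() < 1e-10
        assert np.abs(np.linalg.norm(fact.probelets_, axis=1) - 1).max() < 1e-10
        assert np.all(np.diff(fact.angular_distances_) <= 1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_generalized_eigenproblem_oracle(self, seed):
        """Squared weight ratios are the generalized eigenvalues of the Gram
        pair, and the probelets are the generalized eigenvectors of the
        inverse-Gram pair, up to sign."""
        d1, d2 = random_pair(seed, (12, 6), (11, 6))
        fact = compute_gsvd((d1, d2))
        g1, g2 = d1.T @ d1, d2.T @ d2
        eigvals = np.sort(eigh(g1, g2, eigvals_only=True))
        ratios = np.sort(fact.generalized_singular_values() ** 2)
        assert np.allclose(ratios, eigvals, rtol=1e-8, atol=1e-10)
        # probelets solve inv(G1) z = mu inv(G2) z
        mu, vecs = eigh(np.linalg.inv(g1), np.linalg.inv(g2))
        lam = fact.generalized_singular_values() ** 2
        for i in range(6):
            j = int(np.argmin(np.abs(1 / mu - lam[i])))
            e = vecs[:, j] / np.linalg.norm(vecs[:, j])
            assert abs(abs(fact.probelets_[i] @ e) - 1) < 1e-8

    def test_svd_limit(self):
        """With an orthonormal normal matrix the probelets reduce to the
        tumor matrix's right singular vectors and sigma1 to its singular
        values."""
        rng = np.random.default_rng(7)
        d1 = rng.normal(size=(9, 4))
        d2 = np.linalg.qr(rng.normal(size=(7, 4)))[0]
        fact = compute_gsvd((d1, d2))
        _, s, vt = np.linalg.svd(d1, full_matrices=False)
        assert np.allclose(np.sort(fact.tumor_weights_), np.sort(s), rtol=1e-8)
        for i in range(4):
            match = max(abs(fact.probelets_[i] @ vt[j]) for j in range(4))
            assert abs(match - 1) < 1e-8

    def test_scale_covariance(self):
        d1, d2 = random_pair(3)
        base = compute_gsvd((d1, d2))
        both = compute_gsvd((2.5 * d1, 2.5 * d2))
        assert np.allclose(both.tumor_weights_, 2.5 * base.tumor_weights_)
        assert np.allclose(both.normal_weights_, 2.5 * base.normal_weights_)
        assert np.allclose(both.angular_distances_, base.angular_distances_)
        assert np.allclose(both.weight_fractions("tumor"), base.weight_fractions("tumor"))
        assert np.isclose(both.entropy("tumor"), base.entropy("tumor"))
        tumor_only = compute_gsvd((3.0 * d1, d2))
        r_base = np.sort(base.generalized_singular_values())
        r_scaled = np.sort(tumor_only.generalized_singular_values())
        assert np.allclose(r_scaled, 3.0 * r_base, rtol=1e-8)

    def test_patient_permutation_equivariance(self):
        d1, d2 = random_pair(5)
        perm = np.array([2, 0, 3, 1])
        base = compute_gsvd((d1, d2))
        permuted = compute_gsvd((d1[:, perm], d2[:, perm]))
        assert np.allclose(permuted.angular_distances_, base.angular_distances_)
        assert np.allclose(permuted.tumor_weights_, base.tumor_weights_)
        for i in range(4):
            assert np.allclose(
                np.abs(permuted.probelets_[i]), np.abs(base.probelets_[i][perm]),
                atol=1e-10,
            )

    def test_rank_deficiency_names_dataset(self):
        d1 = np.ones((5, 3))  # rank 1
        d2 = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="tumor"):
            compute_gsvd((d1, d2))
        with pytest.raises(ValueError, match="normal"):
            compute_gsvd((d2, d1))

    def test_mismatched_patient_axes_fail(self):
        with pytest.raises(ValueError, match="patient axes"):
            PairedMatrices(np.eye(3), np.ones((4, 4)))


class TestReconstruct:
    def test_component_selection(self):
        fact = compute_gsvd((np.diag([2.0, 1.0]), np.eye(2)))
        full = fact.reconstruct("tumor")
        assert np.allclose(full, np.diag([2.0, 1.0]), atol=1e-12)
        assert np.allclose(fact.reconstruct("tumor", []), 0.0)
        rank1 = fact.reconstruct("tumor", [0])
        sigma = fact.tumor_weights_[0]
        outer = sigma * np.outer(fact.tumor_arraylets_[:, 0], fact.probelets_[0])
        assert np.allclose(rank1, outer)
        assert np.linalg.matrix_rank(rank1) == 1

    def test_bad_selectors_fail(self):
        fact = compute_gsvd(random_pair(0))
        with pytest.raises(IndexError):
            fact.reconstruct("tumor", [99])
        with pytest.raises(ValueError):
            fact.reconstruct("plasma")


class TestWeightFractions:
    def test_direct_formula(self):
        fact = PairedGSVD()
        fact.tumor_weights_ = np.array([3.0, 4.0])
        assert np.allclose(fact.weight_fractions("tumor"), [9 / 25, 16 / 25])

    def test_uniform_and_normalization(self):
        fact = compute_gsvd(random_pair(2))
        for ds in ("tumor", "normal"):
            p = fact.weight_fractions(ds)
            assert abs(p.sum() - 1) < 1e-12
            assert np.all(p >= 0)
        eq = PairedGSVD()
        eq.normal_weights_ = np.full(5, 2.0)
        assert np.allclose(eq.weight_fractions("normal"), 0.2)

    def test_all_zero_weights_fail(self):
        fact = PairedGSVD()
        fact.tumor_weights_ = np.zeros(3)
        with pytest.raises(ValueError):
            fact.weight_fractions("tumor")


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1, 0, 0, 0], 0.0),                  # all information in one component
            ([0.25] * 4, 1.0),                     # flat spectrum
            ([0.5, 0.5, 0, 0], 0.5),               # log 2 / log 4
        ],
    )
    def test_reference_values(self, p, expected):
        assert generalized_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_bounds_on_random_fractions(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 9)))
            assert 0.0 <= generalized_entropy(p) <= 1.0 + 1e-12

    @pytest.mark.parametrize("bad", [[0.5, 0.6], [-0.1, 1.1], [1.0]])
    def test_invalid_fractions_fail(self, bad):
        with pytest.raises(ValueError):
            generalized_entropy(bad)


class TestAngularDistance:
    def test_exclusive_and_common_limits(self):
        assert angular_distances([1.0], [0.0])[0] == pytest.approx(np.pi / 4)
        assert angular_distances([0.0], [1.0])[0] == pytest.approx(-np.pi / 4)
        assert angular_distances([3.0], [3.0])[0] == pytest.approx(0.0)

    def test_arctan_identity(self):
        theta = angular_distances([np.tan(5 * np.pi / 12)], [1.0])[0]
        assert theta == pytest.approx(np.pi / 6, abs=1e-12)

    def test_both_zero_fails(self):
        with pytest.raises(ValueError, match="component 1"):
            angular_distances([1.0, 0.0], [1.0, 0.0])
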