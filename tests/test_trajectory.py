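"""Latent-class growth model: basis, EM fitter, metrics, selection, naming."""

import numpy as np
import pytest

import _oracles
from qitraj import (
    BasisSpec,
    ConfigurationError,
    DomainError,
    FitMetrics,
    GroupAssignment,
    TrajectoryMixture,
    build_basis,
    compute_bic,
    compute_wmae,
    compute_wrss,
    em_fit,
    order_and_name_groups,
    select_model,
)
from qitraj.trajectory import n_parameters


def make_mixture(beta, basis, pi=None, sigma2=1e-4):
    beta = np.asarray(beta, dtype=float)
    basis = np.asarray(basis, dtype=float)
    K = beta.shape[0]
    return TrajectoryMixture(
        K=K, pi=np.full(K, 1.0 / K) if pi is None else np.asarray(pi),
        beta=beta, sigma2=sigma2, loglik=0.0,
        n_params=n_parameters(K, beta.shape[1]),
        basis_spec=BasisSpec(kind="linear"), basis=basis,
        periods=np.arange(basis.shape[0], dtype=float),
    )


class TestBasis:
    def test_linear_and_quadratic_columns(self):
        B = build_basis(BasisSpec(kind="linear"), [0, 1, 2])
        np.testing.assert_array_equal(B, [[1, 0], [1, 1], [1, 2]])
        B = build_basis(BasisSpec(kind="quadratic"), [0, 1, 3])
        np.testing.assert_array_equal(B, [[1, 0, 0], [1, 1, 1], [1, 3, 9]])

    def test_rank_deficiency_is_an_error(self):
        with pytest.raises(ConfigurationError):
            build_basis(BasisSpec(kind="quadratic"), [0, 1])  # 3 columns, 2 rows

    @pytest.mark.parametrize("df", [4, 5, 6])
    def test_spline_shape_and_rank(self, df):
        B = build_basis(BasisSpec(kind="spline", df=df), np.arange(7))
        assert B.shape == (7, df)
        assert np.linalg.matrix_rank(B) == df
        # B-spline basis forms a partition of unity: rows sum to 1
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_non_increasing_periods_rejected(self):
        with pytest.raises(ConfigurationError):
            build_basis(BasisSpec(kind="linear"), [0, 2, 1])


class TestEMFit:
    def test_k1_equals_pooled_least_squares(self, rng):
        """With one class the EM fit collapses to ordinary least squares."""
        Y = rng.uniform(0.2, 0.8, size=(25, 6))
        spec = BasisSpec(kind="quadratic")
        mixture, assignment, _ = em_fit(Y, 1, spec, seed=0, n_starts=2)
        B = build_basis(spec, np.arange(6))
        np.testing.assert_allclose(mixture.beta[0], _oracles.pooled_ols_beta(Y, B), atol=1e-8)
        np.testing.assert_array_equal(mixture.pi, [1.0])
        assert (assignment.posterior == 1.0).all()

    def test_noiseless_two_class_recovery(self):
        """Two exact flat curves are separated with hard posteriors."""
        Y = np.vstack([np.full((10, 5), 0.2), np.full((10, 5), 0.8)])
        mixture, assignment, metrics = em_fit(Y, 2, BasisSpec(kind="linear"), seed=1, n_starts=3)
        P = assignment.posterior
        assert np.all((P > 1 - 1e-6) | (P < 1e-6))
        means = np.sort(mixture.class_means[:, 0])
        np.testing.assert_allclose(means, [0.2, 0.8], atol=1e-6)
        assert metrics.wmae == pytest.approx(0.0, abs=1e-6)
        assert metrics.wrss == pytest.approx(0.0, abs=1e-6)

    def test_row_permutation_invariance(self, rng):
        Y = np.vstack([
            np.full((8, 4), 0.3) + rng.normal(0, 0.01, (8, 4)),
            np.full((8, 4), 0.7) + rng.normal(0, 0.01, (8, 4)),
        ])
        perm = rng.permutation(len(Y))
        f1 = em_fit(Y, 2, BasisSpec(kind="linear"), seed=5, n_starts=3)
        f2 = em_fit(Y[perm], 2, BasisSpec(kind="linear"), seed=5, n_starts=3)
        assert f1[0].loglik == pytest.approx(f2[0].loglik, abs=1e-6)
        # posteriors agree up to the row permutation (class order may swap)
        P1, P2 = f1[1].posterior[perm], f2[1].posterior
        direct = np.abs(P1 - P2).max()
        swapped = np.abs(P1 - P2[:, ::-1]).max()
        assert min(direct, swapped) < 1e-6

    def test_posterior_rows_normalized(self, small_sim, rng):
        Y = rng.uniform(0, 1, size=(30, 5))
        _, assignment, _ = em_fit(Y, 3, BasisSpec(kind="linear"), seed=2, n_starts=2)
        np.testing.assert_allclose(assignment.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert (assignment.modal == assignment.posterior.argmax(axis=1)).all()

    def test_loglik_trace_monotone(self, rng):
        Y = np.clip(rng.normal(0.5, 0.1, size=(40, 6)), 0, 1)
        mixture, _, _ = em_fit(Y, 3, BasisSpec(kind="linear"), seed=3, n_starts=2)
        assert (np.diff(mixture.loglik_trace) >= -1e-8).all()

    def test_domain_errors(self, rng):
        Y = rng.uniform(0, 1, size=(5, 4))
        with pytest.raises(DomainError):
            em_fit(Y, 0, BasisSpec(kind="linear"))
        with pytest.raises(DomainError):
            em_fit(Y, 6, BasisSpec(kind="linear"))
        Y[0, 0] = np.nan
        with pytest.raises(DomainError):
            em_fit(Y, 2, BasisSpec(kind="linear"))


class TestMetrics:
    @pytest.mark.parametrize(
        "loglik, p, N, expected",
        [(0.0, 2, 100, 2 * np.log(100)), (10.0, 1, 1, -20.0), (-5.0, 3, np.exp(3), 19.0)],
    )
    def test_bic_values(self, loglik, p, N, expected):
        assert compute_bic(loglik, p, int(round(N)) if N == 1 else N) == pytest.approx(expected, abs=1e-6)

    def test_single_term(self):
        mixture = make_mixture([[0.5]], [[1.0]])
        P = np.array([[1.0]])
        Y = np.array([[0.6]])
        assert compute_wmae(Y, mixture, P) == pytest.approx(0.1)
        assert compute_wrss(Y, mixture, P) == pytest.approx(0.01)

    def test_two_class_posterior_weighting(self):
        mixture = make_mixture([[-1.0], [1.0]], [[1.0]])
        P = np.array([[0.5, 0.5]])
        Y = np.array([[0.0]])
        assert compute_wmae(Y, mixture, P) == pytest.approx(1.0)
        assert compute_wrss(Y, mixture, P) == pytest.approx(1.0)

    def test_label_permutation_leaves_metrics_unchanged(self, rng):
        Y = rng.uniform(0, 1, size=(12, 4))
        mixture, assignment, metrics = em_fit(Y, 3, BasisSpec(kind="linear"), seed=9, n_starts=2)
        perm = [2, 0, 1]
        permuted = make_mixture(mixture.beta[perm], mixture.basis, pi=mixture.pi[perm],
                                sigma2=mixture.sigma2)
        P = assignment.posterior[:, perm]
        assert compute_wmae(Y, permuted, P) == pytest.approx(metrics.wmae, abs=1e-12)
        assert compute_wrss(Y, permuted, P) == pytest.approx(metrics.wrss, abs=1e-12)


class TestSelectModel:
    def test_single_k_range(self, rng):
        Y = rng.uniform(0, 1, size=(10, 4))
        table, chosen, fits = select_model(Y, [1], BasisSpec(kind="linear"), seed=0, n_starts=2)
        assert chosen == 1 and list(fits) == [1]

    def test_identical_rows_prefer_k1(self):
        """Duplicated trajectories: extra classes add parameters but no likelihood."""
        Y = np.tile(np.linspace(0.3, 0.6, 5), (12, 1))
        table, chosen, _ = select_model(Y, range(1, 4), BasisSpec(kind="linear"),
                                        seed=4, n_starts=2)
        assert chosen == 1
        assert table["BIC"].iloc[0] == table["BIC"].min()

    def test_empty_range_rejected(self):
        with pytest.raises(DomainError):
            select_model(np.zeros((3, 3)), [], BasisSpec(kind="linear"))


class TestNaming:
    def test_band_names_and_ordering(self):
        # class 0: rising 0.40 -> 0.55; class 1: flat 0.70 (periods 0 and 1, linear basis)
        basis = np.array([[1.0, 0.0], [1.0, 1.0]])
        mixture = make_mixture([[0.40, 0.15], [0.70, 0.0]], basis, pi=[0.4, 0.6])
        assignment = GroupAssignment(
            posterior=np.array([[0.9, 0.1], [0.2, 0.8]]),
            modal=np.array([0, 1]),
        )
        new_mix, new_asg = order_and_name_groups(mixture, assignment, (0.45, 0.60))
        assert new_asg.names == ["high to high", "low to middle"]
        assert new_asg.short_names == ["HH", "LM"]
        # reordered: the flat-high class is now group 0
        np.testing.assert_allclose(new_mix.beta[0], [0.70, 0.0])
        np.testing.assert_array_equal(new_asg.modal, [1, 0])
        np.testing.assert_allclose(new_asg.posterior, [[0.1, 0.9], [0.8, 0.2]])

    def test_duplicate_names_get_suffixes(self):
        basis = np.array([[1.0, 0.0], [1.0, 1.0]])
        mixture = make_mixture([[0.50, 0.0], [0.52, 0.0], [0.3, 0.0]], basis)
        assignment = GroupAssignment(posterior=np.full((2, 3), 1 / 3),
                                     modal=np.array([0, 1]))
        _, named = order_and_name_groups(mixture, assignment, (0.45, 0.60))
        assert named.names == ["middle to middle (1)", "middle to middle (2)", "low to low"]

    def test_bad_thresholds(self):
        basis = np.array([[1.0], [1.0]])
        mixture = make_mixture([[0.5]], basis)
        assignment = GroupAssignment(posterior=np.array([[1.0]]), modal=np.array([0]))
        with pytest.raises(ConfigurationError):
            order_and_name_groups(mixture, assignment, (0.6, 0.45))
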