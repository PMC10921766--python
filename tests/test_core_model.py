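import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from depgp import (
    AffinityMatrix,
    HyperParams,
    KernelParams,
    LatentState,
    SensitivityMatrix,
    conditional_mean,
    log_likelihood_conditional,
    log_marginal_likelihood,
    log_prior,
)
from depgp.core_model import log_structure_prior, mean_matrix
from depgp.kernels import DEFAULT_JITTER, constrained_kernel

from conftest import make_small_instance

KP = KernelParams(0.5, 0.2)
HP = HyperParams(kernel=KP)


def make_state(X, S, Z=None, alpha=None, sigma2=1.0, gamma2=1.0, rng=None):
    P = X.n_proteins
    Z = np.zeros(P, dtype=np.int8) if Z is None else np.asarray(Z, dtype=np.int8)
    alpha = np.zeros(S) if alpha is None else np.asarray(alpha, dtype=float)
    f_values = []
    for p in range(P):
        n = X.present_indices(p).size
        f_values.append(np.zeros((n, S)) if rng is None else rng.normal(size=(n, S)))
    return LatentState(Z=Z, alpha=alpha, sigma2=sigma2, gamma2=gamma2, f_values=f_values)


class TestContainers:
    def test_all_missing_protein_column_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"pA": [1.0, np.nan], "pB": [np.nan, np.nan]},
                          index=["d0", "d1"])
        with caplog.at_level("WARNING"):
            X = AffinityMatrix.from_dataframe(df)
        assert X.protein_ids == ["pA"]
        assert "pB" in caplog.text

    def test_sensitivity_missing_sets(self):
        Y = SensitivityMatrix(np.array([[1.0, np.nan], [2.0, 3.0], [np.nan, 4.0]]),
                              ~np.isnan(np.array([[1.0, np.nan], [2.0, 3.0], [np.nan, 4.0]])),
                              ["d0", "d1", "d2"], ["s0", "s1"])
        ms = Y.missing_sets
        assert list(ms[0]) == [2] and list(ms[1]) == [0]

    def test_underobserved_column_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 0.5]])
        Y = SensitivityMatrix(vals, ~np.isnan(vals), ["a", "b", "c"], ["s0", "s1"])
        with pytest.raises(ValueError, match="s1"):
            Y.check_identifiable()


class TestConditionalMean:
    def test_all_inactive_reduces_to_intercept(self, small_instance):
        X, Y = small_instance
        st_ = make_state(X, Y.n_samples, alpha=[0.3, -0.2])
        assert conditional_mean(st_, X, 1, 0) == pytest.approx(0.3)

    def test_missing_affinity_contributes_nothing(self):
        X = AffinityMatrix(np.array([[np.nan]]), np.array([[False]]), ["d0"], ["p0"])
        st_ = LatentState(Z=np.array([1], dtype=np.int8), alpha=np.array([0.4]),
                          sigma2=1.0, gamma2=1.0, f_values=[np.zeros((0, 1))])
        assert conditional_mean(st_, X, 0, 0) == pytest.approx(0.4)

    def test_single_protein_hand_sum(self):
        X = AffinityMatrix(np.array([[0.6]]), np.array([[True]]), ["d0"], ["p0"])
        st_ = LatentState(Z=np.array([1], dtype=np.int8), alpha=np.array([0.5]),
                          sigma2=1.0, gamma2=1.0, f_values=[np.array([[1.2]])])
        assert conditional_mean(st_, X, 0, 0) == pytest.approx(1.7)

    def test_index_out_of_range(self, small_instance):
        X, Y = small_instance
        st_ = make_state(X, Y.n_samples)
        with pytest.raises(IndexError):
            conditional_mean(st_, X, X.n_drugs, 0)


class TestConditionalLikelihood:
    def test_perfect_fit_value(self, small_instance):
        X, Y = small_instance
        st_ = make_state(X, Y.n_samples, rng=np.random.default_rng(0))
        st_.Z[:] = 1
        mu = mean_matrix(st_, X)
        Yfit = Y.with_values(np.where(Y.observed, mu, np.nan), Y.observed)
        n = Yfit.n_observed
        assert log_likelihood_conditional(st_, X, Yfit) == pytest.approx(
            -n * np.log(2 * np.pi) / 2)

    def test_matches_independent_normal_densities(self, small_instance):
        X, Y = small_instance
        st_ = make_state(X, Y.n_samples, Z=[1, 0], sigma2=0.7,
                         alpha=[0.1, -0.4], rng=np.random.default_rng(1))
        mu = mean_matrix(st_, X)
        expected = stats.norm.logpdf(Y.values[Y.observed], mu[Y.observed],
                                     np.sqrt(0.7)).sum()
        assert log_likelihood_conditional(st_, X, Y) == pytest.approx(expected)

    def test_unmasking_one_entry_adds_one_density_term(self, small_instance):
        X, Y = small_instance
        st_ = make_state(X, Y.n_samples, rng=np.random.default_rng(2))
        d, s = 3, 1
        obs2 = Y.observed.copy()
        assert obs2[d, s]
        obs2[d, s] = False
        vals2 = np.where(obs2, Y.values, np.nan)
        Y2 = Y.with_values(vals2, obs2)
        mu = mean_matrix(st_, X)
        delta = stats.norm.logpdf(Y.values[d, s], mu[d, s], 1.0)
        assert (log_likelihood_conditional(st_, X, Y)
                - log_likelihood_conditional(st_, X, Y2)) == pytest.approx(delta)


class TestMarginalLikelihood:
    def test_null_model_single_observation(self):
        """With no active protein the covariance collapses to gamma^2 + sigma^2."""
        X = AffinityMatrix(np.array([[0.3]]), np.array([[True]]), ["d0"], ["p0"])
        y = 0.37
        Y = SensitivityMatrix(np.array([[y]]), np.array([[True]]), ["d0"], ["s0"])
        got = log_marginal_likelihood([0], 0.5, 0.5, X, Y, KP)
        assert got == pytest.approx(stats.norm.logpdf(y, 0, 1.0), abs=1e-5)

    def test_monte_carlo_marginalization(self):
        """Eq.-level check: exact marginal vs MC average of the conditional
        likelihood over prior draws of (alpha, f)."""
        rng = np.random.default_rng(11)
        for trial in range(3):
            X, Y = make_small_instance(seed=100 + trial)
            s2, g2 = rng.uniform(0.2, 0.6, 2)
            Z = np.array([1, 1])
            exact = log_marginal_likelihood(Z, s2, g2, X, Y, KP)
            N = 100_000
            mu = np.broadcast_to(
                (np.sqrt(g2) * rng.standard_normal((N, Y.n_samples)))[:, None, :],
                (N, X.n_drugs, Y.n_samples)).copy()
            for p in range(X.n_proteins):
                idx = X.present_indices(p)
                x = X.values[idx, p]
                K = constrained_kernel(x[:, None], x[None, :], KP)
                K += DEFAULT_JITTER * KP.nu1 * np.eye(idx.size)
                L = linalg.cholesky(K, lower=True)
                f = np.einsum("ij,jns->ins", L,
                              rng.standard_normal((idx.size, N, Y.n_samples)))
                mu[:, idx, :] += np.moveaxis(f, 0, 1)
            resid = (Y.values[None] - mu)[:, Y.observed]
            nobs = Y.n_observed
            ll = -0.5 * nobs * np.log(2 * np.pi * s2) - 0.5 * (resid**2).sum(1) / s2
            m = ll.max()
            w = np.exp(ll - m)
            mc = m + np.log(w.mean())
            se = w.std() / (w.mean() * np.sqrt(N))
            assert abs(exact - mc) < 3 * se

    def test_masking_equals_reduced_vector_marginal(self, small_instance):
        X, Y = small_instance
        # drop one observed entry; the marginal must equal the reduced-vector value
        d, s = 3, 0
        obs2 = Y.observed.copy()
        obs2[d, s] = False
        Y2 = Y.with_values(np.where(obs2, Y.values, np.nan), obs2)
        # reduced: remove drug row d entirely from column s's observation set
        a = log_marginal_likelihood([1, 1], 0.4, 0.3, X, Y2, KP)
        # build the same reduced data explicitly
        vals = Y.values.copy()
        vals[d, s] = np.nan
        Y3 = SensitivityMatrix(vals, ~np.isnan(vals), Y.drug_ids, Y.sample_ids)
        b = log_marginal_likelihood([1, 1], 0.4, 0.3, X, Y3, KP)
        assert a == pytest.approx(b, abs=1e-12)

    def test_drug_permutation_invariance(self, small_instance):
        X, Y = small_instance
        perm = np.random.default_rng(5).permutation(X.n_drugs)
        Xp = AffinityMatrix(X.values[perm], X.present[perm],
                            [X.drug_ids[i] for i in perm], X.protein_ids)
        Yp = SensitivityMatrix(Y.values[perm], Y.observed[perm],
                               [Y.drug_ids[i] for i in perm], Y.sample_ids)
        a = log_marginal_likelihood([1, 0], 0.3, 0.7, X, Y, KP)
        b = log_marginal_likelihood([1, 0], 0.3, 0.7, Xp, Yp, KP)
        assert a == pytest.approx(b, abs=1e-9)

    def test_inactive_column_is_ignored(self, small_instance):
        X, Y = small_instance
        a = log_marginal_likelihood([1, 0], 0.3, 0.7, X, Y, KP)
        vals = X.values.copy()
        rng = np.random.default_rng(9)
        vals[:, 1] = np.where(X.present[:, 1], rng.uniform(size=X.n_drugs), np.nan)
        X2 = AffinityMatrix(vals, X.present, X.drug_ids, X.protein_ids)
        assert log_marginal_likelihood([1, 0], 0.3, 0.7, X2, Y, KP) == pytest.approx(a)

    def test_column_separability(self, small_instance):
        X, Y = small_instance
        total = log_marginal_likelihood([1, 1], 0.3, 0.7, X, Y, KP)
        parts = 0.0
        for s in range(Y.n_samples):
            obs = np.zeros_like(Y.observed)
            obs[:, s] = Y.observed[:, s]
            Ys = Y.with_values(np.where(obs, Y.values, np.nan), obs)
            parts += log_marginal_likelihood([1, 1], 0.3, 0.7, X, Ys, KP)
        assert total == pytest.approx(parts, abs=1e-9)

    def test_rejects_nonpositive_variances(self, small_instance):
        X, Y = small_instance
        with pytest.raises(ValueError):
            log_marginal_likelihood([0, 0], -0.1, 0.5, X, Y, KP)


class TestPriors:
    def test_bernoulli_mass_all_zero(self):
        hp = HyperParams(kernel=KP, pi0=0.1)
        lp = log_structure_prior(np.zeros(5, dtype=int), 1.0, 1.0, hp)
        # subtract the (Z-independent) variance-prior terms via an empty-Z state
        lp_novars = log_structure_prior(np.zeros(0, dtype=int), 1.0, 1.0, hp)
        assert lp - lp_novars == pytest.approx(5 * np.log(0.9))
        lp1 = log_structure_prior(np.array([1, 0, 0, 0, 0]), 1.0, 1.0, hp)
        assert lp - lp1 == pytest.approx(np.log(0.9) - np.log(0.1))

    def test_invgamma_closed_form_at_one(self):
        # Inv-Gamma(1,1) log-density at 1 is -1
        hp = HyperParams(kernel=KP)
        st_ = LatentState(Z=np.zeros(1, dtype=np.int8), alpha=np.zeros(1),
                          sigma2=1.0, gamma2=1.0, f_values=[])
        base = log_prior(st_, hp)
        st2 = LatentState(Z=np.zeros(1, dtype=np.int8), alpha=np.zeros(1),
                          sigma2=2.0, gamma2=1.0, f_values=[])
        diff = base - log_prior(st2, hp)
        expected = (-2 * np.log(1.0) - 1.0) - (-2 * np.log(2.0) - 0.5)
        assert diff == pytest.approx(expected)

    def test_out_of_support_returns_neg_inf(self):
        hp = HyperParams(kernel=KP)
        st_ = LatentState(Z=np.zeros(1, dtype=np.int8), alpha=np.zeros(1),
                          sigma2=1.0, gamma2=-0.1, f_values=[])
        assert log_prior(st_, hp) == -np.inf

    def test_gp_term_matches_multivariate_normal(self, small_instance):
        X, _ = small_instance
        hp = HyperParams(kernel=KP)
        rng = np.random.default_rng(4)
        st_ = make_state(X, 2, rng=rng)
        with_f = log_prior(st_, hp, X=X)
        no_f = log_prior(LatentState(st_.Z, st_.alpha, st_.sigma2, st_.gamma2, []), hp)
        expected = 0.0
        for p in range(X.n_proteins):
            idx = X.present_indices(p)
            x = X.values[idx, p]
            K = constrained_kernel(x[:, None], x[None, :], KP)
            K += DEFAULT_JITTER * KP.nu1 * np.eye(idx.size)
            for s in range(2):
                expected += stats.multivariate_normal.logpdf(
                    st_.f_values[p][:, s], np.zeros(idx.size), K)
        assert with_f - no_f == pytest.approx(expected, rel=1e-9)
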