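"""Likelihood, GLS, REML/ML optimization, and BLUP against dense oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from larmex import (CovParam, ModelSpec, SimConfig, blup, fit, gls_beta,
                    marginal_cov, neg2_loglik, simulate_dataset, stack_dataset)
from larmex.design import StackedData, StackedDay
from larmex.model import build_cs_matrix


def random_stacked(rng, k=2, n_days=4, n_trans=3):
    """Unstructured random instance (X need not have the VAR block layout)."""
    q = k * k + 2 * k
    days = []
    for i in range(n_days):
        X = rng.standard_normal((k * n_trans, q))
        Y = rng.standard_normal(k * n_trans)
        days.append(StackedDay(day_index=i, Y=Y, X=X, Z=X.copy(), n_transitions=n_trans))
    return StackedData(days=days, k=k)


def random_cov(rng, q, structure="diagonal"):
    if structure == "diagonal":
        return np.diag(rng.uniform(0.05, 0.5, q)), float(rng.uniform(0.1, 1.0))
    v = rng.uniform(0.3, 0.6)
    c = rng.uniform(0.0, 0.2)
    return build_cs_matrix(q, v, c), float(rng.uniform(0.1, 1.0))


def dense_neg2ll(stacked, G, sigma2, method):
    """Independent oracle: -2 log MVN density per day (constants dropped),
    with beta profiled by dense GLS, plus the REML determinant term."""
    Vs = [d.Z @ G @ d.Z.T + sigma2 * np.eye(d.n_rows) for d in stacked.days]
    A = sum(d.X.T @ np.linalg.solve(V, d.X) for d, V in zip(stacked.days, Vs))
    u = sum(d.X.T @ np.linalg.solve(V, d.Y) for d, V in zip(stacked.days, Vs))
    beta = np.linalg.solve(A, u)
    total = 0.0
    for d, V in zip(stacked.days, Vs):
        logpdf = stats.multivariate_normal(mean=d.X @ beta, cov=V).logpdf(d.Y)
        total += -2.0 * logpdf - d.n_rows * np.log(2 * np.pi)
    if method == "REML":
        total += np.linalg.slogdet(A)[1]
    return total


class TestMarginalCov:
    def test_zero_G_gives_scaled_identity(self, rng):
        day = random_stacked(rng).days[0]
        V = marginal_cov(day, np.zeros((8, 8)), 0.7)
        np.testing.assert_allclose(V, 0.7 * np.eye(day.n_rows))

    def test_identity_case(self):
        Z = np.eye(3)
        day = StackedDay(0, Y=np.zeros(3), X=Z.copy(), Z=Z, n_transitions=3)
        np.testing.assert_allclose(
            marginal_cov(day, np.eye(3), 1.0), 2 * np.eye(3))

    def test_minimum_eigenvalue_bounded_by_sigma2(self, rng):
        """Z G Z' is PSD, so every eigenvalue of V is >= sigma2."""
        for _ in range(5):
            day = random_stacked(rng).days[0]
            G, s2 = random_cov(rng, 8)
            V = marginal_cov(day, G, s2)
            assert np.linalg.eigvalsh(V).min() >= s2 - 1e-10
            np.linalg.cholesky(V)   # PD: factorization must succeed

    def test_non_psd_G_rejected(self, rng):
        day = random_stacked(rng).days[0]
        G = -np.eye(8)
        with pytest.raises(ValueError, match="semi-definite"):
            marginal_cov(day, G, 1.0)


class TestGls:
    def test_reduces_to_ols_when_G_zero(self, rng):
        stacked = random_stacked(rng)
        X = np.vstack([d.X for d in stacked.days])
        Y = np.concatenate([d.Y for d in stacked.days])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ Y)
        beta, cov = gls_beta(stacked, np.zeros((8, 8)), 1.0)
        np.testing.assert_allclose(beta, beta_ols, atol=1e-10)
        np.testing.assert_allclose(cov, np.linalg.inv(X.T @ X), atol=1e-10)

    def test_noiseless_data_recovers_beta_exactly(self, noiseless_spec):
        data = simulate_dataset(SimConfig(spec=noiseless_spec, n_days=4, seed=1))
        stacked = stack_dataset(data)
        beta, _ = gls_beta(stacked, np.zeros((8, 8)), 1.0)
        np.testing.assert_allclose(beta, noiseless_spec.beta, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        stacked = random_stacked(rng)
        G, s2 = random_cov(rng, 8)
        beta, cov = gls_beta(stacked, G, s2)
        Vs = [d.Z @ G @ d.Z.T + s2 * np.eye(d.n_rows) for d in stacked.days]
        A = sum(d.X.T @ np.linalg.solve(V, d.X) for d, V in zip(stacked.days, Vs))
        u = sum(d.X.T @ np.linalg.solve(V, d.Y) for d, V in zip(stacked.days, Vs))
        np.testing.assert_allclose(beta, np.linalg.solve(A, u), atol=1e-10)
        np.testing.assert_allclose(cov, np.linalg.inv(A), atol=1e-10)

    def test_cov_beta_symmetric_psd(self, rng):
        stacked = random_stacked(rng)
        G, s2 = random_cov(rng, 8)
        _, cov = gls_beta(stacked, G, s2)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestCovParam:
    @given(st.integers(min_value=2, max_value=4), st.data())
    @settings(max_examples=25, deadline=None)
    def test_diagonal_round_trip(self, k, data):
        q = k * k + 2 * k
        draw = data.draw(st.lists(st.floats(0.01, 5.0), min_size=q, max_size=q))
        sigma2 = data.draw(st.floats(0.01, 10.0))
        cp = CovParam(k, "diagonal")
        G, s2 = cp.decode(cp.encode(np.diag(draw), sigma2))
        np.testing.assert_allclose(np.diag(G), draw, rtol=1e-12)
        assert s2 == pytest.approx(sigma2, rel=1e-12)

    @pytest.mark.parametrize("structure", ["compound_symmetric",
                                           "block_cs_ar_exo_independent"])
    def test_cs_round_trip(self, structure, rng):
        cp = CovParam(2, structure)
        if structure == "compound_symmetric":
            G = build_cs_matrix(8, 0.4, 0.1)
        else:
            G = np.zeros((8, 8))
            G[:4, :4] = build_cs_matrix(4, 0.4, 0.1)
            G[4:6, 4:6] = build_cs_matrix(2, 0.3, -0.05)
            G[6:8, 6:8] = build_cs_matrix(2, 0.2, 0.02)
        G2, s2 = cp.decode(cp.encode(G, 0.7))
        np.testing.assert_allclose(G2, G, atol=1e-12)
        assert s2 == pytest.approx(0.7, rel=1e-12)

    def test_decoded_G_always_psd(self, rng):
        for structure in ("diagonal", "compound_symmetric",
                          "block_cs_ar_exo_independent"):
            cp = CovParam(2, structure)
            for _ in range(20):
                theta = rng.uniform(-3, 3, cp.n_params)
                G, s2 = cp.decode(theta)
                assert s2 > 0
                assert np.linalg.eigvalsh(G).min() >= -1e-12


class TestNeg2Loglik:
    def test_zero_residual_identity_cov_gives_zero(self, rng):
        stacked = random_stacked(rng)
        beta = rng.standard_normal(8)
        for d in stacked.days:
            d.Y = d.X @ beta
        cp = CovParam(2, "diagonal")
        theta = cp.encode(np.zeros((8, 8)), 1.0)
        assert neg2_loglik(theta, stacked, method="ML") == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_matches_dense_mvn_oracle(self, method, rng):
        cp = CovParam(2, "diagonal")
        for _ in range(10):
            stacked = random_stacked(rng)
            G, s2 = random_cov(rng, 8)
            theta = cp.encode(G, s2)
            ours = neg2_loglik(theta, stacked, method=method)
            oracle = dense_neg2ll(stacked, G, s2, method)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_day_relabeling_invariance(self, rng):
        stacked = random_stacked(rng)
        cp = CovParam(2, "diagonal")
        G, s2 = random_cov(rng, 8)
        theta = cp.encode(G, s2)
        perm = StackedData(days=[stacked.days[i] for i in (2, 0, 3, 1)], k=2)
        assert neg2_loglik(theta, stacked, "REML") == pytest.approx(
            neg2_loglik(theta, perm, "REML"), abs=1e-10)

    def test_singular_cov_returns_large_value_not_exception(self, rng):
        stacked = random_stacked(rng)
        theta = np.r_[np.zeros(8), -800.0]   # G = 0 and sigma2 underflows: V singular
        value = neg2_loglik(theta, stacked, method="ML")
        assert np.isfinite(value) and value > 1e9
        assert neg2_loglik.last_penalized


class TestBlup:
    class _State:
        def __init__(self, G, sigma2, beta):
            self.G_hat, self.sigma2_hat, self.beta_hat = G, sigma2, beta

    def test_zero_G_gives_zero_blup(self, rng):
        stacked = random_stacked(rng)
        state = self._State(np.zeros((8, 8)), 1.0, rng.standard_normal(8))
        for d in stacked.days:
            np.testing.assert_array_equal(blup(state, d), np.zeros(8))

    def test_zero_residual_gives_zero_blup(self, rng):
        stacked = random_stacked(rng)
        beta = rng.standard_normal(8)
        d = stacked.days[0]
        d.Y = d.X @ beta
        G, s2 = random_cov(rng, 8)
        np.testing.assert_allclose(blup(self._State(G, s2, beta), d),
                                   np.zeros(8), atol=1e-12)

    def test_matches_dense_formula(self, rng):
        stacked = random_stacked(rng)
        G, s2 = random_cov(rng, 8)
        beta = rng.standard_normal(8)
        d = stacked.days[1]
        V = d.Z @ G @ d.Z.T + s2 * np.eye(d.n_rows)
        expected = G @ d.Z.T @ np.linalg.solve(V, d.Y - d.X @ beta)
        np.testing.assert_allclose(blup(self._State(G, s2, beta), d),
                                   expected, atol=1e-10)

    def test_blups_vanish_continuously_as_G_shrinks(self, rng):
        stacked = random_stacked(rng)
        G, s2 = random_cov(rng, 8)
        beta = rng.standard_normal(8)
        d = stacked.days[0]
        norms = [np.linalg.norm(blup(self._State(s * G, s2, beta), d))
                 for s in (1.0, 0.1, 0.01, 1e-4)]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]


class TestFit:
    def test_smoke_recovery(self, small_stacked, spec):
        result = fit(small_stacked)
        assert result.converged
        assert result.method == "REML"
        # six days is little data; just require the right ballpark
        net = slice(0, 6)
        assert np.abs(result.beta_hat[net] - spec.beta[net]).max() < 0.35
        assert set(result.blups) == {d.day_index for d in small_stacked.days}
        assert result.sigma2_hat > 0

    def test_blup_lookup_for_missing_day_raises(self, small_stacked):
        result = fit(small_stacked)
        with pytest.raises(KeyError):
            result.blup_for(999)

    def test_zero_variance_truth_consistency(self, spec):
        """Data generated with G = 0: sigma2_hat -> sigma2 and G_hat at the
        boundary when many days are pooled."""
        spec0 = ModelSpec(k=2, beta_ar=spec.beta_ar, beta_e=spec.beta_e,
                          beta_c=spec.beta_c, G=np.zeros((8, 8)), sigma2=0.02)
        data = simulate_dataset(SimConfig(spec=spec0, n_days=200, seed=55))
        result = fit(stack_dataset(data))
        assert result.sigma2_hat == pytest.approx(0.02, rel=0.10)
        assert np.diag(result.G_hat).max() < 0.01

    def test_ml_and_reml_converge_with_more_days(self, spec):
        diffs = {}
        for n_days, seed in ((8, 108), (144, 244)):
            data = simulate_dataset(SimConfig(spec=spec, n_days=n_days, seed=seed))
            st_ = stack_dataset(data)
            diffs[n_days] = np.abs(fit(st_, method="ML").beta_hat
                                   - fit(st_, method="REML").beta_hat).max()
        assert diffs[144] < diffs[8]

    def test_matches_statsmodels_mixedlm(self, spec):
        """Independent cross-check: the same variance-components model fitted
        by statsmodels MixedLM gives the same REML estimates."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        data = simulate_dataset(SimConfig(spec=spec, n_days=12, seed=11))
        stacked = stack_dataset(data)
        ours = fit(stacked, method="REML")
        X = np.vstack([d.X for d in stacked.days])
        Y = np.concatenate([d.Y for d in stacked.days])
        groups = np.concatenate([[d.day_index] * d.n_rows for d in stacked.days])
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(8)])
        df["y"], df["g"] = Y, groups
        m = MixedLM.from_formula(
            "y ~ 0 + " + " + ".join(f"x{j}" for j in range(8)), groups="g",
            vc_formula={f"v{j}": f"0 + x{j}" for j in range(8)},
            re_formula="0", data=df)
        theirs = m.fit(reml=True, method="lbfgs", maxiter=500)
        np.testing.assert_allclose(ours.beta_hat, theirs.fe_params.to_numpy(),
                                   atol=2e-3)
        assert ours.sigma2_hat == pytest.approx(theirs.scale, abs=2e-3)
        np.testing.assert_allclose(np.diag(ours.G_hat), theirs.vcomp, atol=2e-3)
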