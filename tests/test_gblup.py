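import numpy as np
import pandas as pd
import pytest

from gxepred import (
    MultiEnvGBLUP,
    SimConfig,
    UnivariateGBLUP,
    additive_grm,
    arc_cosine_kernel,
    metadata_design,
    predict_model_a,
    simulate_bundle,
    simulate_marker_matrix,
    standardize_spatial,
)
from gxepred.kernels import GenomicKernel


def _identity_kernel(n):
    return GenomicKernel([f"H{i}" for i in range(n)], np.eye(n))


def _reml_em_oracle(y, X, Z, max_iter=500_000, tol=1e-14):
    """Independent REML solver: the classical EM algorithm for
    y = X b + Z u + e with u ~ N(0, Vg I_q), iterated to convergence."""
    y = np.asarray(y, float)
    n = y.size
    q = Z.shape[1]
    vg, ve = y.var() / 2, y.var() / 2
    for _ in range(max_iter):
        V = vg * (Z @ Z.T) + ve * np.eye(n)
        Vinv = np.linalg.inv(V)
        P = Vinv - Vinv @ X @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        Py = P @ y
        ZtPy = Z.T @ Py
        vg_new = (vg**2 * (ZtPy @ ZtPy) + vg * q - vg**2 * np.trace(Z.T @ P @ Z)) / q
        ve_new = (ve**2 * (Py @ Py) + ve * n - ve**2 * np.trace(P)) / n
        if abs(vg_new - vg) + abs(ve_new - ve) < tol:
            vg, ve = vg_new, ve_new
            break
        vg, ve = vg_new, ve_new
    return vg, ve


class TestUnivariate:
    def test_matches_independent_em_reml_with_identity_kernel(self, rng):
        """Replicated one-way random-effects data, K = I: the spectral REML
        optimum must agree with a classical EM-REML fit run to convergence."""
        n_hybrids, reps = 30, 3
        hybrids = np.repeat([f"H{i}" for i in range(n_hybrids)], reps)
        u = rng.standard_normal(n_hybrids)
        y = 3.0 + np.repeat(u, reps) + rng.standard_normal(n_hybrids * reps)
        K = _identity_kernel(n_hybrids)
        fit = UnivariateGBLUP(kernel=K).fit(None, y, hybrids=hybrids)
        Z = np.kron(np.eye(n_hybrids), np.ones((reps, 1)))
        vg_em, ve_em = _reml_em_oracle(y, np.ones((len(y), 1)), Z)
        assert fit.vg_ == pytest.approx(vg_em, abs=1e-6)
        assert fit.ve_ == pytest.approx(ve_em, abs=1e-6)

    def test_equivalent_to_ridge_regression_oracle(self, rng):
        """GBLUP with K = ZZ'/c equals ridge on markers at lambda = Ve c/Vg."""
        n, m = 50, 100
        cfg = SimConfig(n_hybrids=n, n_markers=m, seed=21)
        M = simulate_marker_matrix(cfg)
        K = additive_grm(M)
        p = M.to_numpy().mean(axis=0) / 2
        Z = M.to_numpy(float) - 2 * p
        c = 2 * np.sum(p * (1 - p))
        beta_true = rng.normal(0, 0.1, size=m)
        y = 5.0 + Z @ beta_true + rng.standard_normal(n)
        fit = UnivariateGBLUP(kernel=K).fit(None, y, hybrids=M.index)

        lam = fit.ve_ * c / fit.vg_
        X = np.ones((n, 1))
        V = fit.vg_ * K.values + fit.ve_ * np.eye(n)
        b_gls = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, y))
        r = y - X @ b_gls
        alpha = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ r)
        u_ridge = Z @ alpha
        assert np.abs(fit.u_.to_numpy() - u_ridge).max() < 1e-6
        assert fit.beta_.iloc[0] == pytest.approx(b_gls[0], abs=1e-6)

    def test_null_genetic_variance_not_inflated(self):
        """Pure-noise phenotypes: estimated h2 below 0.05 in >=90% of seeds.

        A low-rank kernel (300 hybrids, 50 markers) leaves most directions
        purely residual, so the null genetic variance is well identified.
        """
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(n_hybrids=300, n_markers=50, seed=seed)
            M = simulate_marker_matrix(cfg)
            K = additive_grm(M)
            y = 4.0 + rng.standard_normal(300)
            fit = UnivariateGBLUP(kernel=K).fit(None, y, hybrids=M.index)
            hits += fit.h2_ < 0.05
        assert hits >= 0.9 * n_seeds

    def test_singular_design_lists_aliased_columns(self, rng):
        n = 30
        K = _identity_kernel(n)
        X = pd.DataFrame(
            {"intercept": 1.0, "a": rng.standard_normal(n)}, index=range(n)
        )
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="aliased"):
            UnivariateGBLUP(kernel=K).fit(X, rng.standard_normal(n),
                                          hybrids=[f"H{i}" for i in range(n)])

    def test_duplicate_marker_hybrid_projects_to_same_value(self, rng):
        cfg = SimConfig(n_hybrids=40, n_markers=120, seed=31)
        M = simulate_marker_matrix(cfg)
        M_new = pd.concat([M, M.iloc[[3]].rename(index={M.index[3]: "COPY"})])
        K_full = arc_cosine_kernel(M_new)
        y = rng.standard_normal(40)
        fit = UnivariateGBLUP(kernel=K_full).fit(None, y, hybrids=M.index)
        g = fit.genomic_values(pd.Index([M.index[3], "COPY"]), K_full)
        assert abs(g.iloc[0] - g.iloc[1]) < 1e-8

    def test_prediction_reproduces_fitted_values_in_sample(self, rng):
        n = 25
        K = _identity_kernel(n)
        hybrids = [f"H{i}" for i in range(n)]
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.standard_normal(n)})
        y = 2.0 + X["x"].to_numpy() + rng.standard_normal(n)
        fit = UnivariateGBLUP(kernel=K).fit(X, y, hybrids=hybrids)
        manual = X.to_numpy() @ fit.beta_.to_numpy() + fit.u_.reindex(hybrids).to_numpy()
        pred = fit.predict(X, hybrids=hybrids)
        assert np.allclose(pred, manual, atol=1e-10)

    def test_record_order_permutation_invariance(self, rng):
        cfg = SimConfig(n_hybrids=35, n_markers=80, seed=41)
        M = simulate_marker_matrix(cfg)
        K = additive_grm(M)
        y = rng.standard_normal(35)
        fit1 = UnivariateGBLUP(kernel=K).fit(None, y, hybrids=M.index)
        perm = rng.permutation(35)
        fit2 = UnivariateGBLUP(kernel=K).fit(None, y[perm], hybrids=M.index[perm])
        assert fit1.vg_ == pytest.approx(fit2.vg_, rel=1e-6, abs=1e-9)
        assert np.allclose(
            fit1.u_.sort_index(), fit2.u_.sort_index(), atol=1e-7
        )


@pytest.fixture(scope="module")
def mv_bundle():
    cfg = SimConfig(
        n_hybrids=100, n_markers=150, n_locations=4, n_years=2, n_states=2,
        outlier_rate=0.0, low_stand_rate=0.0, disease_trial_rate=0.0, seed=51,
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="module")
def mv_fit(mv_bundle):
    std = standardize_spatial(mv_bundle.trait)
    K = arc_cosine_kernel(mv_bundle.geno)
    return MultiEnvGBLUP(kernel=K, max_iter=200, tol=1e-6, min_hybrids_per_env=5).fit(
        std.records
    )


class TestMultiEnv:
    def test_loglik_monotone_nondecreasing(self, mv_fit):
        ll = mv_fit.loglik_trace_
        assert np.all(np.diff(ll) >= -1e-6 * (np.abs(ll[:-1]) + 1))

    def test_dense_genetic_values_cover_all_pairs(self, mv_bundle, mv_fit):
        assert mv_fit.g_.shape == (8, 100)
        assert np.isfinite(mv_fit.g_.to_numpy()).all()
        # environment genetic variances should be positive
        assert (np.diag(mv_fit.Sigma_g_.to_numpy()) > 0).all()
        assert (mv_fit.sigma_e_ > 0).all()

    def test_single_environment_reduces_to_univariate(self, rng):
        cfg = SimConfig(n_hybrids=150, n_markers=200, n_locations=1, n_years=1,
                        n_states=1, frac_hybrids_per_env=1.0,
                        outlier_rate=0.0, low_stand_rate=0.0,
                        disease_trial_rate=0.0, seed=61)
        b = simulate_bundle(cfg)
        std = standardize_spatial(b.trait)
        K = arc_cosine_kernel(b.geno)
        mv = MultiEnvGBLUP(kernel=K, max_iter=20000, tol=1e-12,
                           min_hybrids_per_env=5).fit(std.records)
        # univariate REML on the same plot records, no fixed effects
        # (standardized data are exactly mean-zero)
        rec = std.records
        empty_X = pd.DataFrame(index=range(len(rec)))
        uni = UnivariateGBLUP(kernel=K).fit(empty_X, rec["ystar"], hybrids=rec["hybrid"])
        assert mv.Sigma_g_.iloc[0, 0] == pytest.approx(uni.vg_, abs=1e-4)
        assert mv.sigma_e_.iloc[0] == pytest.approx(uni.ve_, abs=1e-4)

    def test_duplicated_environment_gives_high_genetic_correlation(self, mv_bundle):
        std = standardize_spatial(mv_bundle.trait)
        rec = std.records
        env0 = rec["env_id"].iloc[0]
        sub = rec[rec["env_id"] == env0]
        dup = sub.assign(env_id="DUP_" + env0)
        both = pd.concat([sub, dup], ignore_index=True)
        K = arc_cosine_kernel(mv_bundle.geno)
        mv = MultiEnvGBLUP(kernel=K, max_iter=300, tol=1e-8, min_hybrids_per_env=5).fit(both)
        S = mv.Sigma_g_.to_numpy()
        rho = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert rho > 0.95

    def test_disjoint_hybrid_sets_rejected(self):
        recs = pd.DataFrame(
            {
                "env_id": ["A"] * 5 + ["B"] * 5,
                "hybrid": [f"H{i}" for i in range(5)] + [f"H{i}" for i in range(5, 10)],
                "ystar": np.arange(10, dtype=float) / 10 - 0.45,
            }
        )
        K = _identity_kernel(10)
        with pytest.raises(ValueError, match="disconnected"):
            MultiEnvGBLUP(kernel=K, min_hybrids_per_env=2).fit(recs)

    def test_too_small_environment_rejected(self, mv_bundle):
        std = standardize_spatial(mv_bundle.trait)
        K = arc_cosine_kernel(mv_bundle.geno)
        with pytest.raises(ValueError, match="minimum"):
            MultiEnvGBLUP(kernel=K, min_hybrids_per_env=1000).fit(std.records)

    def test_record_order_invariance(self, mv_bundle, mv_fit, rng):
        std = standardize_spatial(mv_bundle.trait)
        shuffled = std.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        K = arc_cosine_kernel(mv_bundle.geno)
        mv2 = MultiEnvGBLUP(kernel=K, max_iter=200, tol=1e-6, min_hybrids_per_env=5).fit(
            shuffled
        )
        assert np.allclose(
            mv_fit.Sigma_g_.to_numpy(), mv2.Sigma_g_.to_numpy(), atol=1e-8
        )


class TestSerialization:
    def test_fit_objects_round_trip_through_json_and_csv(self, tmp_path, mv_fit, rng):
        import json

        from gxepred.gblup import save_multivariate_fit, save_univariate_fit

        n = 20
        K = _identity_kernel(n)
        uni = UnivariateGBLUP(kernel=K).fit(
            None, rng.standard_normal(n), hybrids=[f"H{i}" for i in range(n)]
        )
        save_univariate_fit(uni, tmp_path / "uni")
        payload = json.loads((tmp_path / "uni" / "fit.json").read_text())
        assert payload["vg"] == pytest.approx(uni.vg_)
        u = pd.read_csv(tmp_path / "uni" / "u.csv", index_col="hybrid")
        assert np.allclose(u.iloc[:, 0], uni.u_.reindex(u.index))

        save_multivariate_fit(mv_fit, tmp_path / "mv")
        S = pd.read_csv(tmp_path / "mv" / "sigma_g.csv", index_col="env_id")
        assert np.allclose(S.to_numpy(), mv_fit.Sigma_g_.to_numpy())
        g = pd.read_csv(tmp_path / "mv" / "g.csv", index_col="env_id")
        assert g.shape == mv_fit.g_.shape


class TestModelAPrediction:
    def test_new_year_predictions_positively_correlated(self, small_bundle):
        train, test = small_bundle.split()
        from gxepred import aggregate_metadata, drop_aliased, qc_filter

        qc, _ = qc_filter(train)
        meta = aggregate_metadata(small_bundle.meta)
        K = arc_cosine_kernel(small_bundle.geno)
        pair = qc.groupby(["env_id", "hybrid"], as_index=False)["yield_mg_ha"].mean()
        X = drop_aliased(metadata_design(meta, pair["env_id"]))
        fit = UnivariateGBLUP(kernel=K).fit(
            X, pair["yield_mg_ha"].to_numpy(), hybrids=pair["hybrid"]
        )
        preds = predict_model_a(fit, meta, small_bundle.template, K)
        assert len(preds) == len(small_bundle.template)
        assert preds["yield_mg_ha"].notna().all()
        truth = small_bundle.truth.genetic_values
        cors = []
        for env, sub in preds.groupby("env_id"):
            g = truth.loc[env].reindex(sub["hybrid"]).to_numpy()
            cors.append(np.corrcoef(sub["yield_mg_ha"], g)[0, 1])
        assert np.mean(cors) > 0.0
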