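"""Genomic BLUP models.

Two estimators implement the two halves of the winning competition
strategy:

``UnivariateGBLUP``
    A single-trait linear mixed model y = X beta + Z u + e with
    u ~ N(0, Vg K) for a genomic kernel K, fitted by EMMA-style spectral
    REML: one eigendecomposition of the kernel projected off the fixed
    effects reduces the problem to a one-dimensional likelihood in the
    variance ratio Vg/Ve, which is optimized exactly. Fixed effects are
    environment metadata (station, irrigation, treatment class, previous
    crop class).

``MultiEnvGBLUP``
    The unstructured multi-environment model on standardized phenotypes,
    y* = g + e with g ~ N(0, Sigma_g (x) K) and e ~ N(0, Sigma_e (x) I):
    an environment-by-environment genetic covariance crossed with the
    genomic relationship matrix, and independent heteroscedastic
    residuals. Fitted by an exact expectation-maximization algorithm whose
    E-step conditions on all observed records jointly (replicate means
    enter the Gaussian model; within-replicate contrasts inform the
    residual variances analytically). The observed-data log-likelihood is
    monotone non-decreasing across iterations and is checked at every
    step. Genetic values are imputed for every (environment, hybrid)
    pair — observed or not — from the conditional expectation given K and
    Sigma_g.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .kernels import GenomicKernel

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateGBLUP",
    "MultiEnvGBLUP",
    "metadata_design",
    "drop_aliased",
    "fit_univariate_gblup",
    "predict_model_a",
    "fit_multivariate_gblup",
    "save_univariate_fit",
    "save_multivariate_fit",
]


# --------------------------------------------------------------------------
# fixed-effect design
# --------------------------------------------------------------------------

_DESIGN_FACTORS = ("station", "treatment_class", "previous_crop_class")


def metadata_design(
    meta: pd.DataFrame,
    env_ids,
    columns: pd.Index | None = None,
) -> pd.DataFrame:
    """Fixed-effect design rows for a sequence of environment ids.

    Dummy-codes station, treatment class and previous-crop class (first
    level sorted alphabetically is the reference) plus an irrigation
    indicator and an intercept. State is intentionally omitted: stations
    are nested within states, so state columns would be aliased.

    When ``columns`` (a fitted design's columns) is given, the new design
    is aligned to them; levels unseen in training collapse to the
    reference level with a warning.
    """
    m = meta.set_index("env_id")
    env_ids = list(env_ids)
    missing = [e for e in env_ids if e not in m.index]
    if missing:
        raise KeyError(f"environments missing from metadata: {missing[:5]}")
    rows = m.loc[env_ids]
    parts = {"intercept": np.ones(len(env_ids))}
    if "irrigated" in rows:
        parts["irrigated"] = rows["irrigated"].astype(bool).astype(float).to_numpy()
    design = pd.DataFrame(parts, index=env_ids)
    for factor in _DESIGN_FACTORS:
        if factor not in rows:
            continue
        dummies = pd.get_dummies(rows[factor].astype(str), prefix=factor, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        design = pd.concat([design, dummies.iloc[:, 1:]], axis=1)
    if columns is not None:
        unseen = [c for c in design.columns if c not in columns]
        if unseen:
            warnings.warn(
                f"metadata levels unseen in training mapped to reference: {unseen}",
                stacklevel=2,
            )
        design = design.reindex(columns=columns, fill_value=0.0)
        design["intercept"] = 1.0
    design.index.name = "env_id"
    return design


def drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent design columns (keeping the earliest ones).

    Mirrors how standard LMM software handles aliased factor levels in
    unbalanced designs; the dropped effects are absorbed by the retained
    columns. Use before :class:`UnivariateGBLUP`, which itself insists on
    a full-rank design.
    """
    A = X.to_numpy(dtype=float)
    _, R, piv = sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank == A.shape[1]:
        return X
    keep = sorted(piv[:rank])
    dropped = [X.columns[j] for j in piv[rank:]]
    logger.warning("dropping aliased design columns: %s", dropped)
    return X.iloc[:, keep]


def _check_full_rank(X: np.ndarray, names) -> None:
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed-effect design is singular; aliased columns: {aliased}")


# --------------------------------------------------------------------------
# univariate spectral REML
# --------------------------------------------------------------------------


class UnivariateGBLUP(BaseEstimator, RegressorMixin):
    """Single-trait GBLUP fitted by spectral REML (EMMA).

    Parameters
    ----------
    kernel : GenomicKernel
        Relationship matrix covering at least the training hybrids.
    ridge_eps : float
        Relative ridge added to the training kernel block when projecting
        genomic values onto hybrids outside the training set.
    log_ratio_bounds : tuple
        Search bounds for log10(Vg/Ve).

    Attributes
    ----------
    beta_ : pd.Series            fixed-effect estimates
    vg_, ve_ : float             variance components (REML)
    h2_ : float                  Vg / (Vg + Ve)
    u_ : pd.Series               genomic values of training hybrids
    loglik_ : float              restricted log-likelihood at the optimum
    """

    def __init__(self, kernel: GenomicKernel | None = None, ridge_eps: float = 1e-8,
                 log_ratio_bounds: tuple = (-8.0, 8.0)):
        self.kernel = kernel
        self.ridge_eps = ridge_eps
        self.log_ratio_bounds = log_ratio_bounds

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, hybrids=None):
        if self.kernel is None:
            raise ValueError("a GenomicKernel must be supplied")
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if hybrids is None:
            raise ValueError("per-record hybrid labels are required")
        hybrids = pd.Index(hybrids)
        if len(hybrids) != n:
            raise ValueError("hybrids and y must have equal length")

        if X is None:
            Xdf = pd.DataFrame({"intercept": np.ones(n)})
        elif isinstance(X, pd.DataFrame):
            Xdf = X.reset_index(drop=True).astype(float)
        else:
            X = np.asarray(X, dtype=float)
            Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        Xm = Xdf.to_numpy()
        _check_full_rank(Xm, list(Xdf.columns))
        p = Xm.shape[1]

        train_hybrids = pd.Index(pd.unique(hybrids))
        Ksub = self.kernel.loc(train_hybrids)
        codes = train_hybrids.get_indexer(hybrids)
        A = Ksub[np.ix_(codes, codes)]

        # spectral reduction on the complement of col(X)
        XtX = Xm.T @ Xm
        Px = Xm @ np.linalg.solve(XtX, Xm.T)
        S = np.eye(n) - Px
        M = S @ (A + np.eye(n)) @ S
        w, U = np.linalg.eigh(M)
        order = np.argsort(w)[::-1][: n - p]
        xi = np.clip(w[order] - 1.0, 0.0, None)
        eta = U[:, order].T @ y

        def neg_restricted_ll(log10_phi: float) -> float:
            phi = 10.0 ** log10_phi
            denom = phi * xi + 1.0
            ve = float(np.sum(eta**2 / denom)) / (n - p)
            return 0.5 * ((n - p) * (np.log(2 * np.pi * ve) + 1.0) + np.sum(np.log(denom)))

        lo, hi = self.log_ratio_bounds
        grid = np.linspace(lo, hi, 81)
        values = [neg_restricted_ll(g) for g in grid]
        best = int(np.argmin(values))
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        candidates = [(res.fun, float(res.x))] + [(values[0], grid[0])]
        fun, log10_phi = min(candidates)
        phi = 10.0 ** log10_phi
        if log10_phi <= lo + 1e-9:
            phi = 0.0  # boundary: no genetic variance

        denom = phi * xi + 1.0
        ve = float(np.sum(eta**2 / denom)) / (n - p)
        vg = phi * ve
        self.vg_, self.ve_ = vg, ve
        self.h2_ = vg / (vg + ve)
        self.loglik_ = -neg_restricted_ll(np.log10(phi) if phi > 0 else lo)

        V = phi * A + np.eye(n)
        cho = sla.cho_factor(V, lower=True)
        Vinv_X = sla.cho_solve(cho, Xm)
        Vinv_y = sla.cho_solve(cho, y)
        XtVinvX = Xm.T @ Vinv_X
        beta = np.linalg.solve(XtVinvX, Xm.T @ Vinv_y)
        resid = y - Xm @ beta
        u_train = phi * (Ksub[:, codes] @ sla.cho_solve(cho, resid))

        self.beta_ = pd.Series(beta, index=Xdf.columns)
        self.feature_names_ = list(Xdf.columns)
        self.u_ = pd.Series(u_train, index=train_hybrids, name="genomic_value")
        self.train_hybrids_ = train_hybrids
        self._proj_weights = None
        return self

    # -- prediction --------------------------------------------------------

    def genomic_values(self, hybrids, kernel: GenomicKernel | None = None) -> pd.Series:
        """Genomic values for arbitrary hybrids.

        Training hybrids return their BLUPs; new hybrids are projected
        through the kernel, g_new = K_cross (K_train + eps I)^-1 g_train.
        """
        hybrids = pd.Index(hybrids)
        known = hybrids.isin(self.train_hybrids_)
        out = pd.Series(np.nan, index=hybrids, dtype=float)
        out[known] = self.u_.reindex(hybrids[known]).to_numpy()
        new = hybrids[~known]
        if len(new):
            kern = kernel or self.kernel
            try:
                K_cross = kern.loc(new, self.train_hybrids_)
            except KeyError as exc:
                raise KeyError(f"hybrids absent from genotypes: {exc}") from exc
            if self._proj_weights is None:
                K_train = kern.loc(self.train_hybrids_)
                eps = self.ridge_eps * float(np.mean(np.diag(K_train)))
                self._proj_weights = np.linalg.solve(
                    K_train + eps * np.eye(len(K_train)), self.u_.to_numpy()
                )
            out[~known] = K_cross @ self._proj_weights
        return out

    def predict(self, X, hybrids=None, kernel: GenomicKernel | None = None) -> np.ndarray:
        """yhat = x' beta + g(hybrid) for aligned design rows and hybrids."""
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.feature_names_, fill_value=0.0).to_numpy(float)
        else:
            X = np.asarray(X, dtype=float)
        fixed = X @ self.beta_.to_numpy()
        if hybrids is None:
            return fixed
        return fixed + self.genomic_values(hybrids, kernel).to_numpy()


# --------------------------------------------------------------------------
# multivariate (unstructured) EM
# --------------------------------------------------------------------------


class MultiEnvGBLUP(BaseEstimator):
    """Unstructured multi-environment GBLUP fitted by exact EM.

    Parameters
    ----------
    kernel : GenomicKernel
        Relationship matrix over all genotyped hybrids.
    max_iter, tol : int, float
        EM stops when the maximum relative parameter change drops below
        ``tol`` or after ``max_iter`` iterations.
    min_hybrids_per_env : int
        Environments with fewer observed hybrids raise an error.
    psd_eps : float
        Eigenvalue floor (relative to the largest) used when projecting
        Sigma_g back to the PSD cone each iteration.
    check_monotone : bool
        Assert the observed-data log-likelihood never decreases.

    Attributes
    ----------
    Sigma_g_ : pd.DataFrame      environment x environment genetic covariance
    sigma_e_ : pd.Series         per-environment residual variances
    g_ : pd.DataFrame            dense environment x hybrid genetic values
    loglik_trace_ : np.ndarray   observed-data log-likelihood per iteration
    n_iter_, converged_
    """

    def __init__(
        self,
        kernel: GenomicKernel | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        min_hybrids_per_env: int = 30,
        psd_eps: float = 1e-8,
        check_monotone: bool = True,
    ):
        self.kernel = kernel
        self.max_iter = max_iter
        self.tol = tol
        self.min_hybrids_per_env = min_hybrids_per_env
        self.psd_eps = psd_eps
        self.check_monotone = check_monotone

    def fit(self, records: pd.DataFrame, y=None):
        """Fit from long-format standardized records (env_id, hybrid, ystar)."""
        if self.kernel is None:
            raise ValueError("a GenomicKernel must be supplied")
        for col in ("env_id", "hybrid", "ystar"):
            if col not in records.columns:
                raise ValueError(f"records are missing the '{col}' column")
        kern = self.kernel
        all_hybrids = pd.Index(kern.hybrids)
        if not pd.Index(records["hybrid"].unique()).isin(all_hybrids).all():
            missing = set(records["hybrid"]) - set(all_hybrids)
            raise KeyError(f"hybrids absent from kernel: {sorted(missing)[:5]}")

        grouped = records.groupby(["env_id", "hybrid"], sort=True)["ystar"]
        pair_mean = grouped.mean()
        pair_n = grouped.count()
        pair_ss = (grouped.var(ddof=0) * pair_n).fillna(0.0)  # within-pair SS

        envs = list(pair_mean.index.get_level_values(0).unique())
        E = len(envs)
        env_of = {env: k for k, env in enumerate(envs)}

        obs_idx: list[np.ndarray] = []
        ybar: list[np.ndarray] = []
        reps: list[np.ndarray] = []
        ss_within = np.zeros(E)
        nplots = np.zeros(E)
        for k, env in enumerate(envs):
            sub_mean = pair_mean.loc[env]
            sub_n = pair_n.loc[env]
            if len(sub_mean) < self.min_hybrids_per_env:
                raise ValueError(
                    f"environment {env} has {len(sub_mean)} hybrids; "
                    f"minimum is {self.min_hybrids_per_env}"
                )
            hy = pd.Index(sub_mean.index)
            obs_idx.append(all_hybrids.get_indexer(hy))
            ybar.append(sub_mean.to_numpy(float))
            reps.append(sub_n.to_numpy(float))
            ss_within[k] = float(pair_ss.loc[env].sum())
            nplots[k] = float(sub_n.sum())

        if E > 1:
            self._check_overlap(envs, obs_idx)

        K = kern.values
        H = len(all_hybrids)
        idx_all = np.concatenate(obs_idx)
        sizes = [len(ix) for ix in obs_idx]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        N = int(offsets[-1])
        Kobs = K[np.ix_(idx_all, idx_all)]
        yv = np.concatenate(ybar)
        rv = np.concatenate(reps)
        env_block = np.repeat(np.arange(E), sizes)

        Sigma_g, sig2 = self._initialize(envs, obs_idx, ybar, reps, ss_within, nplots)

        ll_trace = []
        converged = False
        const_reps = float(
            np.sum([(nplots[k] - sizes[k]) * np.log(2 * np.pi) for k in range(E)])
        )
        for iteration in range(self.max_iter):
            d = sig2[env_block] / rv  # noise variance of each replicate mean
            V = Sigma_g[np.ix_(env_block, env_block)] * Kobs
            V[np.diag_indices_from(V)] += d
            L, low = sla.cho_factor(V, lower=True)
            alpha = sla.cho_solve((L, low), yv)
            Vinv = sla.cho_solve((L, low), np.eye(N))

            # observed-data log-likelihood (replicate means + within-pair SS)
            ll = -0.5 * (
                2.0 * float(np.sum(np.log(np.diag(L))))
                + float(yv @ alpha)
                + N * np.log(2 * np.pi)
            )
            ll += -0.5 * const_reps + float(
                np.sum(
                    -0.5 * (nplots - np.array(sizes)) * np.log(sig2)
                    - 0.5 * ss_within / sig2
                )
            )
            if self.check_monotone and ll_trace:
                slack = 1e-6 * (abs(ll_trace[-1]) + 1.0)
                if ll < ll_trace[-1] - slack:
                    raise AssertionError(
                        f"EM log-likelihood decreased at iteration {iteration}: "
                        f"{ll_trace[-1]:.8f} -> {ll:.8f}"
                    )
            ll_trace.append(ll)

            # sufficient statistics in environment-block form
            T_col = np.empty((N, E))
            for b in range(E):
                sl = slice(offsets[b], offsets[b + 1])
                T_col[:, b] = Kobs[:, sl] @ alpha[sl]
            S_mat = np.empty((E, E))
            Q_mat = np.empty((E, E))
            VK = Vinv * Kobs
            for a in range(E):
                sa = slice(offsets[a], offsets[a + 1])
                S_mat[a] = alpha[sa] @ T_col[sa]
                Q_mat[a] = np.add.reduceat(VK[sa].sum(axis=0), offsets[:-1])
            # posterior moments at observed entries via V = Gamma + D identities
            post_mean_obs = yv - d * alpha
            post_var_obs = d - d**2 * np.diag(Vinv)

            Sigma_new = Sigma_g + Sigma_g @ ((S_mat - Q_mat) / H) @ Sigma_g
            Sigma_new = 0.5 * (Sigma_new + Sigma_new.T)
            Sigma_new = self._project_psd(Sigma_new)

            sig2_new = np.empty(E)
            for k in range(E):
                sl = slice(offsets[k], offsets[k + 1])
                dev = yv[sl] - post_mean_obs[sl]
                sig2_new[k] = (
                    ss_within[k]
                    + float(np.sum(rv[sl] * (dev**2 + post_var_obs[sl])))
                ) / nplots[k]
            sig2_new = np.clip(sig2_new, 1e-10, None)

            denom = max(np.abs(Sigma_g).max(), 1e-12)
            delta = max(
                np.abs(Sigma_new - Sigma_g).max() / denom,
                np.abs(sig2_new - sig2).max() / max(sig2.max(), 1e-12),
            )
            Sigma_g, sig2 = Sigma_new, sig2_new
            if delta < self.tol:
                converged = True
                break

        # final E-step with converged parameters: dense genetic values
        d = sig2[env_block] / rv
        V = Sigma_g[np.ix_(env_block, env_block)] * Kobs
        V[np.diag_indices_from(V)] += d
        L, low = sla.cho_factor(V, lower=True)
        alpha = sla.cho_solve((L, low), yv)
        B = K[:, idx_all]  # H x N
        A_mat = np.empty((N, E))
        for e in range(E):
            A_mat[:, e] = Sigma_g[e, env_block] * alpha
        G_dense = (B @ A_mat).T  # E x H

        self.environments_ = envs
        self.Sigma_g_ = pd.DataFrame(Sigma_g, index=envs, columns=envs)
        self.sigma_e_ = pd.Series(sig2, index=envs, name="residual_variance")
        self.g_ = pd.DataFrame(G_dense, index=envs, columns=all_hybrids)
        self.loglik_trace_ = np.asarray(ll_trace)
        self.n_iter_ = len(ll_trace)
        self.converged_ = converged
        fitted = pd.Series(yv - d * alpha, index=pd.MultiIndex.from_arrays(
            [np.repeat(envs, sizes), all_hybrids[idx_all]], names=["env_id", "hybrid"]))
        self.residuals_ = pd.Series(yv, index=fitted.index) - fitted
        if not converged:
            logger.warning("EM reached max_iter=%d without convergence", self.max_iter)
        return self

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _check_overlap(envs, obs_idx) -> None:
        """All environments must be linked through shared hybrids."""
        E = len(envs)
        parent = list(range(E))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        sets = [set(ix.tolist()) for ix in obs_idx]
        for a in range(E):
            for b in range(a + 1, E):
                if sets[a] & sets[b]:
                    ra, rb = find(a), find(b)
                    parent[ra] = rb
        roots = {find(a) for a in range(E)}
        if len(roots) > 1:
            raise ValueError(
                "environments split into disconnected hybrid sets; "
                "between-environment covariances are unidentifiable"
            )

    def _project_psd(self, S: np.ndarray) -> np.ndarray:
        w, U = np.linalg.eigh(S)
        floor = self.psd_eps * max(w.max(), 1e-12)
        if w.min() >= floor:
            return S
        w = np.clip(w, floor, None)
        return (U * w) @ U.T

    def _initialize(self, envs, obs_idx, ybar, reps, ss_within, nplots):
        """Method-of-moments start: pairwise covariances over shared hybrids."""
        E = len(envs)
        sig2 = np.empty(E)
        var_bar = np.array([np.var(y, ddof=1) if len(y) > 1 else 1.0 for y in ybar])
        for k in range(E):
            df = nplots[k] - len(obs_idx[k])
            if df > 0 and ss_within[k] > 0:
                sig2[k] = ss_within[k] / df
            else:
                sig2[k] = 0.5 * var_bar[k] * float(np.mean(reps[k]))
        Sigma = np.zeros((E, E))
        for a in range(E):
            rbar = float(np.mean(reps[a]))
            Sigma[a, a] = max(var_bar[a] - sig2[a] / rbar, 0.05 * var_bar[a])
        maps = [dict(zip(obs_idx[a].tolist(), ybar[a])) for a in range(E)]
        for a in range(E):
            for b in range(a + 1, E):
                shared = sorted(set(maps[a]) & set(maps[b]))
                if len(shared) >= 3:
                    ya = np.array([maps[a][i] for i in shared])
                    yb = np.array([maps[b][i] for i in shared])
                    cov = float(np.cov(ya, yb, ddof=1)[0, 1])
                    cap = 0.95 * np.sqrt(Sigma[a, a] * Sigma[b, b])
                    Sigma[a, b] = Sigma[b, a] = np.clip(cov, -cap, cap)
        return self._project_psd(Sigma), sig2


# --------------------------------------------------------------------------
# serialization: a JSON of scalars/params plus matrix CSVs
# --------------------------------------------------------------------------


def save_univariate_fit(fit: UnivariateGBLUP, directory) -> None:
    """Write a fitted univariate model as ``fit.json`` + ``u.csv``."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": "univariate_gblup",
        "vg": fit.vg_,
        "ve": fit.ve_,
        "h2": fit.h2_,
        "loglik": fit.loglik_,
        "ridge_eps": fit.ridge_eps,
        "beta": fit.beta_.to_dict(),
        "feature_names": fit.feature_names_,
    }
    (directory / "fit.json").write_text(json.dumps(payload, indent=2))
    fit.u_.rename_axis("hybrid").to_csv(directory / "u.csv")


def save_multivariate_fit(fit: MultiEnvGBLUP, directory) -> None:
    """Write a fitted multi-environment model as ``fit.json`` +
    ``sigma_g.csv`` / ``sigma_e.csv`` / ``g.csv``."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": "multi_env_gblup",
        "max_iter": fit.max_iter,
        "tol": fit.tol,
        "min_hybrids_per_env": fit.min_hybrids_per_env,
        "n_iter": int(fit.n_iter_),
        "converged": bool(fit.converged_),
        "loglik_trace": [float(v) for v in fit.loglik_trace_],
        "environments": list(fit.environments_),
    }
    (directory / "fit.json").write_text(json.dumps(payload, indent=2))
    fit.Sigma_g_.rename_axis("env_id").to_csv(directory / "sigma_g.csv")
    fit.sigma_e_.rename_axis("env_id").to_csv(directory / "sigma_e.csv")
    fit.g_.rename_axis("env_id").to_csv(directory / "g.csv")


# --------------------------------------------------------------------------
# thin functional wrappers
# --------------------------------------------------------------------------


def fit_univariate_gblup(y, X, K: GenomicKernel, hybrids, **kwargs) -> UnivariateGBLUP:
    return UnivariateGBLUP(kernel=K, **kwargs).fit(X, y, hybrids=hybrids)


def fit_multivariate_gblup(ystar_records: pd.DataFrame, K: GenomicKernel, **kwargs) -> MultiEnvGBLUP:
    return MultiEnvGBLUP(kernel=K, **kwargs).fit(ystar_records)


def predict_model_a(
    fit: UnivariateGBLUP,
    meta_new: pd.DataFrame,
    template: pd.DataFrame,
    kernel: GenomicKernel | None = None,
) -> pd.DataFrame:
    """Model A predictions for every (environment, hybrid) template pair.

    yhat(env, hybrid) = x(env)' beta + g(hybrid); genomic values of
    hybrids outside the training set are kernel projections.
    """
    design = metadata_design(meta_new, template["env_id"], columns=pd.Index(fit.feature_names_))
    g = fit.genomic_values(pd.Index(template["hybrid"].unique()), kernel)
    out = template[["env_id", "hybrid"]].copy()
    out["yield_mg_ha"] = (
        design.to_numpy() @ fit.beta_.to_numpy()
        + g.reindex(template["hybrid"]).to_numpy()
    )
    out.attrs["model"] = "A"
    return out
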