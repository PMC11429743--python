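"""Environment-mean and environment-SD models (the environmental half of
the location-specific model).

The environment-mean model is a debiased composite: the average of three
sub-models — a random forest of the environmental covariates, a ridge
regression of the covariates (penalty by efficient leave-one-out
cross-validation), and ordinary least squares on the location metadata
design — followed by a linear "unshrinkage" step that regresses observed
training means on the composite and applies the fitted line to all
predictions. Regularized composites compress toward the grand mean; the
debias step restores the observed scale, which matters when the score is
an absolute-error metric rather than a rank correlation.

The SD model predicts per-environment phenotypic standard deviations from
covariates with a random forest, with predictions floored at 10% of the
smallest training SD so downstream rescaling stays positive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, RidgeCV

from .gblup import metadata_design

__all__ = [
    "EnvMeanModel",
    "EnvSdModel",
    "fit_env_mean_model",
    "predict_env_means",
    "fit_env_sd_model",
    "predict_env_sd",
]


def _covariate_matrix(ecs: pd.DataFrame, columns=None, medians=None):
    """Numeric covariate matrix keyed by env_id, median-imputed."""
    if "env_id" not in ecs.columns:
        raise ValueError("covariate table must have an 'env_id' column")
    X = ecs.set_index("env_id")
    X = X.apply(pd.to_numeric, errors="coerce")
    if columns is not None:
        missing = [c for c in columns if c not in X.columns]
        if missing:
            raise KeyError(f"covariate column(s) missing: {missing}")
        X = X[list(columns)]
    if medians is None:
        medians = X.median()
    X = X.fillna(medians)
    return X, medians


class EnvMeanModel(BaseEstimator, RegressorMixin):
    """Debiased composite predictor of environment mean yield (Mg/ha).

    Attributes
    ----------
    debias_intercept_, debias_slope_ : float
        Coefficients (a, b) of the unshrinkage regression; the final
        prediction is a + b * composite.
    submodel_r2_ : dict
        Training diagnostics: out-of-bag R^2 for the forest, in-sample
        R^2 for ridge and least squares.
    fitted_ : pd.Series
        Debiased predictions for the training environments.
    """

    def __init__(self, n_trees: int = 500, random_state: int = 0,
                 ridge_alphas=None, min_train_envs: int = 20):
        self.n_trees = n_trees
        self.random_state = random_state
        self.ridge_alphas = ridge_alphas
        self.min_train_envs = min_train_envs

    def fit(self, env_means: pd.Series, ecs: pd.DataFrame, meta: pd.DataFrame):
        env_means = pd.Series(env_means).dropna()
        envs = list(env_means.index)
        if len(envs) < self.min_train_envs:
            warnings.warn(
                f"only {len(envs)} training environments (< {self.min_train_envs}); "
                "environment-mean model may be unstable",
                stacklevel=2,
            )
        X_all, self.medians_ = _covariate_matrix(ecs)
        self.covariate_columns_ = list(X_all.columns)
        X = X_all.reindex(envs).fillna(self.medians_).to_numpy(float)
        y = env_means.to_numpy(float)

        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            random_state=self.random_state,
            oob_score=True,
            bootstrap=True,
        ).fit(X, y)
        # the composite (and hence the debias fit) uses the same in-sample
        # prediction path as `predict`, so fitted values and predictions
        # coincide exactly on training environments; OOB accuracy is kept
        # as a diagnostic
        rf_train = self.forest_.predict(X)
        oob = np.asarray(self.forest_.oob_prediction_, dtype=float)

        alphas = self.ridge_alphas if self.ridge_alphas is not None else np.logspace(-3, 4, 29)
        self.ridge_ = RidgeCV(alphas=alphas).fit(X, y)
        ridge_train = self.ridge_.predict(X)

        D = metadata_design(meta, envs)
        self.design_columns_ = D.columns
        self.ls_ = LinearRegression(fit_intercept=False).fit(D.to_numpy(float), y)
        ls_train = self.ls_.predict(D.to_numpy(float))

        composite = (rf_train + ridge_train + ls_train) / 3.0
        if np.std(composite) < 1e-12:
            raise ValueError(
                "composite prediction is constant across training environments; "
                "debias slope undefined"
            )
        b, a = np.polyfit(composite, y, 1)
        self.debias_intercept_, self.debias_slope_ = float(a), float(b)

        def _r2(pred):
            ss = np.sum((y - pred) ** 2)
            return 1.0 - ss / np.sum((y - y.mean()) ** 2)

        self.submodel_r2_ = {
            "random_forest_oob": _r2(np.where(np.isfinite(oob), oob, rf_train)),
            "ridge": _r2(ridge_train),
            "least_squares": _r2(ls_train),
        }
        self.fitted_ = pd.Series(a + b * composite, index=envs, name="env_mean_hat")
        self.train_envs_ = envs
        return self

    def composite(self, ecs: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
        """Raw (biased) composite prediction for the envs listed in ``ecs``."""
        X_df, _ = _covariate_matrix(ecs, self.covariate_columns_, self.medians_)
        envs = list(X_df.index)
        X = X_df.to_numpy(float)
        D = metadata_design(meta, envs, columns=self.design_columns_)
        preds = (
            self.forest_.predict(X)
            + self.ridge_.predict(X)
            + self.ls_.predict(D.to_numpy(float))
        ) / 3.0
        return pd.Series(preds, index=envs, name="composite")

    def predict(self, ecs: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
        """Debiased environment-mean prediction, a + b * composite."""
        comp = self.composite(ecs, meta)
        out = self.debias_intercept_ + self.debias_slope_ * comp
        out.name = "env_mean_hat"
        return out


class EnvSdModel(BaseEstimator, RegressorMixin):
    """Random forest for per-environment SDs with a positivity floor."""

    def __init__(self, n_trees: int = 500, random_state: int = 0,
                 floor_fraction: float = 0.1):
        self.n_trees = n_trees
        self.random_state = random_state
        self.floor_fraction = floor_fraction

    def fit(self, env_sds: pd.Series, ecs: pd.DataFrame):
        env_sds = pd.Series(env_sds).dropna()
        if len(env_sds) < 5:
            raise ValueError(
                f"need at least 5 training environments with SDs, got {len(env_sds)}"
            )
        if (env_sds <= 0).any():
            raise ValueError("environment SDs must be strictly positive")
        X_all, self.medians_ = _covariate_matrix(ecs)
        self.covariate_columns_ = list(X_all.columns)
        X = X_all.reindex(env_sds.index).fillna(self.medians_).to_numpy(float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.random_state
        ).fit(X, env_sds.to_numpy(float))
        self.floor_ = self.floor_fraction * float(env_sds.min())
        return self

    def predict(self, ecs: pd.DataFrame) -> pd.Series:
        X_df, _ = _covariate_matrix(ecs, self.covariate_columns_, self.medians_)
        pred = self.forest_.predict(X_df.to_numpy(float))
        pred = np.clip(pred, self.floor_, None)
        return pd.Series(pred, index=X_df.index, name="sigma_k")


def fit_env_mean_model(env_means, ecs, meta, **kwargs) -> EnvMeanModel:
    return EnvMeanModel(**kwargs).fit(env_means, ecs, meta)


def predict_env_means(model: EnvMeanModel, ecs_new, meta_new) -> pd.Series:
    return model.predict(ecs_new, meta_new)


def fit_env_sd_model(env_sds, ecs, **kwargs) -> EnvSdModel:
    return EnvSdModel(**kwargs).fit(env_sds, ecs)


def predict_env_sd(model: EnvSdModel, ecs_new) -> pd.Series:
    return model.predict(ecs_new)
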