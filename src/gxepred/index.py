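"""Selection-index assembly of environment-specific genetic predictions.

The genetic merit of hybrid j in an untested target environment k is a
weighted combination of its genomic values in the observed environments,

    u_k(j) = sigma_k * zscore_j( sum_i w_{i,k} g_i(j) ),

where the weights w_{i,k} blend a deterministic-accuracy statistic (mean
cross-relatedness of the hybrids of environment i to those of k, scaled
by the within-set relatedness of k) with a geography multiplier (same
station > same state > different state), and sigma_k is the predicted
phenotypic SD of the target. The z-scoring deliberately undoes the
shrinkage of regularized genomic predictions before rescaling them to the
target environment's spread — shrinkage hurts absolute-error metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gblup import MultiEnvGBLUP
from .kernels import GenomicKernel

__all__ = [
    "SelectionIndexResult",
    "pair_accuracy",
    "location_weights",
    "selection_index",
    "model_b_predictions",
    "ensemble_average",
]

DEFAULT_GEO_MULTIPLIERS = {"same_station": 1.0, "same_state": 0.75, "other": 0.5}


@dataclass
class SelectionIndexResult:
    """Weights, predicted SD and genetic merit for target environments."""

    weights: pd.DataFrame  # target env x training env
    sigma: pd.Series       # target env -> sigma_k (Mg/ha)
    merit: pd.DataFrame    # target env x hybrid -> u_k (Mg/ha deviations)


def pair_accuracy(K: GenomicKernel, hybrids_i, hybrids_k) -> float:
    """Deterministic accuracy of environment i's hybrids predicting k's.

    Mean cross-relationship between the two hybrid sets rescaled by the
    mean within-set relationship of the target set k, clipped to [0, 1].
    Identical sets score exactly 1.
    """
    hybrids_i = list(hybrids_i)
    hybrids_k = list(hybrids_k)
    if not hybrids_i or not hybrids_k:
        raise ValueError("both hybrid sets must be non-empty")
    cross = float(K.loc(hybrids_i, hybrids_k).mean())
    within_k = float(K.loc(hybrids_k, hybrids_k).mean())
    if within_k <= 0:
        return 0.0
    return float(np.clip(cross / within_k, 0.0, 1.0))


def _geo_class(meta_row_i, meta_row_k) -> str:
    if meta_row_i["station"] == meta_row_k["station"]:
        return "same_station"
    if meta_row_i["state"] == meta_row_k["state"]:
        return "same_state"
    return "other"


def location_weights(
    accuracies: pd.Series,
    meta: pd.DataFrame,
    target_k: str,
    multipliers: dict | None = None,
) -> pd.Series:
    """Normalized training-environment weights for one target environment.

    raw_i = accuracy_i * geography multiplier; weights are normalized to
    sum to one. If every raw weight is zero the weights fall back to
    uniform with a warning.
    """
    accuracies = pd.Series(accuracies).astype(float)
    if (accuracies < 0).any():
        raise ValueError("accuracies must be non-negative")
    mult = dict(DEFAULT_GEO_MULTIPLIERS)
    if multipliers:
        mult.update(multipliers)
    m = meta.set_index("env_id")
    if target_k not in m.index:
        raise KeyError(f"target environment {target_k!r} missing from metadata")
    row_k = m.loc[target_k]
    raw = np.array(
        [
            accuracies[env] * mult[_geo_class(m.loc[env], row_k)]
            for env in accuracies.index
        ]
    )
    total = raw.sum()
    if total <= 0:
        warnings.warn(
            f"all raw weights are zero for target {target_k}; using uniform weights",
            stacklevel=2,
        )
        raw = np.ones_like(raw)
        total = raw.sum()
    return pd.Series(raw / total, index=accuracies.index, name=target_k)


def selection_index(
    fit: MultiEnvGBLUP,
    weights: pd.Series,
    sigma_k: float,
    hybrids_target,
) -> pd.Series:
    """Genetic merit u_k for the target hybrids (centered, SD = sigma_k).

    The raw index sum_i w_i g_i(hybrid) is z-scored across the target
    hybrids (population SD) and multiplied by sigma_k.
    """
    if sigma_k <= 0:
        raise ValueError("sigma_k must be positive")
    weights = pd.Series(weights).astype(float)
    missing = [e for e in weights.index if e not in fit.g_.index]
    if missing:
        raise KeyError(f"weight environments not in the fitted model: {missing[:5]}")
    hybrids_target = pd.Index(hybrids_target)
    not_covered = hybrids_target.difference(fit.g_.columns)
    if len(not_covered):
        raise KeyError(f"hybrids not covered by the dense fit: {list(not_covered[:5])}")
    G = fit.g_.loc[weights.index, hybrids_target].to_numpy(float)
    raw = weights.to_numpy() @ G
    sd = raw.std()
    if sd <= 1e-12:
        raise ValueError("raw selection index has zero variance; rescaling undefined")
    u = sigma_k * (raw - raw.mean()) / sd
    return pd.Series(u, index=hybrids_target, name="u_k")


def model_b_predictions(
    env_means: pd.Series,
    index: SelectionIndexResult,
    template: pd.DataFrame,
) -> pd.DataFrame:
    """Model B predictions: yhat(k, hybrid) = mhat_k + u_k(hybrid)."""
    env_means = pd.Series(env_means)
    out = template[["env_id", "hybrid"]].reset_index(drop=True)
    values = np.empty(len(out))
    for env, sub in out.groupby("env_id"):
        if env not in env_means.index:
            raise KeyError(f"no environment-mean prediction for {env!r}")
        if env not in index.merit.index:
            raise KeyError(f"no selection index for environment {env!r}")
        merit = index.merit.loc[env]
        aligned = merit.reindex(sub["hybrid"])
        missing = list(aligned.index[aligned.isna()])
        if missing:
            raise KeyError(
                f"template pairs without index coverage in {env}: {missing[:5]}"
            )
        values[sub.index] = env_means[env] + aligned.to_numpy()
    out["yield_mg_ha"] = values
    out.attrs["model"] = "B"
    return out


def ensemble_average(preds: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of prediction sets with identical pair coverage."""
    if not preds:
        raise ValueError("need at least one prediction set")
    base = preds[0][["env_id", "hybrid"]]
    key0 = pd.MultiIndex.from_frame(base)
    total = preds[0]["yield_mg_ha"].to_numpy(float).copy()
    for other in preds[1:]:
        keyed = other.set_index(["env_id", "hybrid"])["yield_mg_ha"]
        if len(other) != len(base) or not key0.isin(keyed.index).all():
            missing = key0[~key0.isin(keyed.index)]
            raise ValueError(
                f"prediction sets do not cover identical pairs; e.g. missing "
                f"{list(missing[:5])}"
            )
        total += keyed.loc[key0].to_numpy(float)
    out = base.copy()
    out["yield_mg_ha"] = total / len(preds)
    out.attrs["model"] = "ensemble"
    return out
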