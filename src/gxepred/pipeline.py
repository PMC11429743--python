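"""Configuration-driven orchestration: simulate -> preprocess -> fit ->
ensemble -> score.

A single master seed fans out to named per-stage seeds through a SHA-256
hash, so each stage is individually reproducible without seed collisions.
The run manifest records the configuration hash, the derived seeds,
package versions and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigurationError, SimConfig
from .env_model import EnvMeanModel, EnvSdModel
from .evaluation import ScoreReport, score
from .gblup import (
    MultiEnvGBLUP,
    UnivariateGBLUP,
    drop_aliased,
    metadata_design,
    predict_model_a,
)
from .index import (
    SelectionIndexResult,
    ensemble_average,
    location_weights,
    model_b_predictions,
    pair_accuracy,
    selection_index,
)
from .io import read_bundle, write_submission
from .kernels import arc_cosine_kernel
from .preprocess import aggregate_metadata, env_summaries, qc_filter, standardize_spatial
from .simulate import Bundle, simulate_bundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]

_TOP_LEVEL_KEYS = {
    "seed", "model", "bundle_dir", "sim", "output_dir",
    "qc", "gblup", "env_model", "index",
}
_MODELS = ("A", "B", "ensemble")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    model: str = "ensemble"
    bundle_dir: str | None = None
    sim: dict = field(default_factory=dict)
    output_dir: str | None = None
    qc: dict = field(default_factory=dict)
    gblup: dict = field(default_factory=dict)
    env_model: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigurationError(f"model must be one of {_MODELS}, got {self.model!r}")
        for name in ("sim", "qc", "gblup", "env_model", "index"):
            if not isinstance(getattr(self, name), dict):
                raise ConfigurationError(f"config section '{name}' must be a mapping")
        if self.bundle_dir is None:
            SimConfig(**{**self.sim, "seed": 0})  # validate sim keys eagerly

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_LEVEL_KEYS
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "model": self.model, "bundle_dir": self.bundle_dir,
            "sim": self.sim, "output_dir": self.output_dir, "qc": self.qc,
            "gblup": self.gblup, "env_model": self.env_model, "index": self.index,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    predictions: dict            # model tag -> prediction DataFrame
    scores: dict                 # model tag -> ScoreReport (when truth known)
    manifest: dict
    bundle: Bundle


def _truth_pairs(test_trait: pd.DataFrame) -> pd.DataFrame:
    """Observed test-year pair means, the scoring target."""
    truth = (
        test_trait.groupby(["env_id", "hybrid"], as_index=False)["yield_mg_ha"].mean()
    )
    return truth


def _fit_model_a(cfg, bundle, train_qc, meta_agg, kernel):
    pair = (
        train_qc.groupby(["env_id", "hybrid"], as_index=False)["yield_mg_ha"].mean()
    )
    X = drop_aliased(metadata_design(meta_agg, pair["env_id"]))
    fit = UnivariateGBLUP(
        kernel=kernel, ridge_eps=cfg.gblup.get("ridge_eps", 1e-8)
    ).fit(X, pair["yield_mg_ha"].to_numpy(), hybrids=pair["hybrid"])
    preds = predict_model_a(fit, meta_agg, bundle.template, kernel)
    return fit, preds


def _fit_model_b(cfg, bundle, train_qc, meta_agg, kernel):
    stats = env_summaries(train_qc)
    train_envs = list(stats.index)
    test_envs = sorted(bundle.template["env_id"].unique())

    ec = bundle.ec
    ec_train = ec[ec["env_id"].isin(train_envs)]
    ec_test = ec[ec["env_id"].isin(test_envs)]
    missing_ec = set(test_envs) - set(ec_test["env_id"])
    if missing_ec:
        raise KeyError(f"test environments missing covariates: {sorted(missing_ec)[:5]}")

    em_seed = stage_seed(cfg.seed, "env_mean_model")
    mean_model = EnvMeanModel(
        n_trees=cfg.env_model.get("n_trees", 500), random_state=em_seed
    ).fit(stats["mean"], ec_train, meta_agg)
    m_hat = mean_model.predict(ec_test, meta_agg)

    std = standardize_spatial(train_qc)
    mv = MultiEnvGBLUP(
        kernel=kernel,
        max_iter=cfg.gblup.get("max_iter", 200),
        tol=cfg.gblup.get("tol", 1e-5),
        min_hybrids_per_env=cfg.gblup.get("min_hybrids_per_env", 10),
    ).fit(std.records)

    # sigma_k: the dispersion a genetic deviation should have. The default
    # "genetic" target trains the forest on sqrt(diag Sigma_g) mapped back
    # to Mg/ha through each environment's standardization scale; the
    # "phenotypic" option trains on the plot-yield SDs directly.
    sd_target = cfg.env_model.get("sd_target", "genetic")
    if sd_target == "genetic":
        scale = std.env_stats["sd"]
        gen_var = pd.Series(np.diag(mv.Sigma_g_), index=mv.environments_)
        target_sd = (np.sqrt(gen_var.clip(lower=1e-6)) * scale.reindex(mv.environments_)).dropna()
    elif sd_target == "phenotypic":
        target_sd = stats["sd"].dropna()
    else:
        raise ConfigurationError(f"unknown sd_target {sd_target!r}")
    sd_model = EnvSdModel(
        n_trees=cfg.env_model.get("n_trees", 500),
        random_state=stage_seed(cfg.seed, "env_sd_model"),
    ).fit(target_sd, ec_train)
    sigma_hat = sd_model.predict(ec_test)

    train_sets = {
        env: sorted(sub["hybrid"].unique())
        for env, sub in train_qc.groupby("env_id")
        if env in mv.environments_
    }
    target_sets = {
        env: sorted(sub["hybrid"].unique())
        for env, sub in bundle.template.groupby("env_id")
    }
    multipliers = cfg.index.get("multipliers")
    weights_rows, merit_rows = {}, {}
    for env_k in test_envs:
        acc = pd.Series(
            {
                env_i: pair_accuracy(kernel, train_sets[env_i], target_sets[env_k])
                for env_i in train_sets
            }
        )
        w = location_weights(acc, bundle.meta, env_k, multipliers=multipliers)
        u = selection_index(mv, w, float(sigma_hat[env_k]), target_sets[env_k])
        weights_rows[env_k] = w
        merit_rows[env_k] = u
    result = SelectionIndexResult(
        weights=pd.DataFrame(weights_rows).T,
        sigma=sigma_hat,
        merit=pd.DataFrame(merit_rows).T,
    )
    preds = model_b_predictions(m_hat, result, bundle.template)
    parts = {"mean_model": mean_model, "sd_model": sd_model, "mv": mv, "index": result}
    return parts, preds, m_hat


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured workflow and (when truth is available) score it.

    Alongside the requested model(s), an environment-mean-only baseline
    (every hybrid predicted at the environment's predicted mean) is always
    produced for reference.
    """
    cfg = config
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "version": __version__,
        "seeds": {s: stage_seed(cfg.seed, s) for s in
                  ("simulate", "env_mean_model", "env_sd_model")},
        "stages": {},
    }

    if cfg.bundle_dir:
        bundle = read_bundle(cfg.bundle_dir)
    else:
        sim_cfg = SimConfig(**{**cfg.sim, "seed": stage_seed(cfg.seed, "simulate")})
        bundle = simulate_bundle(sim_cfg)
    train, test = bundle.split()
    manifest["stages"]["input"] = {
        "n_train_plots": int(len(train)),
        "n_test_plots": int(len(test)),
        "n_hybrids": int(bundle.geno.shape[0]),
        "n_markers": int(bundle.geno.shape[1]),
        "n_template_pairs": int(len(bundle.template)),
    }

    train_qc, qc_counts = qc_filter(
        train,
        sd_threshold=cfg.qc.get("sd_threshold", 3.0),
        min_stand=cfg.qc.get("min_stand", 20),
        drop_disease=cfg.qc.get("drop_disease", True),
    )
    # per-environment removal counts (rules act within environments, so
    # per-environment application reproduces the global filter)
    qc_by_env = {}
    for env, sub in train.groupby("env_id"):
        _, env_counts = qc_filter(
            sub,
            sd_threshold=cfg.qc.get("sd_threshold", 3.0),
            min_stand=cfg.qc.get("min_stand", 20),
            drop_disease=cfg.qc.get("drop_disease", True),
        )
        qc_by_env[env] = env_counts
    qc_report = {"total": qc_counts, "per_environment": qc_by_env}
    manifest["stages"]["qc"] = {"removed": qc_counts, "n_kept": int(len(train_qc))}
    meta_agg = aggregate_metadata(bundle.meta)

    kernel = arc_cosine_kernel(bundle.geno)
    manifest["stages"]["kernel"] = {"kind": kernel.kind, "n_hybrids": kernel.n_hybrids}

    predictions: dict[str, pd.DataFrame] = {}
    stats = env_summaries(train_qc)

    if cfg.model in ("A", "ensemble"):
        fit_a, pred_a = _fit_model_a(cfg, bundle, train_qc, meta_agg, kernel)
        predictions["A"] = pred_a
        manifest["stages"]["model_a"] = {
            "vg": fit_a.vg_, "ve": fit_a.ve_, "h2": fit_a.h2_,
            "n_fixed_effects": len(fit_a.beta_),
        }
    m_hat_for_baseline = None
    if cfg.model in ("B", "ensemble"):
        parts_b, pred_b, m_hat = _fit_model_b(cfg, bundle, train_qc, meta_agg, kernel)
        predictions["B"] = pred_b
        m_hat_for_baseline = m_hat
        manifest["stages"]["model_b"] = {
            "em_iterations": int(parts_b["mv"].n_iter_),
            "em_converged": bool(parts_b["mv"].converged_),
            "submodel_r2": parts_b["mean_model"].submodel_r2_,
            "debias": [parts_b["mean_model"].debias_intercept_,
                       parts_b["mean_model"].debias_slope_],
        }
    if cfg.model == "ensemble":
        predictions["ensemble"] = ensemble_average([predictions["A"], predictions["B"]])

    # environment-mean-only reference predictor
    if m_hat_for_baseline is None:
        grand = float(stats["mean"].mean())
        baseline_means = pd.Series(grand, index=sorted(bundle.template["env_id"].unique()))
        ec = bundle.ec
        try:
            mean_model = EnvMeanModel(
                n_trees=cfg.env_model.get("n_trees", 500),
                random_state=stage_seed(cfg.seed, "env_mean_model"),
            ).fit(stats["mean"], ec[ec["env_id"].isin(stats.index)], meta_agg)
            baseline_means = mean_model.predict(
                ec[ec["env_id"].isin(bundle.template["env_id"].unique())], meta_agg
            )
        except Exception as exc:  # fall back to the grand mean
            logger.warning("baseline environment-mean model failed (%s); using grand mean", exc)
        m_hat_for_baseline = baseline_means
    baseline = bundle.template[["env_id", "hybrid"]].copy()
    baseline["yield_mg_ha"] = m_hat_for_baseline.reindex(baseline["env_id"]).to_numpy()
    baseline.attrs["model"] = "env_mean_baseline"
    predictions["env_mean_baseline"] = baseline

    scores: dict[str, ScoreReport] = {}
    if test["yield_mg_ha"].notna().any():
        truth = _truth_pairs(test)
        for tag, pred in predictions.items():
            scores[tag] = score(pred, truth)
        manifest["stages"]["score"] = {
            tag: {"avg_rmse": rep.avg_rmse, "avg_pearson": rep.avg_pearson}
            for tag, rep in scores.items()
        }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        final_tag = cfg.model if cfg.model in predictions else "ensemble"
        write_submission(predictions[final_tag], out / "submission.csv", bundle.template)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        if scores:
            payload = {
                tag: {"avg_rmse": rep.avg_rmse, "avg_pearson": rep.avg_pearson,
                      "global_rmse": rep.global_rmse, "global_pearson": rep.global_pearson}
                for tag, rep in scores.items()
            }
            (out / "scores.json").write_text(json.dumps(payload, indent=2, default=float))

    return PipelineResult(predictions=predictions, scores=scores, manifest=manifest, bundle=bundle)
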