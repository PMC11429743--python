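"""Competition-style scoring, leaderboards and survey-table statistics.

The headline metric is the averaged RMSE: root-mean-square error computed
within each environment, then averaged across environments with equal
weight. Alternative metrics (within-environment Pearson r averaged the
same way, plus global RMSE and global Pearson r pooling all pairs) are
reported alongside, since rankings can shift considerably between
absolute-error and correlation metrics.

Transcribed leaderboard and survey fixtures from the competition report
ship with the package and are exposed through ``load_fixture``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreReport",
    "score",
    "build_leaderboard",
    "top_n_spread",
    "usage_percentages",
    "rank_submission_correlation",
    "load_fixture",
]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a shipped fixture table: 'leaderboard', 'strategies' or 'factors'."""
    files = {"leaderboard": "table2.csv", "strategies": "table3.csv", "factors": "table4.csv"}
    if name not in files:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(files)}")
    with resources.files("gxepred.data").joinpath(files[name]).open() as fh:
        return pd.read_csv(fh)


@dataclass
class ScoreReport:
    """Per-environment and aggregate accuracy of one prediction set."""

    per_env: pd.DataFrame      # env_id -> rmse, pearson_r, n
    avg_rmse: float
    avg_pearson: float         # NaN when undefined in every environment
    global_rmse: float
    global_pearson: float
    n_ignored: int = 0         # predicted pairs absent from the truth


def score(pred: pd.DataFrame, truth: pd.DataFrame) -> ScoreReport:
    """Score predictions against observed values, environment by environment.

    Pairs missing from the truth are ignored (counted); environments with
    zero variance or fewer than two pairs have an undefined Pearson r and
    are excluded from the Pearson average while still contributing RMSE.
    """
    for df, name in ((pred, "predictions"), (truth, "truth")):
        for col in ("env_id", "hybrid", "yield_mg_ha"):
            if col not in df.columns:
                raise ValueError(f"{name} table is missing the '{col}' column")
    t = truth.set_index(["env_id", "hybrid"])["yield_mg_ha"]
    if t.index.has_duplicates:
        t = t.groupby(level=[0, 1]).mean()
    merged = pred[["env_id", "hybrid", "yield_mg_ha"]].copy()
    key = pd.MultiIndex.from_frame(merged[["env_id", "hybrid"]])
    merged["observed"] = t.reindex(key).to_numpy()
    n_ignored = int(merged["observed"].isna().sum())
    merged = merged.dropna(subset=["observed"])
    if merged.empty:
        raise ValueError("no scoreable (environment, hybrid) pairs")

    rows = []
    for env, sub in merged.groupby("env_id", sort=True):
        err = sub["yield_mg_ha"].to_numpy(float) - sub["observed"].to_numpy(float)
        rmse = float(np.sqrt(np.mean(err**2)))
        if len(sub) >= 2 and sub["yield_mg_ha"].std() > 0 and sub["observed"].std() > 0:
            r = float(np.corrcoef(sub["yield_mg_ha"], sub["observed"])[0, 1])
        else:
            r = np.nan
            logger.info("Pearson r undefined in environment %s", env)
        rows.append((env, rmse, r, len(sub)))
    per_env = pd.DataFrame(rows, columns=["env_id", "rmse", "pearson_r", "n"]).set_index("env_id")

    err_all = merged["yield_mg_ha"].to_numpy(float) - merged["observed"].to_numpy(float)
    if merged["yield_mg_ha"].std() > 0 and merged["observed"].std() > 0:
        global_r = float(np.corrcoef(merged["yield_mg_ha"], merged["observed"])[0, 1])
    else:
        global_r = np.nan
    return ScoreReport(
        per_env=per_env,
        avg_rmse=float(per_env["rmse"].mean()),
        avg_pearson=float(per_env["pearson_r"].mean()) if per_env["pearson_r"].notna().any() else float("nan"),
        global_rmse=float(np.sqrt(np.mean(err_all**2))),
        global_pearson=global_r,
        n_ignored=n_ignored,
    )


_METRICS = (
    ("avg_rmse", True),
    ("avg_pearson", False),
    ("global_rmse", True),
    ("global_pearson", False),
)


def build_leaderboard(submissions: dict, truth: pd.DataFrame) -> pd.DataFrame:
    """Score every submission and rank it under each metric.

    Ranks are 1..n within each metric (lower RMSE better, higher r
    better); ties are broken by team label and flagged in ``*_tied``;
    undefined scores are left unranked. ``rank_differs`` marks teams whose
    rank under any alternative metric departs from the headline
    averaged-RMSE rank.
    """
    if not submissions:
        raise ValueError("need at least one submission")
    rows = {}
    for team, pred in submissions.items():
        rep = score(pred, truth)
        rows[team] = {
            "avg_rmse": rep.avg_rmse,
            "avg_pearson": rep.avg_pearson,
            "global_rmse": rep.global_rmse,
            "global_pearson": rep.global_pearson,
        }
    lb = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    for metric, lower_better in _METRICS:
        values = lb[metric]
        order = values.sort_values(ascending=lower_better, kind="mergesort")
        order = order[order.notna()]
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
        lb[f"{metric}_rank"] = ranks.reindex(lb.index)
        lb[f"{metric}_tied"] = values.map(values.value_counts()).gt(1) & values.notna()
    alt = [m for m, _ in _METRICS[1:]]
    diffs = pd.concat(
        [(lb[f"{m}_rank"] != lb["avg_rmse_rank"]) & lb[f"{m}_rank"].notna() for m in alt],
        axis=1,
    )
    lb["rank_differs"] = diffs.any(axis=1)
    lb = lb.sort_values("avg_rmse_rank")
    lb.index.name = "team"
    return lb


def top_n_spread(leaderboard: pd.DataFrame, n: int) -> float:
    """Spread of averaged RMSE between the best and the n-th best team."""
    scores = leaderboard["avg_rmse"].dropna().sort_values()
    if n < 1 or n > len(scores):
        raise ValueError(f"n={n} outside 1..{len(scores)}")
    return float(scores.iloc[n - 1] - scores.iloc[0])


def usage_percentages(table: pd.DataFrame) -> pd.Series:
    """Percent of teams using each strategy/factor, rounded half-up."""
    if len(table) == 0:
        raise ValueError("table has no rows")
    flags = table.select_dtypes(include=["number", "bool"]).drop(
        columns=[c for c in ("rank",) if c in table.columns]
    )
    frac = flags.astype(bool).mean(axis=0) * 100.0
    return np.floor(frac + 0.5).astype(int)


def rank_submission_correlation(ranks, submission_counts) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) between final rank and
    submission count, with a two-sided t-approximation p-value."""
    ranks = np.asarray(ranks, dtype=float)
    counts = np.asarray(submission_counts, dtype=float)
    if ranks.shape != counts.shape or ranks.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = ranks.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(ranks == ranks[0]) or np.all(counts == counts[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, pvalue = stats.spearmanr(ranks, counts)
    return float(rho), float(pvalue)
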