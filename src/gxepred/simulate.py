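"""Synthetic multi-environment maize trial generator with known ground truth.

Every downstream stage of the pipeline (QC, kernels, GBLUP, environment
means, selection index, scoring) has a parameter-recovery test against the
truth objects produced here. The generative model is

    y_plot = m_e + b_rep + g_{e,i} + eps,   eps ~ N(0, sigma_e^2(e))

with environment means ``m_e`` a linear function of numeric covariates plus
location and year effects, genetic values ``g`` drawn from a matrix normal
with between-environment covariance ``Sigma_g`` and between-hybrid
covariance ``K`` (the additive genomic relationship matrix of the simulated
markers), and residual variances set per environment from the plot-level
heritability. Artifacts (outliers, low stand counts, disease trials) are
injected at configurable rates and flagged in the truth bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .kernels import additive_grm

__all__ = [
    "TruthBundle",
    "Bundle",
    "simulate_marker_matrix",
    "simulate_trials",
    "simulate_bundle",
]


@dataclass
class TruthBundle:
    """Ground truth underlying a simulated bundle."""

    env_means: pd.Series          # environment -> true mean, Mg/ha
    env_sd: pd.Series             # environment -> true phenotypic SD, Mg/ha
    genetic_sd: pd.Series         # environment -> true genetic SD, Mg/ha
    genetic_values: pd.DataFrame  # environment x hybrid, Mg/ha deviations
    Sigma_g: pd.DataFrame         # environment x environment genetic covariance
    outlier_flags: pd.Series      # plot-level, aligned with the trait table
    low_stand_flags: pd.Series    # plot-level, aligned with the trait table
    disease_envs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        S = self.Sigma_g.to_numpy()
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("true Sigma_g must be symmetric")
        w = np.linalg.eigvalsh(S)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("true Sigma_g must be positive semidefinite")


@dataclass
class Bundle:
    """A competition-shaped data bundle (tables keyed as in the file roster)."""

    trait: pd.DataFrame
    meta: pd.DataFrame
    ec: pd.DataFrame
    geno: pd.DataFrame
    template: pd.DataFrame
    truth: TruthBundle | None = None
    config: SimConfig | None = None

    @property
    def train_years(self) -> list:
        years = sorted(self.trait["year"].unique())
        return years[:-1]

    @property
    def test_year(self):
        return sorted(self.trait["year"].unique())[-1]

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Training trait rows (all years but the last) and test-year rows."""
        test = self.trait["year"] == self.test_year
        return self.trait.loc[~test].copy(), self.trait.loc[test].copy()


def _hybrid_labels(n: int) -> list[str]:
    return [f"H{i + 1:04d}" for i in range(n)]


def _marker_labels(n: int) -> list[str]:
    return [f"M{j + 1:05d}" for j in range(n)]


def simulate_marker_matrix(
    config: SimConfig, allele_freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Draw a hybrid x variant dosage matrix with all markers polymorphic.

    Allele frequencies are Uniform(0.1, 0.9) unless supplied; dosages are
    Binomial(2, p). Columns that come out monomorphic in a finite sample
    are redrawn so every marker stays informative.
    """
    if config.n_hybrids < 2:
        raise ConfigurationError("n_hybrids must be >= 2 to simulate markers")
    rng = np.random.default_rng(config.seed)
    if allele_freqs is None:
        p = rng.uniform(0.1, 0.9, size=config.n_markers)
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (config.n_markers,):
            raise ConfigurationError(
                f"allele_freqs must have length n_markers={config.n_markers}"
            )
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ConfigurationError(
                "allele frequencies must lie strictly inside (0, 1); "
                "monomorphic markers are not allowed"
            )
    M = rng.binomial(2, p, size=(config.n_hybrids, config.n_markers)).astype(np.int64)
    # redraw sample-monomorphic columns (possible at extreme p and small n)
    for _ in range(100):
        mono = (M.min(axis=0) == M.max(axis=0))
        if not mono.any():
            break
        M[:, mono] = rng.binomial(2, p[mono], size=(config.n_hybrids, mono.sum()))
    else:
        raise ConfigurationError("could not draw polymorphic markers; check allele_freqs")
    out = pd.DataFrame(
        M, index=_hybrid_labels(config.n_hybrids), columns=_marker_labels(config.n_markers)
    )
    out.index.name = "hybrid"
    return out


def _env_correlation(config: SimConfig, states: np.ndarray) -> np.ndarray:
    """Block-structured environment genetic correlation, projected to PSD."""
    same_state = states[:, None] == states[None, :]
    C = np.where(same_state, config.rho_gxe_within_state, config.rho_gxe_between_state)
    np.fill_diagonal(C, 1.0)
    w, U = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    C = (U * w) @ U.T
    d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _matrix_normal(rng, Sigma_rows: np.ndarray, K_cols: np.ndarray) -> np.ndarray:
    """Sample E x H matrix with cov(vec) = Sigma_rows (x) K_cols (both PSD)."""
    wr, Ur = np.linalg.eigh(Sigma_rows)
    Lr = Ur * np.sqrt(np.clip(wr, 0.0, None))
    wc, Uc = np.linalg.eigh(K_cols)
    Lc = Uc * np.sqrt(np.clip(wc, 0.0, None))
    Z = rng.standard_normal((Sigma_rows.shape[0], K_cols.shape[0]))
    return Lr @ Z @ Lc.T


def simulate_trials(
    config: SimConfig, markers: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Simulate plot-level trials, metadata and covariates for one bundle.

    Returns ``(trait, meta, ec, truth)``. The trait table carries a
    ``treatment`` column (joined from the metadata) so QC can run on it
    directly. Environments are (location, year) pairs; each samples
    ``frac_hybrids_per_env`` of the hybrid population with climate-adapted
    hybrids oversampled, so environments in the same state share more
    hybrids than environments in different states.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    H = config.n_hybrids
    hybrids = list(markers.index)
    if len(hybrids) != H:
        raise ConfigurationError("marker matrix does not match n_hybrids")

    n_per_env = int(round(config.frac_hybrids_per_env * H))
    if n_per_env < 2:
        raise ConfigurationError(
            "frac_hybrids_per_env * n_hybrids must be >= 2 "
            f"(got {n_per_env})"
        )

    years = [2018 + t for t in range(config.n_years)]
    loc_states = np.arange(config.n_locations) % config.n_states
    locations = [
        f"{chr(ord('A') + s)}{'H'}{np.sum(loc_states[: l + 1] == loc_states[l])}"
        for l, s in enumerate(loc_states)
    ]
    env_ids, env_loc, env_year, env_state = [], [], [], []
    for y in years:
        for l, loc in enumerate(locations):
            env_ids.append(f"{loc}_{y}")
            env_loc.append(loc)
            env_year.append(y)
            env_state.append(loc_states[l])
    E = len(env_ids)
    env_state = np.asarray(env_state)

    # --- management: treatments, irrigation, disease trials -----------------
    disease = rng.random(E) < config.disease_trial_rate
    treatments = []
    for e in range(E):
        if disease[e]:
            treatments.append("disease trial")
        else:
            treatments.append(
                str(rng.choice(
                    ["Standard", "Standard", "Standard", "Drought stress", "Late planting"]
                ))
            )
    irrigation_prone = rng.random(config.n_locations) < 0.4
    irrigated = np.array(
        [
            rng.random() < (0.7 if irrigation_prone[locations.index(env_loc[e])] else 0.05)
            for e in range(E)
        ]
    )
    treatment_effect = {
        "Standard": 0.0,
        "Drought stress": -1.2,
        "Late planting": -0.6,
        "disease trial": -1.0,
    }

    # --- environment means: covariates + location + year + management ------
    n_cov = config.n_covariates
    loc_base = rng.standard_normal((config.n_locations, n_cov))
    W = np.empty((E, n_cov))
    for e in range(E):
        l = locations.index(env_loc[e])
        W[e] = 0.7 * loc_base[l] + 0.7 * rng.standard_normal(n_cov)
    v = config.var_env_mean
    n_active = min(3, n_cov)
    beta = np.zeros(n_cov)
    beta[:n_active] = np.sqrt(0.5 * v / n_active) * rng.choice([-1.0, 1.0], n_active)
    loc_eff = rng.normal(0.0, np.sqrt(0.25 * v), size=config.n_locations)
    year_eff = rng.normal(0.0, np.sqrt(0.25 * v), size=config.n_years)
    m = np.array(
        [
            config.mean_yield
            + W[e] @ beta
            + loc_eff[locations.index(env_loc[e])]
            + year_eff[years.index(env_year[e])]
            + treatment_effect[treatments[e]]
            + 0.8 * irrigated[e]
            for e in range(E)
        ]
    )

    # --- genetic values: Sigma_g (x) K -------------------------------------
    lo, hi = config.env_sd_range
    sigma_p = rng.uniform(lo, hi, size=E)
    sigma_g = np.sqrt(config.h2_within_env) * sigma_p
    sigma_e = np.sqrt(1.0 - config.h2_within_env) * sigma_p
    C = _env_correlation(config, env_state)
    Sigma_g = C * np.outer(sigma_g, sigma_g)
    K = additive_grm(markers).values
    G = _matrix_normal(rng, Sigma_g, K)  # E x H

    # --- stratified incidence ----------------------------------------------
    hybrid_state = rng.integers(0, config.n_states, size=H)
    incidence: dict[str, np.ndarray] = {}
    for e, env in enumerate(env_ids):
        adapted = hybrid_state == env_state[e]
        weights = np.where(adapted, 3.0, 1.0)
        weights = weights / weights.sum()
        incidence[env] = np.sort(rng.choice(H, size=n_per_env, replace=False, p=weights))

    # --- plot records -------------------------------------------------------
    rows = []
    rep_labels = list(range(1, config.n_replicates + 1))
    for e, env in enumerate(env_ids):
        block_eff = rng.normal(0.0, 0.15, size=config.n_replicates)
        for rep_i, rep in enumerate(rep_labels):
            idx = incidence[env]
            eps = rng.normal(0.0, sigma_e[e], size=len(idx))
            y = m[e] + block_eff[rep_i] + G[e, idx] + eps
            for j, i in enumerate(idx):
                rows.append(
                    (
                        env,
                        env_year[e],
                        env_loc[e],
                        hybrids[i],
                        y[j],
                        rep,
                        rep,
                        treatments[e],
                    )
                )
    trait = pd.DataFrame(
        rows,
        columns=[
            "env_id",
            "year",
            "location_code",
            "hybrid",
            "yield_mg_ha",
            "replicate",
            "block",
            "treatment",
        ],
    )
    n_plots = len(trait)

    # --- artifacts ----------------------------------------------------------
    sigma_p_by_row = trait["env_id"].map(dict(zip(env_ids, sigma_p))).to_numpy()
    outlier = rng.random(n_plots) < config.outlier_rate
    signs = rng.choice([-1.0, 1.0], size=n_plots)
    trait["yield_mg_ha"] = trait["yield_mg_ha"].to_numpy() + np.where(
        outlier, signs * 6.0 * sigma_p_by_row, 0.0
    )
    low_stand = rng.random(n_plots) < config.low_stand_rate
    stand = rng.integers(55, 76, size=n_plots)
    stand[low_stand] = rng.integers(5, 20, size=int(low_stand.sum()))
    trait["stand_count"] = stand
    trait["discarded_flag"] = False
    trait["yield_mg_ha"] = trait["yield_mg_ha"].clip(lower=0.0)
    trait = trait[
        [
            "env_id",
            "year",
            "location_code",
            "hybrid",
            "yield_mg_ha",
            "stand_count",
            "replicate",
            "block",
            "discarded_flag",
            "treatment",
        ]
    ]

    # --- metadata and covariates -------------------------------------------
    prev_crops = ["Soybean", "Wheat", "Maize", "Peas", "Canola", "Fallow"]
    state_names = [f"S{chr(ord('A') + s)}" for s in range(config.n_states)]
    meta_rows = []
    for e, env in enumerate(env_ids):
        l = locations.index(env_loc[e])
        meta_rows.append(
            (
                env,
                state_names[env_state[e]],
                env_loc[e],
                round(34.0 + 1.7 * env_state[e] + 0.13 * l, 4),
                round(-98.0 + 2.3 * env_state[e] + 0.21 * l, 4),
                "yes" if irrigated[e] else "no",
                treatments[e],
                rng.choice(prev_crops),
            )
        )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "env_id",
            "state",
            "station",
            "latitude",
            "longitude",
            "irrigated",
            "treatment",
            "previous_crop",
        ],
    )
    ec = pd.DataFrame(W, columns=[f"ec{j + 1:02d}" for j in range(n_cov)])
    ec.insert(0, "env_id", env_ids)

    genetic_values = pd.DataFrame(G, index=env_ids, columns=hybrids)
    genetic_values.index.name = "env_id"
    Sigma_g_df = pd.DataFrame(Sigma_g, index=env_ids, columns=env_ids)
    Sigma_g_df.index.name = "env_id"
    truth = TruthBundle(
        env_means=pd.Series(m, index=env_ids, name="true_env_mean"),
        env_sd=pd.Series(sigma_p, index=env_ids, name="true_env_sd"),
        genetic_sd=pd.Series(sigma_g, index=env_ids, name="true_genetic_sd"),
        genetic_values=genetic_values,
        Sigma_g=Sigma_g_df,
        outlier_flags=pd.Series(outlier, index=trait.index, name="is_outlier"),
        low_stand_flags=pd.Series(low_stand, index=trait.index, name="is_low_stand"),
        disease_envs=[env_ids[e] for e in range(E) if disease[e]],
    )
    return trait, meta, ec, truth


def simulate_bundle(config: SimConfig) -> Bundle:
    """Simulate a full bundle; the last simulated year is the test set.

    The submission template lists the (environment, hybrid) pairs planted
    in the test year, with an empty yield column.
    """
    markers = simulate_marker_matrix(config)
    trait, meta, ec, truth = simulate_trials(config, markers)
    test_year = sorted(trait["year"].unique())[-1]
    test = trait[trait["year"] == test_year]
    template = (
        test[["env_id", "hybrid"]]
        .drop_duplicates()
        .sort_values(["env_id", "hybrid"])
        .reset_index(drop=True)
    )
    template["yield_mg_ha"] = np.nan
    return Bundle(
        trait=trait, meta=meta, ec=ec, geno=markers, template=template,
        truth=truth, config=config,
    )
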