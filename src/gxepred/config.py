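"""Configuration objects for the synthetic multi-environment-trial generator.

The generator emulates the shape of a public maize yield-trial bundle:
plot-level yields for hybrids grown in year-by-location environments, an
unbalanced, climate-stratified hybrid incidence, environment means driven
partly by numeric covariates, additive marker genetics with
environment-specific variances and between-environment genetic
correlations, heteroscedastic residuals, and the quality-control artifacts
(outliers, low stand counts, disease trials) that downstream filters are
designed to catch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of a synthetic trial bundle.

    Parameters
    ----------
    n_hybrids, n_markers, n_locations, n_years, n_states
        Dimensions of the simulated population and trial network. Each
        (location, year) pair is one environment.
    h2_within_env
        Plot-level heritability within an environment, in [0, 1]; splits
        the phenotypic variance of each environment into genetic and
        residual parts (0 means pure noise, useful for null checks).
    env_sd_range
        (low, high) of the Uniform draw for true per-environment
        phenotypic SDs, Mg/ha. A degenerate range gives equal variances.
    var_env_mean
        Variance of true environment means, (Mg/ha)^2. Split between a
        covariate-driven component, a persistent location effect and a
        year effect.
    rho_gxe_within_state, rho_gxe_between_state
        Genetic correlations between environments in the same / different
        simulated states ("mega-environment" structure).
    frac_hybrids_per_env
        Fraction of the hybrid population grown in each environment.
    outlier_rate, low_stand_rate, disease_trial_rate
        Rates of injected artifacts: plots shifted by +/-6 SD, plots with
        stand counts drawn from {5..19}, and environments whose treatment
        is tagged as a disease trial.
    n_covariates
        Number of numeric environmental covariates written to ``ec.csv``.
    mean_yield
        Grand mean yield in Mg/ha (15.5% moisture scale).
    n_replicates
        Replicates per hybrid-environment combination.
    seed
        Master seed for the generator.
    """

    n_hybrids: int = 200
    n_markers: int = 400
    n_locations: int = 10
    n_years: int = 3
    n_states: int = 4
    h2_within_env: float = 0.5
    var_env_mean: float = 2.0
    rho_gxe_within_state: float = 0.75
    rho_gxe_between_state: float = 0.45
    env_sd_range: tuple = (1.2, 2.2)
    frac_hybrids_per_env: float = 0.5
    outlier_rate: float = 0.01
    low_stand_rate: float = 0.02
    disease_trial_rate: float = 0.05
    n_covariates: int = 6
    mean_yield: float = 9.5
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hybrids", "n_markers", "n_locations", "n_years", "n_states"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
            setattr(self, name, int(value))
        if self.n_states > self.n_locations:
            raise ConfigurationError("n_states cannot exceed n_locations")
        if not 0.0 <= self.h2_within_env <= 1.0:
            raise ConfigurationError("h2_within_env must lie in [0, 1]")
        lo, hi = self.env_sd_range
        if not (0.0 < lo <= hi):
            raise ConfigurationError("env_sd_range must satisfy 0 < low <= high")
        self.env_sd_range = (float(lo), float(hi))
        if self.var_env_mean < 0:
            raise ConfigurationError("var_env_mean must be non-negative")
        for name in (
            "frac_hybrids_per_env",
            "outlier_rate",
            "low_stand_rate",
            "disease_trial_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("rho_gxe_within_state", "rho_gxe_between_state"):
            value = getattr(self, name)
            if not -1.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [-1, 1], got {value!r}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_covariates < 1:
            raise ConfigurationError("n_covariates must be >= 1")

    @property
    def n_environments(self) -> int:
        return self.n_locations * self.n_years

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
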