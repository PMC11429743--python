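"""Reading and writing competition-shaped data bundles.

A bundle directory holds delimited text files (CSV, UTF-8, header row):

- ``trait.csv``: env_id, year, location_code, hybrid, yield_mg_ha,
  stand_count, replicate, block, discarded_flag
- ``meta.csv``: env_id, state, station, latitude, longitude, irrigated,
  treatment, previous_crop
- ``ec.csv``: env_id plus numeric covariate columns
- ``geno.csv``: hybrid plus one column per variant, dosages 0/1/2
- ``template.csv``: env_id, hybrid, yield_mg_ha (empty)

Simulated bundles additionally carry their ground truth as
``truth_env.csv``, ``truth_genetic.csv``, ``truth_sigma_g.csv`` and
``truth_flags.csv``; these are read back if present. Optional VCF import
maps GT genotypes to dosages; multiallelic records are rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FormatError
from .simulate import Bundle, TruthBundle

__all__ = ["write_bundle", "read_bundle", "write_submission", "read_vcf_dosage"]

TRAIT_COLUMNS = [
    "env_id",
    "year",
    "location_code",
    "hybrid",
    "yield_mg_ha",
    "stand_count",
    "replicate",
    "block",
    "discarded_flag",
]
META_COLUMNS = [
    "env_id",
    "state",
    "station",
    "latitude",
    "longitude",
    "irrigated",
    "treatment",
    "previous_crop",
]
TEMPLATE_COLUMNS = ["env_id", "hybrid", "yield_mg_ha"]


def _check(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} is missing mandatory column(s): {missing}")


def write_bundle(bundle: Bundle, directory) -> list[Path]:
    """Write a bundle to ``directory``; returns the files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    trait = bundle.trait[TRAIT_COLUMNS]
    for name, df in [
        ("trait.csv", trait),
        ("meta.csv", bundle.meta[META_COLUMNS]),
        ("ec.csv", bundle.ec),
        ("template.csv", bundle.template[TEMPLATE_COLUMNS]),
    ]:
        path = directory / name
        df.to_csv(path, index=False)
        written.append(path)
    path = directory / "geno.csv"
    bundle.geno.to_csv(path, index_label="hybrid")
    written.append(path)

    if bundle.truth is not None:
        t = bundle.truth
        env = pd.DataFrame(
            {
                "env_id": t.env_means.index,
                "true_env_mean": t.env_means.to_numpy(),
                "true_env_sd": t.env_sd.to_numpy(),
                "true_genetic_sd": t.genetic_sd.to_numpy(),
                "is_disease_trial": [e in set(t.disease_envs) for e in t.env_means.index],
            }
        )
        env.to_csv(directory / "truth_env.csv", index=False)
        t.genetic_values.to_csv(directory / "truth_genetic.csv", index_label="env_id")
        t.Sigma_g.to_csv(directory / "truth_sigma_g.csv", index_label="env_id")
        flags = pd.DataFrame(
            {"is_outlier": t.outlier_flags, "is_low_stand": t.low_stand_flags}
        )
        flags.to_csv(directory / "truth_flags.csv", index_label="row")
        written += [
            directory / "truth_env.csv",
            directory / "truth_genetic.csv",
            directory / "truth_sigma_g.csv",
            directory / "truth_flags.csv",
        ]
    return written


def read_bundle(directory) -> Bundle:
    """Read a bundle directory written by :func:`write_bundle`.

    The trait table gets its ``treatment`` column re-joined from the
    metadata so QC can run on it directly.
    """
    directory = Path(directory)
    trait = pd.read_csv(directory / "trait.csv")
    _check(trait, TRAIT_COLUMNS, "trait.csv")
    meta = pd.read_csv(directory / "meta.csv")
    _check(meta, META_COLUMNS, "meta.csv")
    ec = pd.read_csv(directory / "ec.csv")
    _check(ec, ["env_id"], "ec.csv")
    template = pd.read_csv(directory / "template.csv")
    _check(template, TEMPLATE_COLUMNS, "template.csv")
    geno = pd.read_csv(directory / "geno.csv", index_col="hybrid")

    trait = trait.merge(meta[["env_id", "treatment"]], on="env_id", how="left")

    truth = None
    if (directory / "truth_env.csv").exists():
        env = pd.read_csv(directory / "truth_env.csv").set_index("env_id")
        genetic = pd.read_csv(directory / "truth_genetic.csv", index_col="env_id")
        sigma = pd.read_csv(directory / "truth_sigma_g.csv", index_col="env_id")
        flags = pd.read_csv(directory / "truth_flags.csv", index_col="row")
        truth = TruthBundle(
            env_means=env["true_env_mean"],
            env_sd=env["true_env_sd"],
            genetic_sd=env["true_genetic_sd"],
            genetic_values=genetic,
            Sigma_g=sigma,
            outlier_flags=flags["is_outlier"],
            low_stand_flags=flags["is_low_stand"],
            disease_envs=list(env.index[env["is_disease_trial"]]),
        )
    return Bundle(trait=trait, meta=meta, ec=ec, geno=geno, template=template, truth=truth)


def write_submission(predictions: pd.DataFrame, path, template: pd.DataFrame | None = None) -> Path:
    """Write a submission CSV (Env, Hybrid, Yield_Mg_ha, 6 decimals).

    When a template is given, rows are emitted in template order and any
    missing pair raises a format error.
    """
    _check(predictions, ["env_id", "hybrid", "yield_mg_ha"], "predictions")
    out = predictions[["env_id", "hybrid", "yield_mg_ha"]]
    if template is not None:
        keyed = out.set_index(["env_id", "hybrid"])["yield_mg_ha"]
        idx = pd.MultiIndex.from_frame(template[["env_id", "hybrid"]])
        if not idx.isin(keyed.index).all():
            missing = idx[~idx.isin(keyed.index)]
            raise FormatError(f"predictions missing template pairs: {list(missing[:5])}")
        out = keyed.loc[idx].reset_index()
    out = out.rename(
        columns={"env_id": "Env", "hybrid": "Hybrid", "yield_mg_ha": "Yield_Mg_ha"}
    )
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_vcf_dosage(path) -> pd.DataFrame:
    """Import a VCF as a hybrid x variant dosage matrix (GT -> 0/1/2).

    Multiallelic records are rejected; missing genotypes raise, since
    imputation is upstream of the kernels.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {variant.CHROM}:{variant.POS}; "
                "split or filter the VCF first"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types)
        if np.any(gt == 2):
            raise FormatError(
                f"missing genotypes at {variant.CHROM}:{variant.POS}; impute upstream"
            )
        dosage = np.where(gt == 3, 2, gt)
        name = variant.ID or f"{variant.CHROM}_{variant.POS}"
        names.append(name)
        columns.append(dosage.astype(np.int64))
    if not names:
        raise FormatError("VCF contains no usable records")
    return pd.DataFrame(np.column_stack(columns), index=samples, columns=names)
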