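"""Readers and writers for genotype/phenotype tables and result files.

Formats are deliberately plain: UTF-8 tab-separated text with '.'
decimals.  Genotypes are minor-allele counts 0/1/2, one row per subject
with an ``id`` index column and one column per SNP; the PLINK ``.raw``
dialect (FID/IID/PAT/MAT/SEX/PHENOTYPE prefix columns, allele-dosage
SNP columns, ``NA`` for missing) is also accepted.  Phenotype tables
need ``id``, ``time`` and ``event`` columns; any extra numeric column
becomes an adjustment covariate.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotype",
    "load_dataset",
    "write_genotypes",
    "write_phenotype",
    "write_cohort",
    "write_result_json",
]

_PLINK_PREFIX = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path, dialect: str = "tsv") -> pd.DataFrame:
    """Genotype matrix as a DataFrame (index = subject id, columns = SNPs).

    ``dialect='plink_raw'`` strips the six PLINK prefix columns and uses
    IID as the subject id; subjects with any missing dosage are dropped
    with a logged count.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "plink_raw":
        raw = pd.read_csv(path, sep=r"\s+")
        missing = [c for c in _PLINK_PREFIX if c not in raw.columns]
        if missing:
            raise ValueError(f"not a PLINK .raw file: missing {missing}")
        df = raw.drop(columns=_PLINK_PREFIX).set_index(raw["IID"].astype(str))
        n_miss = int(df.isna().any(axis=1).sum())
        if n_miss:
            logger.info("dropping %d subject(s) with missing genotypes",
                        n_miss)
            df = df.dropna()
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated subject id {dup!r}")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1, 2)) | ~np.isfinite(values.astype(float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype {values[i, j]!r} out of {{0,1,2}} at subject "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    df.index = df.index.astype(str)
    return df.astype(np.int8)


def read_phenotype(path) -> pd.DataFrame:
    """Phenotype table indexed by subject id (time, event, covariates)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"id": str})
    for col in ("id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"phenotype table is missing column {col!r}")
    df = df.set_index("id")
    if df.index.duplicated().any():
        raise ValueError("duplicated subject id in phenotype table")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"non-positive time for subject {bad!r}")
    if ~df["event"].isin((0, 1)).all():
        bad = df.index[~df["event"].isin((0, 1))][0]
        raise ValueError(f"event not in {{0,1}} for subject {bad!r}")
    return df


def load_dataset(geno_path, pheno_path,
                 dialect: str = "tsv") -> SurvivalDataset:
    """Inner-join genotypes and phenotypes on subject id."""
    geno = read_genotypes(geno_path, dialect=dialect)
    pheno = read_phenotype(pheno_path)
    common = geno.index.intersection(pheno.index)
    logger.info("join: %d genotyped, %d phenotyped, %d in common",
                len(geno), len(pheno), len(common))
    if len(common) == 0:
        raise ValueError("0 subjects after joining genotypes and phenotypes")
    geno = geno.loc[common]
    pheno = pheno.loc[common]
    n_nan = int(pheno.isna().any(axis=1).sum())
    if n_nan:
        logger.info("dropping %d subject(s) with missing phenotype values",
                    n_nan)
        pheno = pheno.dropna()
        geno = geno.loc[pheno.index]
    cov_cols = [c for c in pheno.columns if c not in ("time", "event")]
    cov = pheno[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return SurvivalDataset(
        times=pheno["time"].to_numpy(dtype=float),
        events=pheno["event"].to_numpy(dtype=int),
        genotypes=geno.to_numpy(),
        covariates=cov,
        ids=tuple(pheno.index),
        snp_names=tuple(geno.columns),
    )


def write_genotypes(path, genotypes, ids, snp_names) -> None:
    df = pd.DataFrame(np.asarray(genotypes), index=list(ids),
                      columns=list(snp_names))
    df.index.name = "id"
    df.to_csv(Path(path), sep="\t")


def write_phenotype(path, times, events, ids, covariates=None,
                    cov_names=None) -> None:
    df = pd.DataFrame({"time": np.asarray(times),
                       "event": np.asarray(events)}, index=list(ids))
    if covariates is not None:
        cov = np.asarray(covariates)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = cov_names or [f"z{j + 1}" for j in range(cov.shape[1])]
        for j, name in enumerate(names):
            df[name] = cov[:, j]
    df.index.name = "id"
    df.to_csv(Path(path), sep="\t")


def write_cohort(out_dir, cohort, prefix: str = "cohort") -> dict:
    """Write the fixture trio: genotype TSV, phenotype TSV, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = cohort.data
    paths = {
        "genotypes": out_dir / f"{prefix}.geno.tsv",
        "phenotype": out_dir / f"{prefix}.pheno.tsv",
        "truth": out_dir / f"{prefix}.truth.json",
    }
    write_genotypes(paths["genotypes"], data.genotypes, data.ids,
                    data.snp_names)
    write_phenotype(paths["phenotype"], data.times, data.events, data.ids,
                    covariates=data.covariates)
    truth = {
        "causal_pair": list(cohort.causal_pair),
        "causal_snps": [data.snp_names[j] for j in cohort.causal_pair],
        "penetrance": np.asarray(cohort.model.f).tolist(),
        "maf": cohort.model.maf,
        "prevalence": cohort.model.K,
        "heritability": cohort.model.h2,
        "config": cohort.config.to_dict(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}


def write_result_json(path, result, run_config: dict, *, snp_names=None,
                      top: int = 10) -> None:
    """Serialize an MDRResult with full provenance (config + version)."""
    from . import __version__

    ranked = sorted(
        result.scores,
        key=lambda s: (-(s.mean_test if np.isfinite(s.mean_test) else
                         -np.inf), -s.cvc, s.combo),
    )

    def combo_entry(ms):
        entry = {
            "combo": list(ms.combo),
            "mean_test_score": ms.mean_test,
            "mean_train_score": ms.mean_train,
            "cvc": ms.cvc,
        }
        if snp_names is not None:
            entry["snps"] = [snp_names[j] for j in ms.combo]
        return entry

    payload = {
        "package": "survmdr",
        "version": __version__,
        "run_config": run_config,
        "method": result.method,
        "k": result.k,
        "selection_rule": result.selection_rule,
        "best": combo_entry(result.best),
        "ranking": [combo_entry(ms) for ms in ranked[:top]],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
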