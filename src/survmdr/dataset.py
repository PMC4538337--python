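"""Subject-level survival-genotype data container.

A :class:`SurvivalDataset` bundles the four pieces every method in this
package consumes: observed times, event indicators, a subject x SNP
genotype matrix coded as minor-allele counts, and an optional matrix of
numeric adjustment covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SurvivalDataset"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival outcomes with SNP genotypes.

    Parameters
    ----------
    times : (n,) array of positive floats
        Observed follow-up times (event or censoring), one time unit
        throughout.
    events : (n,) array of {0, 1}
        1 = event observed, 0 = right-censored.
    genotypes : (n, p) array of {0, 1, 2}
        Minor-allele counts per subject and SNP.
    covariates : (n, q) array, optional
        Numeric adjustment covariates; ``q = 0`` (default) means the null
        survival model is intercept/baseline only.
    ids : sequence of str, optional
        Opaque subject labels; defaults to ``s0..s{n-1}``.
    snp_names : sequence of str, optional
        Column labels for the genotype matrix; defaults to ``SNP1..SNPp``.
    """

    times: np.ndarray
    events: np.ndarray
    genotypes: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]
    ids: tuple = field(default=None)  # type: ignore[assignment]
    snp_names: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        geno = np.asarray(self.genotypes, dtype=np.int8)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D subject x SNP matrix")
        n = times.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if events.shape[0] != n or geno.shape[0] != n:
            raise ValueError("times, events and genotypes disagree on n")
        if not np.all(times > 0):
            raise ValueError("all times must be > 0")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (event)")
        bad = ~np.isin(geno, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype out of {{0,1,2}} at subject {i}, SNP column {j}"
            )
        cov = self.covariates
        cov = np.empty((n, 0)) if cov is None else np.asarray(cov, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates disagree with n")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(cov)):
            raise ValueError("non-finite values in times or covariates")
        ids = self.ids
        if ids is None:
            ids = tuple(f"s{i}" for i in range(n))
        else:
            ids = tuple(str(x) for x in ids)
            if len(ids) != n:
                raise ValueError("ids disagree with n")
            if len(set(ids)) != n:
                raise ValueError("duplicated subject ids")
        snp_names = self.snp_names
        if snp_names is None:
            snp_names = tuple(f"SNP{j + 1}" for j in range(geno.shape[1]))
        else:
            snp_names = tuple(str(x) for x in snp_names)
            if len(snp_names) != geno.shape[1]:
                raise ValueError("snp_names disagree with p")
        for name, val in (
            ("times", times), ("events", events), ("genotypes", geno),
            ("covariates", cov), ("ids", ids), ("snp_names", snp_names),
        ):
            object.__setattr__(self, name, val)
        for arr in (times, events, geno, cov):
            arr.setflags(write=False)

    @property
    def n_subjects(self) -> int:
        return self.times.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())
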