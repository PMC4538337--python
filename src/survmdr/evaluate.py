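"""Detection power and false-detection-rate estimation.

Power of a method at one simulation-grid cell is the fraction of
simulated datasets in which the method's overall best model is exactly
the (unordered) causal SNP pair; the false detection rate is the same
fraction on null cohorts where survival is independent of every SNP, so
each method is effectively picking one of the C(p, 2) pairs at random
and the expected rate is 1 / C(p, 2).

Methods evaluated on the same dataset share the simulated cohort, the
null-model fits and the cross-validation cell sums, which is what makes
grid-scale replication affordable on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import engine, residuals, simulate
from .dataset import SurvivalDataset
from .simulate import PenetranceModel, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PowerEstimate",
    "expected_null_rate",
    "run_methods",
    "estimate_power",
    "estimate_false_detection",
    "null_rate_grid",
    "results_to_frame",
]


def expected_null_rate(p: int, k: int = 2) -> float:
    """Chance level of selecting one designated combination: 1 / C(p, k)."""
    if k > p:
        raise ValueError("k cannot exceed p")
    return 1.0 / comb(p, k)


@dataclass(frozen=True)
class PowerEstimate:
    """Hit fraction of one method at one simulation-grid cell."""

    method: str
    config: dict
    n_models: int
    n_datasets_per_model: int
    hits: int
    total: int
    failures: int
    per_model_hits: tuple

    @property
    def power(self) -> float:
        return self.hits / self.total if self.total else np.nan

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = proportion_confint(self.hits, self.total, alpha=0.05,
                                    method="wilson")
        return float(lo), float(hi)


def _method_scores(data: SurvivalDataset, methods, *, family="lognormal",
                   raft_bounds=(-2.0, 2.0), adjust=False):
    """Residual score vectors per method, fitting each null model once."""
    if not adjust:
        data = SurvivalDataset(times=data.times, events=data.events,
                               genotypes=data.genotypes)
    out = {}
    if {"cox", "qcox"} & set(methods):
        mart = residuals.martingale_residuals(
            residuals.fit_cox_null(data), data)
        for m in ("cox", "qcox"):
            if m in methods:
                out[m] = mart
    aft_like = {"aft", "qaft", "daft", "raft"} & set(methods)
    if aft_like:
        std = residuals.standardized_risk_scores(
            residuals.fit_aft_null(data, family=family), data)
        if "aft" in methods:
            out["aft"] = std
        if "qaft" in methods:
            out["qaft"] = std
        if "daft" in methods:
            out["daft"] = residuals.discretize_scores(std)
        if "raft" in methods:
            out["raft"] = residuals.winsorize_scores(std, *raft_bounds)
    return out


def run_methods(data: SurvivalDataset, methods, *, k=2, folds=5, repeats=10,
                seed=None, family="lognormal", raft_bounds=(-2.0, 2.0),
                adjust=False) -> dict[str, engine.MDRResult]:
    """Full MDR search for several methods on one dataset.

    All methods see identical fold splits; cell sums are shared where
    methods use the same score vector.
    """
    scores = _method_scores(data, methods, family=family,
                            raft_bounds=raft_bounds, adjust=adjust)
    masks = engine.fold_masks(data.n_subjects, folds, repeats, seed)
    combos = engine.enumerate_combos(data.n_snps, k)
    mats = engine._cv_many(data.genotypes, k, scores, masks)
    return {
        m: engine._result_from_matrices(m, k, combos, tr, te, seed)
        for m, (tr, te) in mats.items()
    }


def _spawn_seeds(seed, n):
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _tally(methods, config, models, datasets_per_model, runner):
    """Shared hit-counting loop for power and null-rate estimation."""
    hits = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    per_model = {m: [] for m in methods}
    total = 0
    for model, ds_seeds in zip(models, datasets_per_model):
        model_hits = {m: 0 for m in methods}
        for s in ds_seeds:
            total += 1
            try:
                results, causal = runner(model, s)
            except residuals.FitError as exc:
                logger.warning("dataset failed, counted as non-hit: %s", exc)
                for m in methods:
                    failures[m] += 1
                continue
            for m in methods:
                if results[m].best_combo == causal:
                    model_hits[m] += 1
        for m in methods:
            hits[m] += model_hits[m]
            per_model[m].append(model_hits[m])
    return {
        m: PowerEstimate(
            method=m, config=dict(config), n_models=len(models),
            n_datasets_per_model=len(datasets_per_model[0]),
            hits=hits[m], total=total, failures=failures[m],
            per_model_hits=tuple(per_model[m]),
        )
        for m in methods
    }


def estimate_power(methods, config: SimulationConfig, *, n_models=5,
                   n_datasets=100, seed=None, k=2, folds=5, repeats=10,
                   family="lognormal", raft_bounds=(-2.0, 2.0),
                   adjust=None) -> dict[str, PowerEstimate]:
    """Causal-pair detection power, pooled over fresh penetrance models.

    For each of ``n_models`` penetrance tables (seeded rejection search
    at the cell's MAF and heritability) ``n_datasets`` cohorts are
    simulated and every method's best model compared with the ground
    truth.  Covariate adjustment defaults to on iff the generating
    covariate effect is nonzero.
    """
    methods = [methods] if isinstance(methods, str) else list(methods)
    if adjust is None:
        adjust = config.gamma != 0
    model_seeds = _spawn_seeds(seed, n_models)
    models = [simulate.generate_penetrance(config.maf, config.h2, s)
              for s in model_seeds]
    ds_seeds = [_spawn_seeds(s + 1, n_datasets) for s in model_seeds]
    bound = (simulate.censoring_bound(config)
             if config.censor_prop > 0 else None)

    def runner(model, s):
        rng = np.random.default_rng(s)
        cohort = simulate.simulate_dataset(model, config, rng,
                                           censor_bound=bound)
        results = run_methods(cohort.data, methods, k=k, folds=folds,
                              repeats=repeats, seed=s, family=family,
                              raft_bounds=raft_bounds, adjust=adjust)
        return results, cohort.causal_pair

    return _tally(methods, config.to_dict(), models, ds_seeds, runner)


def estimate_false_detection(methods, *, maf=0.2, censor_prop=0.0,
                             n_null_datasets=1000, seed=None,
                             time_model="lognormal", gamma=0.0, K=0.5,
                             k=2, folds=5, repeats=10, family="lognormal",
                             raft_bounds=(-2.0, 2.0),
                             adjust=None) -> dict[str, PowerEstimate]:
    """Detection rate of a randomly designated pair under the null.

    Cohorts use the constant penetrance table ``f_ij = K`` so survival
    is independent of every SNP; the "causal" pair recorded at
    generation is a uniformly random pair, and its detection rate should
    sit near ``1 / C(p, 2)``.
    """
    methods = [methods] if isinstance(methods, str) else list(methods)
    config = SimulationConfig(maf=maf, h2=0.2, time_model=time_model,
                              gamma=gamma, censor_prop=censor_prop)
    if adjust is None:
        adjust = gamma != 0
    model = simulate.null_penetrance(maf, K)
    ds_seeds = [_spawn_seeds(seed, n_null_datasets)]
    bound = (simulate.censoring_bound(config)
             if censor_prop > 0 else None)

    def runner(model, s):
        rng = np.random.default_rng(s)
        cohort = simulate.simulate_dataset(model, config, rng,
                                           censor_bound=bound)
        results = run_methods(cohort.data, methods, k=k, folds=folds,
                              repeats=repeats, seed=s, family=family,
                              raft_bounds=raft_bounds, adjust=adjust)
        return results, cohort.causal_pair

    out = _tally(methods, {"maf": maf, "censor_prop": censor_prop,
                           "time_model": time_model, "gamma": gamma,
                           "null": True},
                 [model], ds_seeds, runner)
    return out


def null_rate_grid(methods, *, mafs=(0.2, 0.4), censor_props=(0.0, 0.3, 0.5),
                   n_datasets_per_setting=200, seed=None,
                   time_model="lognormal", gamma=0.0, K=0.5, k=2, folds=5,
                   repeats=10) -> dict[tuple, PowerEstimate]:
    """Null detection rates over the (MAF, censoring) grid.

    One base cohort per (MAF, dataset) is reused across censoring levels
    by re-censoring its latent times, so the grid costs one simulation
    per dataset rather than one per setting.  Keys are
    ``(maf, censor_prop, method)``.
    """
    methods = [methods] if isinstance(methods, str) else list(methods)
    adjust = gamma != 0
    out: dict[tuple, PowerEstimate] = {}
    maf_seeds = _spawn_seeds(seed, len(mafs))
    for maf, mseed in zip(mafs, maf_seeds):
        model = simulate.null_penetrance(maf, K)
        configs = {cp: SimulationConfig(maf=maf, h2=0.2,
                                        time_model=time_model, gamma=gamma,
                                        censor_prop=cp)
                   for cp in censor_props}
        bounds = {cp: (simulate.censoring_bound(cfg) if cp > 0 else None)
                  for cp, cfg in configs.items()}
        counters = {(cp, m): [0, 0, 0] for cp in censor_props
                    for m in methods}  # hits, total, failures
        for s in _spawn_seeds(mseed, n_datasets_per_setting):
            rng = np.random.default_rng(s)
            base_cfg = configs[censor_props[0]]
            geno, status, causal = simulate.sample_cohort(model, base_cfg,
                                                          rng)
            z = rng.standard_normal(status.shape[0])
            t_raw, _ = simulate.generate_survival(status, z, base_cfg, rng)
            for cp in censor_props:
                obs, events = simulate.apply_censoring(
                    t_raw, cp, seed=rng.integers(2**31), bound=bounds[cp],
                )
                data = SurvivalDataset(times=obs, events=events,
                                       genotypes=geno, covariates=z[:, None])
                try:
                    results = run_methods(data, methods, k=k, folds=folds,
                                          repeats=repeats, seed=s,
                                          adjust=adjust)
                except residuals.FitError as exc:
                    logger.warning("null dataset failed: %s", exc)
                    for m in methods:
                        counters[(cp, m)][1] += 1
                        counters[(cp, m)][2] += 1
                    continue
                for m in methods:
                    counters[(cp, m)][1] += 1
                    if results[m].best_combo == causal:
                        counters[(cp, m)][0] += 1
        for cp in censor_props:
            for m in methods:
                h, tot, fail = counters[(cp, m)]
                out[(maf, cp, m)] = PowerEstimate(
                    method=m,
                    config={"maf": maf, "censor_prop": cp,
                            "time_model": time_model, "gamma": gamma,
                            "null": True},
                    n_models=1, n_datasets_per_model=tot, hits=h,
                    total=tot, failures=fail, per_model_hits=(h,),
                )
    return out


def results_to_frame(estimates) -> pd.DataFrame:
    """Tidy one-row-per-estimate table (method, grid cell, power, CI)."""
    rows = []
    for est in estimates:
        lo, hi = est.ci95
        row = {"method": est.method, "hits": est.hits, "total": est.total,
               "power": est.power, "ci_low": lo, "ci_high": hi,
               "failures": est.failures}
        row.update({k: v for k, v in est.config.items()
                    if np.isscalar(v) or v is None})
        rows.append(row)
    return pd.DataFrame(rows)
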