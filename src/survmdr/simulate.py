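"""Two-locus epistasis simulator with survival outcomes.

Cohorts are built the way the power study is designed: a 3x3 penetrance
table ``f[i, j] = P(high risk | g1 = i, g2 = j)`` over two causal SNPs
(both at the same minor allele frequency, Hardy-Weinberg equilibrium)
assigns each subject a latent high/low-risk status; equal numbers of
high- and low-risk subjects are sampled, causal-pair genotypes drawn
conditional on status by Bayes' rule, and the remaining loci filled with
independent HWE noise SNPs.  Survival times then depend on genotype only
through the binary status (log-normal, Weibull or proportional-hazards
form), with an optional independent standard-normal covariate and
uniform random censoring calibrated to a target censored fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .dataset import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "SimulatedCohort",
    "hwe_probs",
    "heritability",
    "generate_penetrance",
    "null_penetrance",
    "sample_cohort",
    "generate_survival",
    "censoring_bound",
    "apply_censoring",
    "simulate_dataset",
]

TIME_MODELS = ("lognormal", "weibull", "cox")


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for minor-allele counts 0,1,2."""
    if not 0 < maf < 1:
        raise ValueError("maf must be in (0, 1)")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def heritability(f: np.ndarray, maf: float) -> tuple[float, float]:
    """Prevalence K and variance-explained heritability of a penetrance table.

    ``K = sum_ij p_ij f_ij`` and ``h2 = sum_ij p_ij (f_ij - K)^2 / (K(1-K))``
    with ``p_ij`` the product-HWE genotype probabilities at the shared
    minor allele frequency.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (3, 3) or (f < 0).any() or (f > 1).any():
        raise ValueError("penetrance table must be 3x3 with entries in [0,1]")
    p1 = hwe_probs(maf)
    p = np.outer(p1, p1)
    k = float((p * f).sum())
    if not 0 < k < 1:
        raise ValueError(f"degenerate prevalence K={k}: heritability undefined")
    h2 = float((p * (f - k) ** 2).sum() / (k * (1 - k)))
    return k, h2


@dataclass(frozen=True)
class PenetranceModel:
    """3x3 penetrance table with its MAF, prevalence and heritability."""

    f: np.ndarray
    maf: float
    K: float
    h2: float

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        f.setflags(write=False)
        object.__setattr__(self, "f", f)
        k, h2 = heritability(f, self.maf)
        if abs(k - self.K) > 1e-6 or abs(h2 - self.h2) > 1e-6:
            raise ValueError("stored K/h2 disagree with the table")

    @classmethod
    def from_table(cls, f: np.ndarray, maf: float) -> "PenetranceModel":
        k, h2 = heritability(f, maf)
        return cls(f=np.asarray(f, dtype=float), maf=maf, K=k, h2=h2)


def null_penetrance(maf: float, K: float = 0.5) -> PenetranceModel:
    """Constant table ``f_ij = K``: status carries no genotype information."""
    return PenetranceModel.from_table(np.full((3, 3), K), maf)


def generate_penetrance(maf: float, h2_target: float, seed=None,
                        tol: float = 0.01, max_tries: int = 500, *,
                        prevalence_range: tuple[float, float] = (0.05, 0.5),
                        min_frontier_fraction: float = 0.5
                        ) -> PenetranceModel:
    """Seeded search for a pure-epistasis table at the target heritability.

    Emulates the character of the published two-locus epistasis model
    archives: tables whose risk variance is carried entirely by the
    joint genotype (both single-locus marginal penetrances exactly
    constant) with the corner-like structure of searched models (cell
    penetrances pushed toward the [0, 1] bounds).

    One candidate is built per try: a prevalence K is drawn uniformly
    from ``prevalence_range``, an extremal zero-marginal deviation table
    is found by maximizing the weighted deviation variance subject to
    the marginal and box constraints (random start -> diverse vertices),
    and the deviations are scaled down to hit ``h2_target`` exactly.
    The candidate is accepted when the target is within the table's
    frontier (scaling factor <= 1) and the table retains at least
    ``min_frontier_fraction`` of its maximal variance (keeps the
    corner-like structure; h2 caps at the frontier, which couples the
    accepted K range to the target).
    """
    if not 0 < h2_target < 1:
        raise ValueError("h2_target must be in (0, 1)")
    from scipy.optimize import minimize  # local: optional heavy import

    rng = np.random.default_rng(seed)
    p1 = hwe_probs(maf)
    p9 = np.outer(p1, p1).ravel()
    marg_rows = []
    for i in range(3):
        row = np.zeros(9)
        row[3 * i:3 * i + 3] = p1
        marg_rows.append(row)
    for j in range(3):
        col = np.zeros(9)
        col[j::3] = p1
        marg_rows.append(col)
    constraints = [{"type": "eq", "fun": lambda d, a=a: a @ d}
                   for a in marg_rows]

    for _ in range(max_tries):
        k = rng.uniform(*prevalence_range)
        d0 = rng.uniform(-k, 1 - k, 9)
        res = minimize(lambda d: -(p9 * d * d).sum(), d0,
                       constraints=constraints, bounds=[(-k, 1 - k)] * 9,
                       method="SLSQP",
                       options={"maxiter": 300, "ftol": 1e-12})
        if not res.success:
            continue
        h2_max = float((p9 * res.x ** 2).sum()) / (k * (1 - k))
        if h2_max <= 0:
            continue
        c2 = h2_target / h2_max
        if c2 > 1 or c2 < min_frontier_fraction:
            continue
        f = np.clip((k + np.sqrt(c2) * res.x).reshape(3, 3), 0.0, 1.0)
        k2, h22 = heritability(f, maf)
        if abs(h22 - h2_target) > tol:
            continue
        return PenetranceModel(f=f, maf=maf, K=k2, h2=h22)
    raise RuntimeError(
        f"no penetrance table at h2={h2_target}, maf={maf} after "
        f"{max_tries} tries; the target may exceed the pure-epistasis "
        f"frontier for prevalences in {prevalence_range}"
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one simulated cohort.

    Defaults are the power-study conditions: 200 high-risk plus 200
    low-risk subjects, 20 unlinked diallelic SNPs, genetic effect size
    1.0 on the linear predictor, one optional standard-normal covariate.
    """

    maf: float = 0.2
    h2: float = 0.2
    n_high: int = 200
    n_low: int = 200
    n_snps: int = 20
    time_model: str = "lognormal"
    beta: float = 1.0
    gamma: float = 0.0
    censor_prop: float = 0.0
    noise_maf: float | None = None  # defaults to the causal maf
    seed: int | None = None

    def __post_init__(self):
        if self.time_model not in TIME_MODELS:
            raise ValueError(f"time_model must be one of {TIME_MODELS}")
        if not 0 <= self.censor_prop < 1:
            raise ValueError("censor_prop must be in [0, 1)")
        if self.n_high + self.n_low < 10:
            raise ValueError("need at least 10 subjects")
        if self.n_snps < 2:
            raise ValueError("need at least the two causal SNPs")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated dataset plus its ground truth."""

    data: SurvivalDataset
    status: np.ndarray          # latent high-risk indicator
    causal_pair: tuple          # ground-truth SNP indices, sorted
    model: PenetranceModel
    config: SimulationConfig
    latent_times: np.ndarray = field(default=None)  # pre-censoring


def sample_cohort(model: PenetranceModel, config: SimulationConfig,
                  rng: np.random.Generator | None = None):
    """Genotypes and status for a balanced high/low-risk cohort.

    Causal-pair genotype cells are drawn from the status-conditional
    distributions ``P(g | high) = p_g f_g / K`` and
    ``P(g | low) = p_g (1 - f_g) / (1 - K)``; the other SNPs are
    independent HWE draws, and the two causal positions are randomized
    among the ``n_snps`` columns.

    Returns ``(genotypes, status, causal_pair)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p1 = hwe_probs(model.maf)
    p = np.outer(p1, p1).ravel()
    f = model.f.ravel()
    p_high = p * f / model.K
    p_low = p * (1 - f) / (1 - model.K)

    n = config.n_high + config.n_low
    status = np.concatenate(
        [np.ones(config.n_high, dtype=int), np.zeros(config.n_low, dtype=int)]
    )
    cells = np.concatenate([
        rng.choice(9, size=config.n_high, p=p_high),
        rng.choice(9, size=config.n_low, p=p_low),
    ])
    g1, g2 = cells // 3, cells % 3

    noise_maf = config.noise_maf if config.noise_maf is not None else model.maf
    geno = rng.binomial(2, noise_maf, size=(n, config.n_snps)).astype(np.int8)
    causal = np.sort(rng.choice(config.n_snps, size=2, replace=False))
    geno[:, causal[0]] = g1
    geno[:, causal[1]] = g2
    return geno, status, (int(causal[0]), int(causal[1]))


def _raw_times(status: np.ndarray, z: np.ndarray, config: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Uncensored survival times; high risk is stochastically shorter."""
    lp = config.beta * status + config.gamma * z
    n = status.shape[0]
    if config.time_model == "lognormal":
        return np.exp(-lp + rng.standard_normal(n))
    if config.time_model == "weibull":
        # standard minimum extreme value: log(-log U), U ~ U(0,1)
        eps = np.log(-np.log(rng.uniform(size=n)))
        return np.exp(-lp + eps)
    # cox: unit exponential baseline hazard
    return -np.log(rng.uniform(size=n)) / np.exp(lp)


def generate_survival(status: np.ndarray, z: np.ndarray,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None):
    """Event times from the configured time model (no censoring yet).

    AFT forms: ``log T = -(beta * status + gamma * z) + eps`` with eps
    standard normal (lognormal) or standard minimum-extreme-value
    (weibull); Cox form: ``T = -log(U) / exp(beta * status + gamma * z)``.
    Returns ``(times, events)`` with all events 1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = _raw_times(np.asarray(status), np.asarray(z), config, rng)
    return t, np.ones(t.shape[0], dtype=int)


def censoring_bound(config: SimulationConfig, *, n_ref: int = 20000,
                    seed=12345, tol: float = 1e-4) -> float:
    """Upper bound c* of the U(0, c*) censoring law hitting the target.

    The censored fraction under ``C ~ U(0, c*)`` is
    ``E[min(T / c*, 1)]``; it is solved against ``config.censor_prop``
    by root bracketing on a large reference sample of times drawn from
    the cohort's marginal time distribution (half high risk, half low,
    fresh standard-normal covariate).  Calibration is marginal: one
    bound per configuration, not per dataset.
    """
    if config.censor_prop == 0:
        return np.inf
    rng = np.random.default_rng(seed)
    n = n_ref
    status = (np.arange(n) < n // 2).astype(int)
    z = rng.standard_normal(n)
    t_ref = _raw_times(status, z, config, rng)

    def censored_fraction_minus_target(c):
        return float(np.minimum(t_ref / c, 1.0).mean()) - config.censor_prop

    lo, hi = np.min(t_ref) * 1e-6, np.max(t_ref) * 1e6
    f_lo = censored_fraction_minus_target(lo)
    f_hi = censored_fraction_minus_target(hi)
    if not f_lo > 0 > f_hi:
        raise RuntimeError(
            f"censoring calibration bracket failed: f({lo:g})={f_lo:g}, "
            f"f({hi:g})={f_hi:g}"
        )
    c_star = brentq(censored_fraction_minus_target, lo, hi, xtol=tol)
    return float(c_star)


def apply_censoring(times: np.ndarray, censor_prop: float, seed=None, *,
                    bound: float | None = None,
                    config: SimulationConfig | None = None):
    """Random right censoring at a calibrated uniform bound.

    ``censor_prop = 0`` leaves the data fully observed.  Otherwise
    censoring times ``C_i ~ U(0, c*)`` are drawn with ``c*`` either
    supplied (``bound``) or calibrated from ``config`` via
    :func:`censoring_bound`; observed time is ``min(T, C)`` and the
    event indicator ``1{T <= C}``.
    """
    times = np.asarray(times, dtype=float)
    if not 0 <= censor_prop < 1:
        raise ValueError("censor_prop must be in [0, 1)")
    if censor_prop == 0:
        return times.copy(), np.ones(times.shape[0], dtype=int)
    if bound is None:
        if config is None:
            raise ValueError("need a precomputed bound or a config")
        bound = censoring_bound(config)
    rng = np.random.default_rng(seed)
    c = rng.uniform(0, bound, size=times.shape[0])
    observed = np.minimum(times, c)
    events = (times <= c).astype(int)
    frac = 1 - events.mean()
    logger.debug("realized censored fraction %.3f (target %.3f)",
                 frac, censor_prop)
    return observed, events


def simulate_dataset(model: PenetranceModel, config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     censor_bound: float | None = None) -> SimulatedCohort:
    """One full cohort: genotypes, covariate, times, censoring, truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geno, status, causal = sample_cohort(model, config, rng)
    z = rng.standard_normal(status.shape[0])
    t_raw, _ = generate_survival(status, z, config, rng)
    if config.censor_prop > 0 and censor_bound is None:
        censor_bound = censoring_bound(config)
    obs, events = apply_censoring(
        t_raw, config.censor_prop,
        seed=rng.integers(2**31), bound=censor_bound, config=config,
    )
    data = SurvivalDataset(times=obs, events=events, genotypes=geno,
                           covariates=z[:, None])
    return SimulatedCohort(data=data, status=status, causal_pair=causal,
                           model=model, config=config, latent_times=t_raw)
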