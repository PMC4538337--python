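"""Null survival-model fits and residual-derived risk scores.

Every MDR variant in this package starts from a covariates-only ("null")
survival model — SNPs never enter the fit — and converts each subject's
departure from that model into a scalar risk score:

* Cox null model  -> martingale residual  ``delta_i - Lambda0(t_i) exp(z_i'g)``
* AFT null model  -> standardized residual ``(log t_i - mu - z_i'g) / sigma``,
  returned negated so that *larger score = shorter-than-expected survival =
  higher risk* uniformly across score kinds.

The discretized (case/control) and winsorized transforms feed the
dAFT-MDR and rAFT-MDR variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dataset import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NullModelFit",
    "RiskScoreVector",
    "FitError",
    "ConvergenceError",
    "AllCensoredError",
    "DegenerateScaleError",
    "fit_cox_null",
    "fit_aft_null",
    "martingale_residuals",
    "standardized_risk_scores",
    "discretize_scores",
    "winsorize_scores",
]

AFT_FAMILIES = ("lognormal", "weibull")


class FitError(RuntimeError):
    """A null survival model could not be fitted."""


class ConvergenceError(FitError):
    pass


class AllCensoredError(FitError):
    pass


class DegenerateScaleError(FitError):
    pass


@dataclass(frozen=True)
class NullModelFit:
    """Fitted covariates-only survival model.

    ``family`` is one of ``cox``, ``lognormal``, ``weibull``.  For the AFT
    families ``intercept`` and ``scale`` hold (mu, sigma); for Cox the
    Breslow baseline cumulative hazard is stored as a step function over
    the distinct event times.
    """

    family: str
    coefficients: np.ndarray
    intercept: float | None = None
    scale: float | None = None
    baseline_times: np.ndarray | None = None
    baseline_cumhaz: np.ndarray | None = None
    loglik: float = np.nan
    n_iter: int = 0

    def cumulative_hazard(self, times: np.ndarray) -> np.ndarray:
        """Breslow baseline cumulative hazard evaluated at ``times``.

        Zero before the first event; flat beyond the last one.
        """
        if self.family != "cox":
            raise ValueError("baseline hazard only defined for a Cox fit")
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.baseline_times, times, side="right")
        n_beyond = int((times > self.baseline_times[-1]).sum())
        if n_beyond:
            logger.debug(
                "%d time(s) beyond the last baseline step; "
                "flat extrapolation of the cumulative hazard", n_beyond,
            )
        return np.concatenate(([0.0], self.baseline_cumhaz))[idx]


@dataclass(frozen=True)
class RiskScoreVector:
    """Per-subject risk scores under the uniform orientation.

    Larger score always means shorter-than-expected survival (higher
    risk), whatever the ``kind`` (``martingale``, ``neg_standardized``,
    ``discretized``, ``winsorized``).
    """

    scores: np.ndarray
    kind: str
    bounds: tuple[float, float] | None = field(default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "scores", np.asarray(self.scores, dtype=float)
        )
        self.scores.setflags(write=False)

    def __len__(self) -> int:
        return self.scores.shape[0]


def _drop_constant_covariates(z: np.ndarray) -> np.ndarray:
    """Indices of covariate columns with nonzero variance."""
    return np.flatnonzero(z.std(axis=0) > 0)


def fit_cox_null(data: SurvivalDataset, *, tol: float = 1e-8,
                 max_iter: int = 100) -> NullModelFit:
    """Fit the covariates-only Cox model by Newton-Raphson.

    Breslow handling of tied event times throughout; the baseline
    cumulative hazard is the Breslow estimator at the fitted
    coefficients (the Nelson-Aalen estimator when there are no
    covariates).  Convergence is declared when the Newton step
    (score scaled by the information) drops below ``tol`` in absolute
    value.
    """
    if data.n_events == 0:
        raise AllCensoredError(
            "all subjects censored: no events to anchor the baseline hazard"
        )
    t = data.times
    d = data.events.astype(float)
    z_full = data.covariates
    active = _drop_constant_covariates(z_full)
    z = z_full[:, active]
    q = z.shape[1]

    order = np.argsort(t, kind="stable")
    t_s, d_s, z_s = t[order], d[order], z[order]
    n = t_s.shape[0]
    # first index of each subject's tie group: risk set of t is {k: t_k >= t}
    first_idx = np.searchsorted(t_s, t_s, side="left")
    event_rows = np.flatnonzero(d_s == 1)

    gamma = np.zeros(q)
    n_iter = 0
    if q:
        for n_iter in range(1, max_iter + 1):
            eta = z_s @ gamma
            w = np.exp(eta)
            # reversed cumulative sums give risk-set aggregates S0, S1, S2
            s0 = np.cumsum(w[::-1])[::-1][first_idx]
            s1 = np.cumsum((w[:, None] * z_s)[::-1], axis=0)[::-1][first_idx]
            zz = z_s[:, :, None] * z_s[:, None, :]
            s2 = np.cumsum((w[:, None, None] * zz)[::-1], axis=0)[::-1][first_idx]
            mu = s1 / s0[:, None]
            grad = (z_s[event_rows] - mu[event_rows]).sum(axis=0)
            v = s2 / s0[:, None, None] - mu[:, :, None] * mu[:, None, :]
            info = v[event_rows].sum(axis=0)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError(
                    f"singular information matrix at iteration {n_iter}"
                ) from exc
            gamma = gamma + step
            if np.max(np.abs(step)) < tol:
                break
        else:
            raise ConvergenceError(
                f"Cox partial-likelihood fit did not converge "
                f"in {max_iter} iterations"
            )

    eta = z_s @ gamma
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1][first_idx]
    loglik = float((eta[event_rows] - np.log(s0[event_rows])).sum())

    # Breslow baseline over distinct event times: dLambda = d_j / S0(t_j)
    ev_times = t_s[event_rows]
    uniq, first_of = np.unique(ev_times, return_index=True)
    d_per = np.add.reduceat(np.ones_like(ev_times), first_of)
    s0_per = s0[event_rows][first_of]
    cumhaz = np.cumsum(d_per / s0_per)

    coef = np.zeros(z_full.shape[1])
    coef[active] = gamma
    if len(active) < z_full.shape[1]:
        logger.info(
            "dropped %d constant covariate column(s) from the Cox fit",
            z_full.shape[1] - len(active),
        )
    return NullModelFit(
        family="cox", coefficients=coef, baseline_times=uniq,
        baseline_cumhaz=cumhaz, loglik=loglik, n_iter=n_iter,
    )


def martingale_residuals(fit: NullModelFit,
                         data: SurvivalDataset) -> RiskScoreVector:
    """``delta_i - Lambda0(t_i) exp(z_i' gamma)`` per subject.

    Already oriented: positive means more events than expected (higher
    risk).  At the fitted null model the residuals sum to zero.
    """
    if fit.family != "cox":
        raise ValueError("martingale residuals require a Cox fit")
    cumhaz = fit.cumulative_hazard(data.times)
    eta = data.covariates @ fit.coefficients
    scores = data.events - cumhaz * np.exp(eta)
    return RiskScoreVector(scores=scores, kind="martingale")


def _aft_loglik_parts(family: str):
    """(event, censored) log-density/log-survival and d/dr terms on the
    standardized residual scale."""
    if family == "lognormal":
        def parts(r, delta, s):
            ev = delta == 1
            ll = np.where(
                ev,
                -s - 0.5 * r * r - 0.5 * np.log(2 * np.pi),
                stats.norm.logsf(r),
            )
            # d loglik / d r
            mills = np.exp(stats.norm.logpdf(r) - stats.norm.logsf(r))
            dldr = np.where(ev, -r, -mills)
            return ll, dldr
    else:  # weibull: Gumbel (minimum extreme value) error
        def parts(r, delta, s):
            er = np.exp(np.clip(r, None, 500.0))
            ll = np.where(delta == 1, -s + r - er, -er)
            dldr = np.where(delta == 1, 1.0 - er, -er)
            return ll, dldr
    return parts


def fit_aft_null(data: SurvivalDataset, family: str = "lognormal", *,
                 gtol: float = 1e-12) -> NullModelFit:
    """Maximum likelihood for the covariates-only AFT null model.

    ``log t = mu + z' gamma + sigma eps`` with standard-normal ``eps``
    (lognormal) or standard minimum-extreme-value ``eps`` (weibull);
    censored subjects contribute the log survival function.  The
    uncensored lognormal case is the exact closed-form normal MLE
    (variance divisor ``n``); otherwise the likelihood is maximized by
    BFGS with an analytic gradient.
    """
    if family not in AFT_FAMILIES:
        raise ValueError(f"family must be one of {AFT_FAMILIES}")
    if data.n_events == 0:
        raise AllCensoredError("all subjects censored: AFT null fit undefined")
    y = np.log(data.times)
    delta = data.events
    z_full = data.covariates
    active = _drop_constant_covariates(z_full)
    z = z_full[:, active]
    n, q = z.shape[0], z.shape[1]
    x = np.column_stack([np.ones(n), z])

    beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid0 = y - x @ beta0
    sd0 = float(np.sqrt(np.mean(resid0**2)))
    if sd0 < 1e-10:
        raise DegenerateScaleError(
            "log-times are (conditionally) constant: scale estimate "
            "degenerates to 0"
        )

    if family == "lognormal" and delta.all():
        # exact closed form: OLS coefficients, MLE (divisor n) variance
        mu, gamma, sigma = float(beta0[0]), beta0[1:], sd0
        r = resid0 / sigma
        loglik = float(
            (-np.log(sigma) - 0.5 * r**2 - 0.5 * np.log(2 * np.pi)).sum()
        )
        n_iter = 0
    else:
        parts = _aft_loglik_parts(family)

        def negloglik_and_grad(theta):
            b, s = theta[:-1], theta[-1]
            sigma = np.exp(s)
            r = (y - x @ b) / sigma
            ll, dldr = parts(r, delta, s)
            # dr/db_j = -x_j/sigma ; dr/ds = -r ; events carry a direct -1 in d/ds
            grad_b = -(dldr / sigma) @ x
            grad_s = -(dldr * r).sum() - float(delta.sum())
            return -ll.sum(), -np.concatenate([grad_b, [grad_s]])

        theta0 = np.concatenate([beta0, [np.log(sd0)]])
        res = optimize.minimize(
            negloglik_and_grad, theta0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            raise ConvergenceError(f"AFT {family} fit diverged: {res.message}")
        if not res.success and np.max(np.abs(res.jac)) > 1e-5:
            raise ConvergenceError(
                f"AFT {family} fit did not converge after {res.nit} "
                f"iterations: {res.message}"
            )
        theta = res.x
        mu, gamma = float(theta[0]), theta[:-1][1:]
        sigma = float(np.exp(theta[-1]))
        if sigma < 1e-8:
            raise DegenerateScaleError(
                f"AFT {family} scale degenerated to {sigma:g}"
            )
        loglik = -float(res.fun)
        n_iter = int(res.nit)

    coef = np.zeros(z_full.shape[1])
    coef[active] = gamma
    return NullModelFit(
        family=family, coefficients=coef, intercept=mu, scale=sigma,
        loglik=loglik, n_iter=n_iter,
    )


def standardized_risk_scores(fit: NullModelFit,
                             data: SurvivalDataset) -> RiskScoreVector:
    """Negated standardized AFT residuals.

    The raw residual ``r_i = (log t_i - mu - z_i' gamma) / sigma`` (the
    same formula for censored subjects) is negative when survival is
    shorter than the null model expects, so ``-r_i`` puts the vector in
    the uniform larger-is-higher-risk orientation: a subject with a
    negative raw residual (a case) gets a positive score.
    """
    if fit.family not in AFT_FAMILIES:
        raise ValueError("standardized risk scores require an AFT fit")
    r = (np.log(data.times) - fit.intercept
         - data.covariates @ fit.coefficients) / fit.scale
    return RiskScoreVector(scores=-r, kind="neg_standardized")


def discretize_scores(scores: RiskScoreVector) -> RiskScoreVector:
    """Binary case/control labels from score signs.

    Label 1 (case) iff the oriented score is strictly positive, i.e. the
    raw standardized residual is negative; exact zeros are controls.
    """
    labels = (scores.scores > 0).astype(float)
    return RiskScoreVector(scores=labels, kind="discretized")


def winsorize_scores(scores: RiskScoreVector, lower: float = -2.0,
                     upper: float = 2.0) -> RiskScoreVector:
    """Clip scores into ``[lower, upper]`` (oriented score scale)."""
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    clipped = np.clip(scores.scores, lower, upper)
    n_clip = int((clipped != scores.scores).sum())
    if n_clip:
        logger.info("winsorized %d score(s) to [%g, %g]", n_clip, lower, upper)
    return RiskScoreVector(scores=clipped, kind="winsorized",
                           bounds=(float(lower), float(upper)))
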