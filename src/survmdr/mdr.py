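"""Scikit-learn style estimators for the six survival-MDR variants.

Each estimator takes a subject x SNP genotype matrix ``X`` (minor-allele
counts 0/1/2) and a right-censored survival outcome ``y``, fits the
covariates-only null survival model, converts subjects to residual risk
scores, and runs the cross-validated MDR search for the best k-locus
interaction.  ``predict`` maps new genotype rows to the high/low-risk
attribute of the selected model (cells never seen in training predict
low risk).

``y`` may be a structured array with ``event``/``time`` fields (the
scikit-survival convention), an ``(n, 2)`` array of ``[time, event]``
columns, or a ``(times, events)`` pair.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import engine, residuals
from .dataset import SurvivalDataset

__all__ = [
    "BaseSurvivalMDR",
    "CoxMDR",
    "QCoxMDR",
    "AFTMDR",
    "QAFTMDR",
    "DiscretizedAFTMDR",
    "RestrictedAFTMDR",
    "make_estimator",
    "ESTIMATORS",
]


def parse_survival_y(y):
    """Normalize the survival outcome to ``(times, events)`` arrays."""
    if isinstance(y, tuple) and len(y) == 2:
        times, events = y
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = {n.lower(): n for n in y.dtype.names}
        try:
            times = y[names["time"]]
            events = y[names["event"]]
        except KeyError as exc:
            raise ValueError(
                "structured y needs 'time' and 'event' fields"
            ) from exc
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                "y must be (times, events), a structured event/time array, "
                "or an (n, 2) array of [time, event]"
            )
        times, events = arr[:, 0], arr[:, 1]
    return (np.asarray(times, dtype=float),
            np.asarray(events).astype(int))


class BaseSurvivalMDR(BaseEstimator):
    """Shared fit/predict machinery; subclasses set the method string."""

    _method: str = ""

    def __init__(self, k=2, folds=5, repeats=10, random_state=None):
        self.k = k
        self.folds = folds
        self.repeats = repeats
        self.random_state = random_state

    # subclasses override ------------------------------------------------
    def _null_fit(self, data: SurvivalDataset) -> residuals.NullModelFit:
        raise NotImplementedError

    def _risk_scores(self, fit, data) -> residuals.RiskScoreVector:
        raise NotImplementedError

    # --------------------------------------------------------------------
    def fit(self, X, y, covariates=None):
        """Run the null-model fit and the cross-validated MDR search."""
        X = np.asarray(X)
        times, events = parse_survival_y(y)
        data = SurvivalDataset(times=times, events=events, genotypes=X,
                               covariates=covariates)
        self.null_fit_ = self._null_fit(data)
        self.risk_scores_ = self._risk_scores(self.null_fit_, data)
        self.result_ = engine.cross_validate(
            data.genotypes, self.risk_scores_, self._method, k=self.k,
            folds=self.folds, repeats=self.repeats, seed=self.random_state,
        )
        self.best_combo_ = self.result_.best_combo
        self.cvc_ = self.result_.best.cvc
        self.mean_test_score_ = self.result_.best.mean_test
        # final cell classification on all subjects, used by predict
        cells = engine.assign_cells(data.genotypes, self.best_combo_)
        self.cell_classification_ = engine.classify_cells(
            self.risk_scores_, cells, self._method,
            np.ones(data.n_subjects, dtype=bool), combo=self.best_combo_,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """High-risk indicator (1 = high) under the selected model."""
        check_is_fitted(self, "best_combo_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} SNPs, expected {self.n_features_in_}"
            )
        cells = engine.assign_cells(X, self.best_combo_)
        return self.cell_classification_.predict(cells)


class _CoxScored(BaseSurvivalMDR):
    def _null_fit(self, data):
        return residuals.fit_cox_null(data)

    def _risk_scores(self, fit, data):
        return residuals.martingale_residuals(fit, data)


class _AFTScored(BaseSurvivalMDR):
    def __init__(self, k=2, folds=5, repeats=10, random_state=None,
                 family="lognormal"):
        super().__init__(k=k, folds=folds, repeats=repeats,
                         random_state=random_state)
        self.family = family

    def _null_fit(self, data):
        return residuals.fit_aft_null(data, family=self.family)

    def _risk_scores(self, fit, data):
        return residuals.standardized_risk_scores(fit, data)


class CoxMDR(_CoxScored):
    """Cox-MDR: cells high iff their martingale-residual sum is positive;
    balanced accuracy against the residual-sign pseudo status."""

    _method = "cox"


class QCoxMDR(_CoxScored):
    """qCox-MDR: cells high iff their mean martingale residual exceeds the
    overall training mean; pooled two-sample t as the split score."""

    _method = "qcox"


class AFTMDR(_AFTScored):
    """AFT-MDR: cells high iff their (negated) standardized-residual sum
    is positive; balanced accuracy scoring."""

    _method = "aft"


class QAFTMDR(_AFTScored):
    """qAFT-MDR: standardized-residual cell means against the overall
    mean; pooled two-sample t scoring."""

    _method = "qaft"


class DiscretizedAFTMDR(_AFTScored):
    """dAFT-MDR: subjects discretized to case (negative raw residual) or
    control, then the original MDR case/control-ratio cell rule."""

    _method = "daft"

    def _risk_scores(self, fit, data):
        return residuals.discretize_scores(
            residuals.standardized_risk_scores(fit, data)
        )


class RestrictedAFTMDR(_AFTScored):
    """rAFT-MDR: standardized residuals winsorized into [lower, upper]
    (oriented score scale) before the sum-sign cell rule."""

    _method = "raft"

    def __init__(self, k=2, folds=5, repeats=10, random_state=None,
                 family="lognormal", lower=-2.0, upper=2.0):
        super().__init__(k=k, folds=folds, repeats=repeats,
                         random_state=random_state, family=family)
        self.lower = lower
        self.upper = upper

    def _risk_scores(self, fit, data):
        return residuals.winsorize_scores(
            residuals.standardized_risk_scores(fit, data),
            lower=self.lower, upper=self.upper,
        )


ESTIMATORS = {
    "cox": CoxMDR,
    "qcox": QCoxMDR,
    "aft": AFTMDR,
    "qaft": QAFTMDR,
    "daft": DiscretizedAFTMDR,
    "raft": RestrictedAFTMDR,
}


def make_estimator(method: str, **params) -> BaseSurvivalMDR:
    """Instantiate an estimator by its short method name."""
    try:
        cls = ESTIMATORS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; pick from {sorted(ESTIMATORS)}"
        ) from None
    return cls(**params)
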