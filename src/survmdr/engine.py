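"""Genotype-cell MDR search over k-locus combinations.

The engine enumerates all C(p, k) SNP combinations, collapses each
combination's 3^k genotype cells into a binary high/low-risk attribute
on a training fold, scores the attribute on training and testing
subjects, and selects the best interaction model by repeated k-fold
cross-validation.

Six classification/scoring rules are supported, all driven by a
residual-derived risk score in the uniform "larger = higher risk"
orientation:

========  =======================================  =====================
method    cell rule (training subjects)            split score
========  =======================================  =====================
cox       sum of martingale residuals > 0          balanced accuracy
aft       sum of neg. standardized residuals > 0   balanced accuracy
raft      as aft, on winsorized residuals          balanced accuracy
daft      case/control ratio > overall ratio       balanced accuracy
qcox      cell mean > overall training mean        pooled two-sample t
qaft      cell mean > overall training mean        pooled two-sample t
========  =======================================  =====================

For the balanced-accuracy methods the subject-level pseudo case/control
status is the sign of the subject's own score (case iff score > 0).
Per split the best combination is the training-score argmax; the overall
best model is the mean-testing-score argmax (cross-validation
consistency, then lexicographic order, break ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .residuals import RiskScoreVector, discretize_scores

__all__ = [
    "METHODS",
    "CellClassification",
    "ModelScore",
    "MDRResult",
    "enumerate_combos",
    "assign_cells",
    "classify_cells",
    "balanced_accuracy",
    "t_statistic",
    "fold_masks",
    "cross_validate",
    "select_best",
]

METHODS = ("cox", "aft", "daft", "raft", "qcox", "qaft")

#: score kinds accepted per method
_COMPATIBLE_KINDS = {
    "cox": ("martingale",),
    "qcox": ("martingale",),
    "aft": ("neg_standardized", "winsorized"),
    "qaft": ("neg_standardized", "winsorized"),
    "raft": ("neg_standardized", "winsorized"),
    "daft": ("discretized",),
}

#: scoring family per method
_SCORING = {
    "cox": "ba", "aft": "ba", "daft": "ba", "raft": "ba",
    "qcox": "t", "qaft": "t",
}

HIGH, LOW, EMPTY = 1, 0, -1


@dataclass(frozen=True)
class CellClassification:
    """High/low/empty label per genotype cell of one SNP combination."""

    combo: tuple
    labels: np.ndarray  # (3^k,) int8 of {HIGH, LOW, EMPTY}
    method: str

    def predict(self, cells: np.ndarray) -> np.ndarray:
        """1 where a subject's cell is high risk; empty cells predict low."""
        return (self.labels[cells] == HIGH).astype(int)


@dataclass(frozen=True)
class ModelScore:
    """Per-split training/testing scores of one SNP combination."""

    combo: tuple
    train_scores: np.ndarray  # (n_splits,)
    test_scores: np.ndarray   # (n_splits,)
    cvc: int

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_scores))

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_scores))


@dataclass(frozen=True)
class MDRResult:
    """Outcome of an MDR search: the selected model plus the full ranking."""

    method: str
    k: int
    best_combo: tuple
    scores: tuple  # all ModelScore, lexicographic combo order
    seed: int | None
    selection_rule: str = (
        "max mean testing score; ties by cross-validation consistency, "
        "then lexicographic combination order"
    )

    @property
    def best(self) -> ModelScore:
        idx = [s.combo for s in self.scores].index(self.best_combo)
        return self.scores[idx]


def enumerate_combos(p: int, k: int) -> list[tuple]:
    """All C(p, k) unordered SNP index tuples in lexicographic order."""
    if not 1 <= k <= p:
        raise ValueError(f"need 1 <= k <= p, got k={k}, p={p}")
    return list(combinations(range(p), k))


def assign_cells(genotypes: np.ndarray, combo: tuple) -> np.ndarray:
    """Base-3 genotype cell index per subject for one SNP combination.

    For k = 2 the genotype pair (g1, g2) maps to cell ``3*g1 + g2``.
    """
    g = np.asarray(genotypes)[:, list(combo)]
    bad = ~np.isin(g, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype out of {{0,1,2}} for subject {i}, SNP {combo[j]}"
        )
    k = len(combo)
    weights = 3 ** np.arange(k - 1, -1, -1)
    return (g * weights).sum(axis=1).astype(np.int64)


def classify_cells(scores: RiskScoreVector, cells: np.ndarray, method: str,
                   train_mask: np.ndarray,
                   combo: tuple = ()) -> CellClassification:
    """Label each genotype cell high/low risk from training subjects only.

    Reference (per-cell loop) implementation of the three rules; the
    cross-validation path vectorizes the same arithmetic.
    """
    _check_method(method, scores)
    cells = np.asarray(cells)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("empty training set")
    s = scores.scores
    n_cells = int(3 ** len(combo)) if combo else int(cells.max()) + 1
    labels = np.full(n_cells, EMPTY, dtype=np.int8)

    s_tr, cells_tr = s[train_mask], cells[train_mask]
    if method == "daft":
        tot_case = float(s_tr.sum())
        tot_ctrl = float(len(s_tr) - tot_case)
    elif method in ("qcox", "qaft"):
        overall_mean = float(s_tr.mean())

    for c in range(n_cells):
        in_cell = cells_tr == c
        if not in_cell.any():
            continue
        sc = s_tr[in_cell]
        if method in ("cox", "aft", "raft"):
            high = sc.sum() > 0
        elif method == "daft":
            cases = float(sc.sum())
            ctrls = float(len(sc) - cases)
            # cross-multiplied case/control ratio comparison; a cell with
            # cases but no controls is high
            high = cases * tot_ctrl > ctrls * tot_case
        else:  # qcox / qaft
            high = sc.mean() > overall_mean
        labels[c] = HIGH if high else LOW
    return CellClassification(combo=tuple(combo), labels=labels, method=method)


def balanced_accuracy(labels: np.ndarray, predicted: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 of high-risk predictions.

    ``labels`` are subject case/control status (1 = case), ``predicted``
    the cell-derived high-risk indicator.  A side with no subjects (no
    cases, or no controls) contributes the chance level 0.5.
    """
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions differ in length")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    sens = (predicted[pos] == 1).mean() if n_pos else 0.5
    spec = (predicted[~pos] == 0).mean() if n_neg else 0.5
    return float((sens + spec) / 2)


def t_statistic(scores: np.ndarray, group_high: np.ndarray) -> float:
    """Pooled-variance two-sample t, high minus low.

    Sentinels keep the ranking well defined: an empty group gives
    ``-inf`` (such a model can never win), a zero pooled variance gives
    ``+inf`` when the means differ and 0 when they coincide.
    """
    scores = np.asarray(scores, dtype=float)
    group_high = np.asarray(group_high, dtype=bool)
    hi, lo = scores[group_high], scores[~group_high]
    if hi.size == 0 or lo.size == 0:
        return -np.inf
    diff = hi.mean() - lo.mean()
    df = hi.size + lo.size - 2
    ss = ((hi - hi.mean()) ** 2).sum() + ((lo - lo.mean()) ** 2).sum()
    if df <= 0 or ss <= 0:
        return 0.0 if abs(diff) <= 1e-12 else np.inf
    sp2 = ss / df
    return float(diff / np.sqrt(sp2 * (1.0 / hi.size + 1.0 / lo.size)))


def fold_masks(n: int, folds: int, repeats: int, seed) -> np.ndarray:
    """Training masks, one row per (repeat, fold) split.

    Subjects are shuffled once per repeat and cut into ``folds``
    contiguous blocks; row ``r * folds + f`` holds True for subjects
    *outside* block f of repeat r (no stratification).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds (one must be held out)")
    if n < folds:
        raise ValueError(f"cannot cut {n} subjects into {folds} folds")
    rng = np.random.default_rng(seed)
    masks = np.ones((folds * repeats, n), dtype=bool)
    for r in range(repeats):
        perm = rng.permutation(n)
        for f, block in enumerate(np.array_split(perm, folds)):
            masks[r * folds + f, block] = False
    return masks


def _check_method(method: str, scores: RiskScoreVector) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; pick from {METHODS}")
    if scores.kind not in _COMPATIBLE_KINDS[method]:
        raise ValueError(
            f"method {method!r} needs a score of kind "
            f"{_COMPATIBLE_KINDS[method]}, got {scores.kind!r}"
        )


# ---------------------------------------------------------------------------
# vectorized cross-validation core


def _one_hot_cells(genotypes: np.ndarray, combos: list[tuple]) -> np.ndarray:
    """(n, n_combos * 3^k) indicator matrix of subject cell membership."""
    n = genotypes.shape[0]
    n_cells = 3 ** len(combos[0])
    cells = np.empty((len(combos), n), dtype=np.int64)
    for j, combo in enumerate(combos):
        cells[j] = assign_cells(genotypes, combo)
    c = np.zeros((n, len(combos) * n_cells))
    cols = np.arange(len(combos)) * n_cells + cells.T  # (n, n_combos)
    c[np.arange(n)[:, None], cols] = 1.0
    return c


class _CellSums:
    """Caches (train, test) per-cell sums of subject vectors.

    All aggregates the engine needs are of the form
    ``sum over training subjects in cell c of v_i`` for some subject
    vector v; computing them as one matrix product per vector and
    reusing them across methods is what makes the 5x10 CV over all
    combinations cheap.
    """

    def __init__(self, onehot: np.ndarray, masks: np.ndarray):
        self._c = onehot
        self._m = masks.astype(float)
        self._cache: dict = {}

    def sums(self, v: np.ndarray | None):
        key = "ones" if v is None else id(v)
        if key not in self._cache:
            vv = np.ones(self._c.shape[0]) if v is None else v
            tr = (self._m * vv) @ self._c
            te = vv @ self._c - tr
            self._cache[key] = (tr, te)
        return self._cache[key]


def _ba_scores(shape, high, a_tr, b_tr, a_te, b_te):
    """Balanced accuracy per (split, combo) for train and test sides."""
    out = []
    for a, b in ((a_tr, b_tr), (a_te, b_te)):
        tp = (high * a).reshape(shape).sum(axis=2)
        fp = (high * b).reshape(shape).sum(axis=2)
        tot_a = a.reshape(shape).sum(axis=2)
        tot_b = b.reshape(shape).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sens = np.where(tot_a > 0, tp / tot_a, 0.5)
            spec = np.where(tot_b > 0, (tot_b - fp) / tot_b, 0.5)
        out.append((sens + spec) / 2)
    return out


def _t_scores(shape, high, n_s, s_s, q_s):
    """Pooled t per (split, combo) from per-cell count/sum/sum-of-squares."""
    n_h = (high * n_s).reshape(shape).sum(axis=2)
    s_h = (high * s_s).reshape(shape).sum(axis=2)
    q_h = (high * q_s).reshape(shape).sum(axis=2)
    n_l = n_s.reshape(shape).sum(axis=2) - n_h
    s_l = s_s.reshape(shape).sum(axis=2) - s_h
    q_l = q_s.reshape(shape).sum(axis=2) - q_h
    with np.errstate(invalid="ignore", divide="ignore"):
        m_h = s_h / n_h
        m_l = s_l / n_l
        diff = m_h - m_l
        df = n_h + n_l - 2
        ss = (q_h - n_h * m_h**2) + (q_l - n_l * m_l**2)
        ss = np.maximum(ss, 0.0)
        t = diff / np.sqrt(ss / df * (1.0 / n_h + 1.0 / n_l))
    degen = (df <= 0) | (ss <= 1e-28)
    t = np.where(degen & (np.abs(diff) > 1e-12), np.inf, t)
    t = np.where(degen & (np.abs(diff) <= 1e-12), 0.0, t)
    t = np.where((n_h == 0) | (n_l == 0), -np.inf, t)
    return t


def _cv_many(genotypes: np.ndarray, k: int,
             method_scores: dict[str, RiskScoreVector],
             masks: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(train, test) score matrices of shape (n_splits, n_combos) per method.

    Matrix products over the cell-membership indicator are shared between
    methods that use the same underlying score vector.
    """
    combos = enumerate_combos(genotypes.shape[1], k)
    onehot = _one_hot_cells(genotypes, combos)
    sums = _CellSums(onehot, masks)
    mfl = masks.astype(float)
    shape = (masks.shape[0], len(combos), 3 ** k)

    # per-split totals are combo-independent
    n_tr_tot = mfl.sum(axis=1)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    squares: dict[int, np.ndarray] = {}
    for method, rsv in method_scores.items():
        _check_method(method, rsv)
        s = rsv.scores
        n_tr, n_te = sums.sums(None)
        if _SCORING[method] == "ba":
            y = s if rsv.kind == "discretized" else (s > 0).astype(float)
            a_tr, a_te = sums.sums(y)
            b_tr, b_te = n_tr - a_tr, n_te - a_te
            if method == "daft":
                tot_a = a_tr.reshape(shape).sum(axis=2)
                tot_b = b_tr.reshape(shape).sum(axis=2)
                high = (a_tr.reshape(shape) * tot_b[:, :, None]
                        > b_tr.reshape(shape) * tot_a[:, :, None])
                high = high.reshape(a_tr.shape)
            else:
                s_tr, _ = sums.sums(s)
                high = s_tr > 0
            tr, te = _ba_scores(shape, high, a_tr, b_tr, a_te, b_te)
        else:  # t-statistic methods
            s_tr, s_te = sums.sums(s)
            key = id(s)
            if key not in squares:
                squares[key] = s * s
            q_tr, q_te = sums.sums(squares[key])
            mean_tr = (mfl @ s) / n_tr_tot
            high = (s_tr > mean_tr[:, None] * n_tr) & (n_tr > 0)
            tr = _t_scores(shape, high, n_tr, s_tr, q_tr)
            te = _t_scores(shape, high, n_te, s_te, q_te)
        out[method] = (tr, te)
    return out


def _result_from_matrices(method: str, k: int, combos: list[tuple],
                          tr: np.ndarray, te: np.ndarray,
                          seed) -> MDRResult:
    best_per_split = np.argmax(tr, axis=1)  # first index wins ties (lex)
    cvc = np.bincount(best_per_split, minlength=len(combos))
    scores = tuple(
        ModelScore(combo=combos[j], train_scores=tr[:, j].copy(),
                   test_scores=te[:, j].copy(), cvc=int(cvc[j]))
        for j in range(len(combos))
    )
    return select_best(scores, method=method, k=k, seed=seed)


def cross_validate(genotypes: np.ndarray, scores: RiskScoreVector,
                   method: str, k: int = 2, folds: int = 5,
                   repeats: int = 10, seed=None) -> MDRResult:
    """Full MDR search: repeated k-fold CV over all C(p, k) combinations.

    Per split, cells are classified on the training folds and scored on
    both sides; the per-split winner (training-score argmax) feeds the
    cross-validation consistency count.  Cells empty in training predict
    low risk in testing.
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if len(scores) != n:
        raise ValueError("scores and genotypes disagree on n")
    masks = fold_masks(n, folds, repeats, seed)
    combos = enumerate_combos(genotypes.shape[1], k)
    tr, te = _cv_many(genotypes, k, {method: scores}, masks)[method]
    return _result_from_matrices(method, k, combos, tr, te, seed)


def select_best(scores, method: str = "", k: int | None = None,
                seed=None) -> MDRResult:
    """Pick the overall best model from per-combination ModelScores.

    Maximum mean testing score; ties broken by higher cross-validation
    consistency, then by lexicographic combination order.
    """
    scores = tuple(scores)
    if not scores:
        raise ValueError("no model scores to select from")
    mean_test = np.array([s.mean_test for s in scores])
    # a mix of +inf/-inf split scores averages to NaN; such a model never wins
    mean_test = np.where(np.isnan(mean_test), -np.inf, mean_test)
    cvc = np.array([s.cvc for s in scores])
    best = max(range(len(scores)),
               key=lambda j: (mean_test[j], cvc[j], -j))
    if k is None:
        k = len(scores[0].combo)
    return MDRResult(method=method, k=k, best_combo=scores[best].combo,
                     scores=scores, seed=seed)
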