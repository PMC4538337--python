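"""MDR engine: cell assignment, classification rules, scores, CV search.

The vectorized cross-validation path is checked against a brute-force
re-computation written independently of the engine (plain loops over
cells and splits), and the t statistic against scipy's pooled t.
"""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from survmdr import engine
from survmdr.engine import (EMPTY, HIGH, LOW, assign_cells,
                            balanced_accuracy, classify_cells,
                            cross_validate, enumerate_combos, fold_masks,
                            select_best, t_statistic)
from survmdr.residuals import RiskScoreVector


class TestCombosAndCells:
    @pytest.mark.parametrize("p,k,count", [(20, 2, 190), (3, 3, 1), (5, 1, 5)])
    def test_combination_counts(self, p, k, count):
        combos = enumerate_combos(p, k)
        assert len(combos) == count == comb(p, k)
        assert combos == sorted(combos)

    def test_k_larger_than_p_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combos(3, 4)

    def test_base3_encoding(self):
        geno = np.array([[0, 0], [2, 2], [1, 2], [0, 2]])
        np.testing.assert_array_equal(assign_cells(geno, (0, 1)),
                                      [0, 8, 5, 2])

    def test_cells_in_range(self, rng):
        geno = rng.integers(0, 3, (50, 6))
        cells = assign_cells(geno, (1, 4))
        assert cells.shape == (50,)
        assert cells.min() >= 0 and cells.max() < 9

    def test_bad_genotype_names_subject_and_snp(self):
        geno = np.array([[0, 1], [3, 0]])
        with pytest.raises(ValueError, match="subject 1"):
            assign_cells(geno, (0, 1))


class TestClassifyCells:
    def test_sum_rule_positive_sum_is_high(self):
        # cell 0 holds scores {0.3, -0.1}: sum 0.2 > 0 -> high risk
        scores = RiskScoreVector(scores=np.array([0.3, -0.1, -0.5]),
                                 kind="martingale")
        cells = np.array([0, 0, 1])
        cc = classify_cells(scores, cells, "cox",
                            np.ones(3, dtype=bool), combo=(0, 1))
        assert cc.labels[0] == HIGH
        assert cc.labels[1] == LOW
        assert cc.labels[2] == EMPTY

    def test_mean_rule_tie_is_low(self):
        # cell mean exactly equal to the overall mean -> low (strict rule)
        scores = RiskScoreVector(scores=np.array([1.0, 1.0, 1.0, 1.0]),
                                 kind="martingale")
        cc = classify_cells(scores, np.array([0, 0, 1, 1]), "qcox",
                            np.ones(4, dtype=bool), combo=(0, 1))
        assert cc.labels[0] == LOW and cc.labels[1] == LOW

    def test_ratio_rule_daft(self):
        # cell 0: 3 cases / 1 control vs overall ratio 1.0 -> high;
        # a case-only cell is high; an empty cell stays empty
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1.0])
        cells = np.array([0, 0, 0, 0, 1, 1, 1, 2])
        scores = RiskScoreVector(scores=labels, kind="discretized")
        cc = classify_cells(scores, cells, "daft",
                            np.ones(8, dtype=bool), combo=(0, 1))
        assert cc.labels[0] == HIGH
        assert cc.labels[1] == LOW
        assert cc.labels[2] == HIGH  # 1 case, 0 controls
        assert cc.labels[3] == EMPTY

    def test_training_mask_restricts_subjects(self):
        scores = RiskScoreVector(scores=np.array([5.0, -1.0]),
                                 kind="martingale")
        mask = np.array([False, True])
        cc = classify_cells(scores, np.array([0, 0]), "cox", mask,
                            combo=(0, 1))
        assert cc.labels[0] == LOW  # only the -1.0 subject is in training

    def test_incompatible_score_kind_rejected(self):
        scores = RiskScoreVector(scores=np.zeros(2), kind="martingale")
        with pytest.raises(ValueError, match="kind"):
            classify_cells(scores, np.zeros(2, dtype=int), "daft",
                           np.ones(2, dtype=bool), combo=(0, 1))


class TestScoresFunctions:
    def test_balanced_accuracy_two_by_two(self):
        # labels (1,1,0,0), predictions (1,0,0,0): sens 1/2, spec 1
        assert balanced_accuracy([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75

    def test_balanced_accuracy_perfect_and_chance(self, rng):
        y = rng.integers(0, 2, 40)
        assert balanced_accuracy(y, y) == 1.0
        assert balanced_accuracy(y, 1 - y) == 0.0

    def test_balanced_accuracy_empty_side_contributes_half(self):
        assert balanced_accuracy([1, 1], [1, 0]) == pytest.approx(0.5)

    def test_t_statistic_closed_form(self):
        # high {4,5,6} vs low {1,2,3}: t = 3 / sqrt(2/3) = 3.674...
        t = t_statistic(np.array([4, 5, 6, 1, 2, 3.0]),
                        np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_t_statistic_matches_scipy_oracle(self, rng):
        for _ in range(25):
            x = rng.standard_normal(rng.integers(5, 40))
            g = rng.uniform(size=x.size) < 0.4
            if g.all() or (~g).any() is False or g.sum() < 2 or (~g).sum() < 2:
                continue
            ours = t_statistic(x, g)
            ref = stats.ttest_ind(x[g], x[~g], equal_var=True).statistic
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_t_statistic_antisymmetric_and_degenerate(self, rng):
        x = rng.standard_normal(12)
        g = np.arange(12) < 5
        assert t_statistic(x, g) == pytest.approx(-t_statistic(x, ~g))
        assert t_statistic(x, np.zeros(12, dtype=bool)) == -np.inf
        same = np.full(6, 2.0)
        assert t_statistic(same, np.arange(6) < 3) == 0.0
        diff = np.array([1.0, 1.0, 2.0, 2.0])
        assert t_statistic(diff, np.array([0, 0, 1, 1], dtype=bool)) == np.inf


class TestFolds:
    def test_partition_and_determinism(self):
        m1 = fold_masks(23, 5, 10, seed=3)
        m2 = fold_masks(23, 5, 10, seed=3)
        np.testing.assert_array_equal(m1, m2)
        assert m1.shape == (50, 23)
        # within each repeat the 5 test folds partition the subjects
        for r in range(10):
            test_counts = (~m1[5 * r:5 * r + 5]).sum(axis=0)
            np.testing.assert_array_equal(test_counts, np.ones(23))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            fold_masks(10, 1, 1, seed=0)

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            fold_masks(3, 5, 1, seed=0)


def _brute_force_cv(genotypes, scores, method, folds, repeats, seed):
    """Independent slow re-computation of per-split train/test scores."""
    from survmdr.residuals import discretize_scores

    n, p = genotypes.shape
    combos = list(combinations(range(p), 2))
    masks = fold_masks(n, folds, repeats, seed)
    if scores.kind == "discretized":
        y = scores.scores
    else:
        y = (scores.scores > 0).astype(float)
    tr = np.zeros((len(masks), len(combos)))
    te = np.zeros_like(tr)
    for j, combo in enumerate(combos):
        cells = assign_cells(genotypes, combo)
        for s, mask in enumerate(masks):
            cc = classify_cells(scores, cells, method, mask, combo=combo)
            pred = cc.predict(cells)
            if method in ("qcox", "qaft"):
                tr[s, j] = t_statistic(scores.scores[mask],
                                       pred[mask].astype(bool))
                te[s, j] = t_statistic(scores.scores[~mask],
                                       pred[~mask].astype(bool))
            else:
                tr[s, j] = balanced_accuracy(y[mask], pred[mask])
                te[s, j] = balanced_accuracy(y[~mask], pred[~mask])
    return combos, tr, te


@pytest.mark.parametrize("method,kind", [
    ("cox", "martingale"), ("aft", "neg_standardized"),
    ("daft", "discretized"), ("raft", "winsorized"),
    ("qcox", "martingale"), ("qaft", "neg_standardized"),
])
def test_engine_matches_brute_force(method, kind, rng):
    """Vectorized CV equals the independent loop re-computation, n <= 30."""
    n, p = 30, 5
    geno = rng.integers(0, 3, (n, p))
    raw = rng.standard_normal(n)
    raw -= raw.mean()
    s = (raw > 0).astype(float) if kind == "discretized" else raw
    scores = RiskScoreVector(scores=s, kind=kind)
    result = cross_validate(geno, scores, method, k=2, folds=3, repeats=2,
                            seed=11)
    combos, tr, te = _brute_force_cv(geno, scores, method, 3, 2, 11)
    for j, ms in enumerate(result.scores):
        assert ms.combo == combos[j]
        np.testing.assert_allclose(ms.train_scores, tr[:, j], atol=1e-10)
        np.testing.assert_allclose(ms.test_scores, te[:, j], atol=1e-10)
    # selection agrees with a direct argmax on the oracle matrices
    mean_te = np.where(np.isnan(te.mean(0)), -np.inf, te.mean(0))
    cvc = np.bincount(np.argmax(tr, axis=1), minlength=len(combos))
    best = max(range(len(combos)), key=lambda i: (mean_te[i], cvc[i], -i))
    assert result.best_combo == combos[best]


class TestCrossValidate:
    def test_split_count_and_determinism(self, rng):
        geno = rng.integers(0, 3, (40, 4))
        scores = RiskScoreVector(scores=rng.standard_normal(40),
                                 kind="martingale")
        r1 = cross_validate(geno, scores, "cox", folds=5, repeats=10, seed=2)
        r2 = cross_validate(geno, scores, "cox", folds=5, repeats=10, seed=2)
        assert all(ms.train_scores.shape == (50,) for ms in r1.scores)
        assert r1.best_combo == r2.best_combo
        for a, b in zip(r1.scores, r2.scores):
            np.testing.assert_array_equal(a.test_scores, b.test_scores)

    def test_subject_permutation_leaves_scores_unchanged(self, rng):
        # fold membership is defined by subject identity, so scores are
        # invariant when the same permutation is applied to subjects and
        # to the fold masks
        n = 30
        geno = rng.integers(0, 3, (n, 4))
        s = rng.standard_normal(n)
        perm = rng.permutation(n)
        masks = fold_masks(n, 3, 2, seed=5)
        combos = enumerate_combos(4, 2)
        m1 = engine._cv_many(geno, 2, {"qcox": RiskScoreVector(
            s, "martingale")}, masks)["qcox"]
        m2 = engine._cv_many(geno[perm], 2, {"qcox": RiskScoreVector(
            s[perm], "martingale")}, masks[:, perm])["qcox"]
        np.testing.assert_allclose(m1[0], m2[0], atol=1e-10)
        np.testing.assert_allclose(m1[1], m2[1], atol=1e-10)
        # and the per-cell classification itself is order-free
        cells = assign_cells(geno, combos[0])
        c1 = classify_cells(RiskScoreVector(s, "martingale"), cells, "cox",
                            np.ones(n, dtype=bool), combo=combos[0])
        c2 = classify_cells(RiskScoreVector(s[perm], "martingale"),
                            cells[perm], "cox", np.ones(n, dtype=bool),
                            combo=combos[0])
        np.testing.assert_array_equal(c1.labels, c2.labels)

    def test_cvc_totals_match_split_count(self, easy_cohort):
        from survmdr.evaluate import run_methods
        res = run_methods(easy_cohort.data, ["qaft"], folds=5, repeats=10,
                          seed=1)["qaft"]
        assert sum(ms.cvc for ms in res.scores) == 50

    def test_easy_cohort_recovers_causal_pair(self, easy_cohort):
        from survmdr.evaluate import run_methods
        res = run_methods(easy_cohort.data, ["qaft", "qcox"], seed=4)
        assert res["qaft"].best_combo == easy_cohort.causal_pair
        assert res["qcox"].best_combo == easy_cohort.causal_pair


class TestSelectBest:
    def _ms(self, combo, te, cvc):
        return engine.ModelScore(combo=combo, train_scores=np.zeros(2),
                                 test_scores=np.asarray(te, dtype=float),
                                 cvc=cvc)

    def test_single_and_clear_winner(self):
        a = self._ms((0, 1), [0.9, 0.9], 1)
        b = self._ms((0, 2), [0.3, 0.3], 1)
        assert select_best([a]).best_combo == (0, 1)
        assert select_best([a, b]).best_combo == (0, 1)

    def test_tie_broken_by_cvc_then_lex(self):
        a = self._ms((0, 1), [0.5, 0.5], 10)
        b = self._ms((0, 2), [0.5, 0.5], 40)
        assert select_best([a, b]).best_combo == (0, 2)
        c = self._ms((0, 3), [0.5, 0.5], 40)
        assert select_best([b, c]).best_combo == (0, 2)


def test_daft_labels_equal_logtime_threshold(rng):
    """No censoring, no covariates, lognormal: dAFT case label is exactly
    the indicator {log t below the mean log t}."""
    from survmdr.dataset import SurvivalDataset
    from survmdr.residuals import (discretize_scores, fit_aft_null,
                                   standardized_risk_scores)
    t = rng.lognormal(0.3, 1.0, 60)
    data = SurvivalDataset(times=t, events=np.ones(60, dtype=int),
                           genotypes=np.zeros((60, 2), dtype=int))
    labels = discretize_scores(standardized_risk_scores(
        fit_aft_null(data, "lognormal"), data)).scores
    np.testing.assert_array_equal(labels,
                                  (np.log(t) < np.log(t).mean()).astype(int))
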