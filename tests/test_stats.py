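"""ROC/AUC inference: pair-count oracle, DeLong variance calibration,
bootstrap cross-check of the paired test, folds, Holm, merging, CV."""

import numpy as np
import pytest
from oracles import auc_bruteforce

from mammoseq import stats
from mammoseq import synthetic as syn
from mammoseq.imaging import Case, Exam


def _score_set(scores, labels, tag="a"):
    n = len(scores)
    return stats.ScoreSet([f"c{i}" for i in range(n)], np.asarray(scores, float),
                          np.asarray(labels, int), np.zeros(n, int), classifier=tag)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def _dummy_cases(n_pos, n_neg):
    out = []
    for i in range(n_pos + n_neg):
        label = "malignant" if i < n_pos else "benign"
        out.append(Case(f"c{i}", label, "left", [Exam(0.0), Exam(1.0)]))
    return out


def test_fold_assignment_matches_cohort_structure():
    cases = _dummy_cases(49, 50)
    fa = stats.assign_folds(cases, k=5, seed=0)
    labels = {c.case_id: c.y for c in cases}
    for row in fa.summary(labels):
        assert 19 <= row["n"] <= 20
        assert 9 <= row["n_malignant"] <= 10
    assert sorted(fa.mapping) == sorted(c.case_id for c in cases)  # each once
    fa2 = stats.assign_folds(cases, k=5, seed=0)
    assert fa.mapping == fa2.mapping
    with pytest.raises(ValueError):
        stats.assign_folds(_dummy_cases(3, 50), k=5)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_closed_forms():
    assert stats.auc(_score_set([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])).auc == 1.0
    r = stats.auc(_score_set([0.5] * 6, [1, 1, 1, 0, 0, 0]))
    assert r.auc == 0.5
    with pytest.raises(ValueError):
        stats.auc(_score_set([0.1, 0.2], [1, 1]))


def test_auc_matches_exhaustive_pair_counting(rng):
    for _ in range(20):
        n = int(rng.integers(6, 30))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        ours = stats.auc(_score_set(scores, labels)).auc
        assert ours == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)


def test_auc_is_rank_invariant(rng):
    labels = rng.integers(0, 2, 40)
    labels[:3] = 1
    labels[-3:] = 0
    scores = rng.normal(size=40)
    a = stats.auc(_score_set(scores, labels)).auc
    b = stats.auc(_score_set(np.exp(3 * scores), labels)).auc
    assert a == b


def test_delong_se_matches_empirical_auc_spread():
    """Null simulation: the DeLong SE should track the empirical sd of the
    AUC over replicates within 10% (n=200 per class)."""
    rng = np.random.default_rng(42)
    aucs, ses = [], []
    for _ in range(500):
        scores = rng.normal(size=400)
        labels = np.array([1] * 200 + [0] * 200)
        r = stats.auc(scores, labels)
        aucs.append(r.auc)
        ses.append(r.se)
    assert np.mean(ses) == pytest.approx(np.std(aucs), rel=0.10)


def test_ci_contains_auc_and_flip_identity(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    labels[:2] = 1
    labels[-2:] = 0
    r = stats.auc(_score_set(scores, labels))
    assert r.ci95[0] <= r.auc <= r.ci95[1]
    flipped = stats.auc(_score_set(scores, 1 - labels))
    assert r.auc == pytest.approx(1.0 - flipped.auc)


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def test_compare_paired_identical_and_flipped(rng):
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = 1
    labels[-2:] = 0
    a = _score_set(scores, labels, "a")
    res = stats.compare_paired(a, _score_set(scores, labels, "b"))
    assert res["delta_auc"] == 0.0 and res["p"] == 1.0
    flipped = stats.compare_paired(a, _score_set(1 - scores, labels, "b"))
    auc_a = stats.auc(a).auc
    assert flipped["delta_auc"] == pytest.approx(2 * auc_a - 1)


def test_compare_paired_rejects_case_mismatch(rng):
    a = _score_set([0.1, 0.9, 0.4, 0.6], [0, 1, 0, 1])
    b = stats.ScoreSet(["x0", "x1", "x2", "x3"], np.array([0.1, 0.9, 0.4, 0.6]),
                       np.array([0, 1, 0, 1]), np.zeros(4, int))
    with pytest.raises(ValueError):
        stats.compare_paired(a, b)


def test_compare_paired_matches_bootstrap(rng):
    """Case-resampling bootstrap oracle: the DeLong p-value should agree with
    a bootstrap-SE normal p within 0.02."""
    n = 80
    labels = np.array([1] * 40 + [0] * 40)
    strength = rng.normal(size=n)
    sa = strength * 0.8 + rng.normal(size=n) + labels * 0.8
    sb = strength * 0.8 + rng.normal(size=n) + labels * 0.4
    a = _score_set(sa, labels, "a")
    b = _score_set(sb, labels, "b")
    res = stats.compare_paired(a, b)

    deltas = []
    for _ in range(10_000):
        idx = rng.integers(0, n, n)
        if labels[idx].sum() in (0, n):
            continue
        da = auc_delta = (stats.auc(sa[idx], labels[idx]).auc
                          - stats.auc(sb[idx], labels[idx]).auc)
        deltas.append(da)
    from scipy.stats import norm

    p_boot = 2 * norm.sf(abs(res["delta_auc"]) / np.std(deltas))
    assert res["p"] == pytest.approx(p_boot, abs=0.02)


# ---------------------------------------------------------------------------
# Holm and merging
# ---------------------------------------------------------------------------

def test_holm_sequential_rule():
    res = stats.holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
    assert res["reject"] == [True, False, False]
    single = stats.holm_bonferroni([0.04])
    assert single["reject"] == [True] and single["p_adjusted"] == [0.04]
    ones = stats.holm_bonferroni([1.0, 1.0])
    assert ones["reject"] == [False, False]
    assert all(p == 1.0 for p in ones["p_adjusted"])
    with pytest.raises(ValueError):
        stats.holm_bonferroni([])


def test_merge_outputs_arithmetic(rng):
    labels = np.array([0, 1])
    a = _score_set([0.2, 0.6], labels, "a")
    b = _score_set([0.4, 0.8], labels, "b")
    merged = stats.merge_outputs(a, b)
    np.testing.assert_allclose(merged.scores, [0.3, 0.7])
    same = stats.merge_outputs(a, a)
    assert stats.auc(same).auc == stats.auc(a).auc


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class _MeanDiffTrainer:
    """Deterministic toy trainer: scores by first-vs-last feature change."""

    def fit(self, cases):
        return self

    def score(self, case):
        first = np.asarray(case.exams[0].left)
        last = np.asarray(case.exams[-1].left)
        return float((last - first).sum())


def test_cross_validate_scores_each_case_once(small_cohort):
    folds = stats.assign_folds(small_cohort, k=5, seed=1)
    ss = stats.cross_validate(_MeanDiffTrainer, small_cohort, folds)
    assert sorted(ss.case_ids) == sorted(c.case_id for c in small_cohort)
    ss2 = stats.cross_validate(_MeanDiffTrainer, small_cohort, folds)
    np.testing.assert_array_equal(ss.scores, ss2.scores)


def test_cross_validate_permuted_labels_is_null():
    """Label permutation kills the drift signal: mean CV AUC of the toy
    change-detector stays within 2 SE of 0.5 over 5 permutations."""
    cases = syn.generate_feature_sequences(
        syn.CohortSpec(n_cases=100, prevalence=0.5, seed=8), dim=4
    )
    rng = np.random.default_rng(0)
    aucs = []
    for _ in range(5):
        labels = np.array([c.y for c in cases])
        rng.shuffle(labels)
        permuted = [
            Case(c.case_id, "malignant" if y else "benign",
                 c.affected_laterality, c.exams)
            for c, y in zip(cases, labels)
        ]
        folds = stats.assign_folds(permuted, k=5, seed=3)
        ss = stats.cross_validate(_MeanDiffTrainer, permuted, folds)
        aucs.append(stats.auc(ss).auc)
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) <= 2 * max(se, 0.02)
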