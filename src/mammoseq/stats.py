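"""Evaluation machinery: grouped stratified folds, ROC/AUC inference,
paired AUC comparison, multiplicity correction, and classifier merging.

AUC is the Mann--Whitney statistic (ties counted 1/2).  Its standard error,
confidence interval and tests come from DeLong's nonparametric method: the
variance of the AUC (and the covariance of two AUCs computed on the *same*
cases) is estimated from the per-case placement values, which also yields the
paired z-test for a difference of AUCs.  Tests against chance use
``z = (AUC - 0.5) / SE``, two-sided.  Family-wise error over a set of
comparisons is controlled step-down (Holm--Bonferroni).

All exams of a case share its fold ("grouped"), and folds are stratified by
the case label so each fold carries the cohort's malignant/benign ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy import stats as sps

from .imaging import Case


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """case_id -> fold index, with the stratification summary per fold."""

    mapping: dict[str, int]
    k: int
    seed: int

    def fold_of(self, case_id: str) -> int:
        return self.mapping[case_id]

    def summary(self, labels: dict[str, int]) -> list[dict]:
        out = []
        for f in range(self.k):
            ids = [cid for cid, ff in self.mapping.items() if ff == f]
            pos = sum(labels[cid] for cid in ids)
            out.append({"fold": f, "n": len(ids), "n_malignant": pos})
        return out


@dataclass
class ScoreSet:
    """Out-of-fold per-case scores with labels and provenance tags."""

    case_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    folds: np.ndarray
    classifier: str = ""
    laterality: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.folds = np.asarray(self.folds, dtype=int)
        n = len(self.case_ids)
        if not (len(self.scores) == len(self.labels) == len(self.folds) == n):
            raise ValueError("score-set fields must have equal length")
        if len(set(self.case_ids)) != n:
            raise ValueError("one score per case: duplicate case_ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def aligned(self, other: "ScoreSet") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Scores of both sets in this set's case order; labels must agree."""
        if set(self.case_ids) != set(other.case_ids):
            raise ValueError("score sets cover different cases")
        pos = {cid: k for k, cid in enumerate(other.case_ids)}
        idx = np.array([pos[cid] for cid in self.case_ids])
        if not np.array_equal(self.labels, other.labels[idx]):
            raise ValueError("labels disagree between score sets")
        return self.scores, other.scores[idx], self.labels


@dataclass
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    p_vs_chance: float
    n_pos: int = 0
    n_neg: int = 0


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

def assign_folds(cases: list[Case], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Case-level stratified folds, deterministic given the seed.

    Within each class, cases are shuffled by a seeded RNG and dealt
    round-robin over folds, so per-fold class counts differ by at most one
    from exact proportionality.  The same assignment is reused by every
    classifier to keep pairwise comparisons paired.
    """
    rng = np.random.default_rng(seed)
    mapping: dict[str, int] = {}
    for label in (1, 0):
        ids = [c.case_id for c in cases if c.y == label]
        if len(ids) < k:
            raise ValueError(f"class {label} has {len(ids)} cases, fewer than k={k}")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for j, cid in enumerate(ids):
            mapping[cid] = j % k
    return FoldAssignment(mapping, k, seed)


# ---------------------------------------------------------------------------
# AUC and DeLong inference
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Mann--Whitney AUC plus DeLong per-case placement values V10, V01."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # pairwise comparison with ties counted 1/2
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :])
    psi = gt + 0.5 * eq
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # one per positive case
    v01 = psi.mean(axis=0)  # one per negative case
    return auc, v10, v01


def _var1(v: np.ndarray) -> float:
    """Sample variance (ddof=1); 0 for a single observation."""
    return float(v.var(ddof=1)) if len(v) > 1 else 0.0


def _cov1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1]) if len(a) > 1 else 0.0


def auc(scores: ScoreSet | np.ndarray, labels: np.ndarray | None = None) -> ROCResult:
    """AUC with DeLong SE, 95% CI, and two-sided p-value against chance."""
    if isinstance(scores, ScoreSet):
        s, y = scores.scores, scores.labels
    else:
        s, y = np.asarray(scores, float), np.asarray(labels, int)
    a, v10, v01 = _placements(s, y)
    m, n = len(v10), len(v01)
    var = _var1(v10) / m + _var1(v01) / n
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    if se > 0:
        z = (a - 0.5) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = 0.0 if a != 0.5 else 1.0
    return ROCResult(a, se, ci, p, n_pos=m, n_neg=n)


def compare_paired(a: ScoreSet, b: ScoreSet) -> dict:
    """Paired DeLong test for the AUC difference of two classifiers.

    Both score sets must cover the same cases (same fold structure); the
    covariance between the two AUCs is estimated from the joint placements.
    Returns ``delta_auc = AUC_a - AUC_b`` with its 95% CI and two-sided p.
    """
    sa, sb, y = a.aligned(b)
    auc_a, v10_a, v01_a = _placements(sa, y)
    auc_b, v10_b, v01_b = _placements(sb, y)
    m, n = len(v10_a), len(v01_a)
    var_a = _var1(v10_a) / m + _var1(v01_a) / n
    var_b = _var1(v10_b) / m + _var1(v01_b) / n
    cov = _cov1(v10_a, v10_b) / m + _cov1(v01_a, v01_b) / n
    var_d = max(var_a + var_b - 2.0 * cov, 0.0)
    delta = auc_a - auc_b
    se = float(np.sqrt(var_d))
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(delta) / se))
    else:
        p = 1.0 if delta == 0 else 0.0
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delta_auc": float(delta),
        "se": se,
        "ci95": (float(delta - 1.96 * se), float(delta + 1.96 * se)),
        "p": p,
    }


def holm_bonferroni(pvals, alpha: float = 0.05) -> dict:
    """Step-down Holm correction: per-test reject flags and adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return {"reject": reject.tolist(), "p_adjusted": adjusted.tolist()}


def merge_outputs(a: ScoreSet, b: ScoreSet, laterality: str = "merged") -> ScoreSet:
    """Per-case arithmetic mean of two classifiers' scores (same cases)."""
    sa, sb, _ = a.aligned(b)
    return ScoreSet(
        list(a.case_ids), (sa + sb) / 2.0, a.labels, a.folds,
        classifier=f"mean({a.classifier},{b.classifier})", laterality=laterality,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

class Trainer(Protocol):
    def fit(self, cases: list[Case]) -> "Trainer": ...
    def score(self, case: Case) -> float: ...


def cross_validate(
    trainer_factory,
    cases: list[Case],
    folds: FoldAssignment,
    classifier: str = "",
    laterality: str = "",
) -> ScoreSet:
    """Out-of-fold scores: for each fold, fit a fresh trainer on the other
    folds (all preprocessing inside the loop) and score the held-out cases.

    ``trainer_factory()`` must return an object with ``fit(cases)`` and
    ``score(case)``; every case is scored exactly once.
    """
    ids, scores, labels, fold_idx = [], [], [], []
    for f in range(folds.k):
        train_cases = [c for c in cases if folds.fold_of(c.case_id) != f]
        test_cases = [c for c in cases if folds.fold_of(c.case_id) == f]
        if len({c.y for c in train_cases}) < 2:
            raise ValueError(f"fold {f}: training portion has a single class")
        model = trainer_factory().fit(train_cases)
        for c in test_cases:
            ids.append(c.case_id)
            scores.append(model.score(c))
            labels.append(c.y)
            fold_idx.append(f)
    return ScoreSet(ids, np.array(scores), np.array(labels), np.array(fold_idx),
                    classifier=classifier, laterality=laterality)
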