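"""Single-timepoint comparator: PCA to 25 components, then an SVM.

Where the LSTM sees the whole antecedent sequence, this baseline sees only
the chronologically last antecedent exam (the one closest to diagnosis).
Features are z-scored, projected onto the leading principal components, and
classified by a support vector machine whose continuous decision margin is
used directly as the ROC score (AUC is rank-based, so no calibration is
needed).  Scaler, PCA and SVM are all fit strictly on training-fold cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .imaging import Case
from .lstm import FeatureSequence, sequences_from_cases


@dataclass
class SVMConfig:
    n_components: int = 25
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_components * component variance)
    seed: int = 0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ValueError("C must be positive")


def select_last_prior(case: Case, laterality: str = "affected") -> FeatureSequence:
    """The features of the chronologically last antecedent exam.

    Exams are sorted by date first, so manifest ordering is irrelevant.
    Returned as a length-1 sequence to keep provenance alongside the vector.
    """
    if not case.exams:
        raise ValueError(f"case {case.case_id} has no exams")
    (seq,) = sequences_from_cases([case], laterality)
    return FeatureSequence(
        seq.case_id, seq.label, seq.laterality,
        seq.times[-1:], seq.features[-1:, :],
    )


def fit_pca(train_matrix: np.ndarray, n_components: int = 25) -> PCA:
    """PCA with a deterministic sign convention on centered training rows.

    Components exceeding the matrix rank raise; each component's
    largest-magnitude loading is made positive so repeated fits agree.
    """
    x = np.asarray(train_matrix, dtype=float)
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    for k in range(pca.components_.shape[0]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
    return pca


def train_svm(components: np.ndarray, labels: np.ndarray, config: SVMConfig) -> SVC:
    """Fit the SVM on PCA components; both classes must be present."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class training set")
    svm = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
              random_state=config.seed)
    svm.fit(np.asarray(components, float), labels)
    return svm


def score_svm(model: SVC, x: np.ndarray) -> np.ndarray:
    """Continuous decision scores (signed margin) for ROC analysis."""
    return model.decision_function(np.atleast_2d(np.asarray(x, float)))


class SVMTrainer:
    """Leakage-safe fit/score pipeline over the last antecedent exam.

    ``fit`` learns scaler -> PCA -> SVM on training cases only; ``score``
    applies the frozen transforms to one held-out case.
    """

    def __init__(self, config: SVMConfig | None = None, laterality: str = "affected"):
        self.config = config or SVMConfig()
        self.laterality = laterality
        self.scaler: StandardScaler | None = None
        self.pca: PCA | None = None
        self.svm: SVC | None = None

    def _matrix(self, cases: list[Case]) -> tuple[np.ndarray, np.ndarray]:
        rows = [select_last_prior(c, self.laterality) for c in cases]
        x = np.vstack([r.features for r in rows])
        y = np.array([r.label for r in rows])
        return x, y

    def fit(self, cases: list[Case]) -> "SVMTrainer":
        x, y = self._matrix(cases)
        if self.config.scale_features:
            self.scaler = StandardScaler().fit(x)
            x = self.scaler.transform(x)
        n_comp = min(self.config.n_components, min(x.shape[0] - 1, x.shape[1]))
        self.pca = fit_pca(x, n_comp)
        self.svm = train_svm(self.pca.transform(x), y, self.config)
        return self

    def score(self, case: Case) -> float:
        if self.svm is None:
            raise RuntimeError("trainer is not fitted")
        x = select_last_prior(case, self.laterality).features
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return float(score_svm(self.svm, self.pca.transform(x))[0])
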