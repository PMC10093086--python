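"""End-to-end experiment orchestration.

One :class:`RunConfig` drives the whole study design: simulate a cohort,
obtain per-exam feature sequences for two feature banks ("cnn"-style pooled
deep features and "radiomics"), train the temporal LSTM and the
single-timepoint PCA+SVM baseline on the affected and contralateral breasts
with one shared fold assignment, merge classifier outputs across
lateralities and across feature banks, and report ROC/AUC inference plus the
pre-registered pairwise comparisons with Holm--Bonferroni correction.

The report's classifier table has seven rows per classifier family --
{cnn, radiomics} x {affected, contralateral, both lateralities} plus the
cnn+radiomics merge -- and, mirroring the study design, no significance
tests are attached to merged classifiers.

Two data paths exist: ``mode="features"`` (default) draws feature-level
sequences directly from the synthetic generator, which is the fast path used
for classifier experiments; ``mode="images"`` renders texture patches and
runs the actual extractors (slow, but exercises the full chain).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deep, radiomics
from .baseline import SVMConfig, SVMTrainer
from .imaging import Case, Exam
from .lstm import LSTMConfig, LSTMTrainer
from .stats import (FoldAssignment, ScoreSet, assign_folds, auc,
                    compare_paired, cross_validate, holm_bonferroni,
                    merge_outputs)
from .synthetic import CohortSpec, generate_feature_sequences, render_texture, sample_cohort

FEATURE_SET_DIMS = {"radiomics": 50, "cnn": 64}
LATERALITIES_EVAL = ("affected", "contralateral")


@dataclass
class RunConfig:
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    roi_size: int = 512
    feature_sets: tuple[str, ...] = ("cnn", "radiomics")
    mode: str = "features"
    lstm: LSTMConfig = dc_field(
        default_factory=lambda: LSTMConfig(hidden_dim=8, learning_rate=0.5,
                                           epochs=300, batch_size=8, seed=0)
    )
    svm: SVMConfig = dc_field(default_factory=SVMConfig)
    cv_k: int = 5
    cv_seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.feature_sets) - set(FEATURE_SET_DIMS)
        if unknown:
            raise ValueError(f"unknown feature set(s): {sorted(unknown)}")
        if self.mode not in ("features", "images"):
            raise ValueError("mode must be 'features' or 'images'")
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_sets"] = list(self.feature_sets)
        return d

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Feature acquisition
# ---------------------------------------------------------------------------

def _feature_cases(config: RunConfig, feature_set: str) -> list[Case]:
    """Cases whose exam payloads are feature vectors for one feature bank.

    Cohort structure is shared across feature sets (same seed); only the
    feature content differs, so fold assignments and pairings line up.
    """
    offset = {"cnn": 1, "radiomics": 2}[feature_set]
    spec = config.cohort
    if config.mode == "features":
        return generate_feature_sequences(
            spec, dim=FEATURE_SET_DIMS[feature_set],
            feature_seed=spec.seed + 10_000 * offset,
        )
    # image path: render each breast's texture and run the real extractor
    layout = deep.backbone_layout("tiny-test", f"random:{config.cohort.seed}")
    out = []
    for case in sample_cohort(spec):
        exams = []
        for k, exam in enumerate(case.exams):
            payload = {}
            for j, side in enumerate(("left", "right")):
                rng = np.random.default_rng(
                    (abs(hash((case.case_id, k, side))) + spec.seed) % (2**31)
                )
                img = render_texture(exam.side(side),
                                     (config.roi_size, config.roi_size), rng)
                if feature_set == "radiomics":
                    payload[side] = radiomics.extract_radiomics(img).values
                else:
                    payload[side] = deep.extract_deep(img, layout).values
            exams.append(Exam(exam.date_years, payload["left"], payload["right"]))
        out.append(Case(case.case_id, case.label, case.affected_laterality, exams))
    return out


# ---------------------------------------------------------------------------
# Feature-table interchange (CSV schema shared by the CLI tools)
# ---------------------------------------------------------------------------

def cases_to_frame(cases: list[Case], names: list[str] | None = None) -> pd.DataFrame:
    """Flatten feature-payload cases to one row per (case, exam, laterality)."""
    rows = []
    for case in cases:
        for k, exam in enumerate(case.exams):
            for side in ("left", "right"):
                vec = np.asarray(exam.side(side), dtype=float)
                cols = names or [f"f{j}" for j in range(len(vec))]
                row = {
                    "case_id": case.case_id,
                    "label": case.label,
                    "affected_laterality": case.affected_laterality,
                    "exam_index": k,
                    "exam_date": exam.date_years,
                    "laterality": side,
                }
                row.update(dict(zip(cols, vec)))
                rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cases(df: pd.DataFrame) -> list[Case]:
    """Inverse of :func:`cases_to_frame`."""
    meta = ["case_id", "label", "affected_laterality", "exam_index",
            "exam_date", "laterality"]
    feat_cols = [c for c in df.columns if c not in meta]
    cases = []
    for cid, sub in df.groupby("case_id", sort=True):
        label = sub["label"].iloc[0]
        aff = sub["affected_laterality"].iloc[0]
        exams = []
        for _, esub in sorted(sub.groupby("exam_index"), key=lambda kv: kv[0]):
            sides = {}
            for side in ("left", "right"):
                srow = esub[esub["laterality"] == side]
                sides[side] = srow[feat_cols].to_numpy(float)[0] if len(srow) else None
            exams.append(Exam(float(esub["exam_date"].iloc[0]),
                              sides["left"], sides["right"]))
        cases.append(Case(str(cid), label, aff, exams))
    return cases


def scores_to_frame(ss: ScoreSet) -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": ss.case_ids, "fold": ss.folds, "score": ss.scores,
        "label": ss.labels, "classifier": ss.classifier, "laterality": ss.laterality,
    })


# ---------------------------------------------------------------------------
# The experiment
# ---------------------------------------------------------------------------

def _roc_row(name: str, ss: ScoreSet, tested: bool = True) -> dict:
    r = auc(ss)
    row = {"classifier": name, "auc": r.auc, "se": r.se, "ci95": list(r.ci95),
           "n_pos": r.n_pos, "n_neg": r.n_neg}
    if tested:
        row["p_vs_chance"] = r.p_vs_chance
    else:
        row["p_vs_chance"] = None  # merged classifiers are reported untested
    return row


def run_experiment(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report."""
    cohort_cases = generate_feature_sequences(config.cohort, dim=2)  # fold skeleton
    folds = assign_folds(cohort_cases, k=config.cv_k, seed=config.cv_seed)

    score_sets: dict[tuple[str, str, str], ScoreSet] = {}
    for fs in config.feature_sets:
        cases = _feature_cases(config, fs)
        for lat in LATERALITIES_EVAL:
            lstm_cfg = dataclasses.replace(config.lstm)
            score_sets[(fs, "lstm", lat)] = cross_validate(
                lambda: LSTMTrainer(lstm_cfg, lat), cases, folds,
                classifier=f"{fs}-lstm", laterality=lat,
            )
            svm_cfg = dataclasses.replace(config.svm)
            score_sets[(fs, "svm", lat)] = cross_validate(
                lambda: SVMTrainer(svm_cfg, lat), cases, folds,
                classifier=f"{fs}-svm", laterality=lat,
            )

    rows = []
    merged: dict[tuple[str, str], ScoreSet] = {}
    for model in ("lstm", "svm"):
        for fs in config.feature_sets:
            a = score_sets[(fs, model, "affected")]
            c = score_sets[(fs, model, "contralateral")]
            both = merge_outputs(a, c, laterality="merged")
            merged[(fs, model)] = both
            rows.append(_roc_row(f"{fs} (affected) {model}", a))
            rows.append(_roc_row(f"{fs} (contralateral) {model}", c))
            rows.append(_roc_row(f"{fs} (both lateralities) {model}", both,
                                 tested=False))
        if len(config.feature_sets) == 2:
            fs1, fs2 = config.feature_sets
            combo = merge_outputs(merged[(fs1, model)], merged[(fs2, model)],
                                  laterality="merged")
            rows.append(_roc_row(f"{fs1}+{fs2} (both lateralities) {model}", combo,
                                 tested=False))

    # pre-registered pairwise comparisons (unmerged classifiers only)
    comparisons = []
    for lat in LATERALITIES_EVAL:
        if len(config.feature_sets) == 2:
            fs1, fs2 = config.feature_sets
            comparisons.append((
                f"{fs1}-lstm vs {fs2}-lstm ({lat})",
                compare_paired(score_sets[(fs1, "lstm", lat)],
                               score_sets[(fs2, "lstm", lat)]),
            ))
        for fs in config.feature_sets:
            comparisons.append((
                f"{fs}: lstm vs svm ({lat})",
                compare_paired(score_sets[(fs, "lstm", lat)],
                               score_sets[(fs, "svm", lat)]),
            ))
    for fs in config.feature_sets:
        comparisons.append((
            f"{fs}-lstm: affected vs contralateral",
            compare_paired(score_sets[(fs, "lstm", "affected")],
                           score_sets[(fs, "lstm", "contralateral")]),
        ))
    holm = holm_bonferroni([c[1]["p"] for c in comparisons])

    report = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "folds": folds.summary({c.case_id: c.y for c in cohort_cases}),
        "classifiers": rows,
        "comparisons": [
            {"name": name, **res, "holm_reject": rej, "p_holm": padj}
            for (name, res), rej, padj in zip(
                comparisons, holm["reject"], holm["p_adjusted"]
            )
        ],
        "notes": "AUC inference by DeLong's method; merged classifiers reported "
                 "without significance tests.",
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        for (fs, model, lat), ss in score_sets.items():
            scores_to_frame(ss).to_csv(out / f"scores_{fs}_{model}_{lat}.csv",
                                       index=False)
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return report
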