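"""Synthetic longitudinal two-breast cohorts with a temporal "field effect".

The generator emulates the structure of the case--control screening cohort
the package targets: ~99 women (about half with a future malignant biopsy),
2--9 craniocaudal exams per woman at irregular intervals averaging 1.27
years, and left+right parenchymal texture at every exam.  The only
label-dependent signal is a slow *temporal drift* of texture parameters in
future-malignant cases -- present in the affected breast and, when the
``field_effect`` flag is set, equally in the contralateral breast.  Per-case
baseline jitter is made much larger than the total drift, so a single
timepoint carries (by construction) essentially no label information; only
change over time does.

Two paths are provided:

* an image path (:func:`render_texture`) producing 512x512 power-law noise
  fields with clustered Gaussian lumps, a standard surrogate for
  mammographic parenchyma, on which the radiomic bank operates; and
* a fast feature-level path (:func:`generate_feature_sequences`) producing
  AR(1) feature trajectories with the same drift logic, for classifier
  experiments that do not need images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .imaging import Case, Exam, write_image_png16, write_manifest

# Distribution of exams per case: mass concentrated at 2-4 with a tail to 9,
# mirroring the target cohort's histogram shape (implementer constant).
SEQ_LEN_SUPPORT = np.arange(2, 10)
SEQ_LEN_PROBS = np.array([0.30, 0.25, 0.17, 0.10, 0.07, 0.05, 0.03, 0.03])

# Texture-path scales: how the abstract per-year effect size delta maps onto
# texture parameters, and how large the per-case baseline jitter is.
BETA_DRIFT_SCALE = 0.05       # d(beta)/dyear per unit delta
LUMP_DRIFT_SCALE = 0.10      # relative d(log lump_density)/dyear per unit delta
BETA_JITTER_SCALE = 0.05      # sd of per-case beta offset per unit baseline_jitter
LUMP_JITTER_SD = 0.10         # sd of per-case log lump_density offset

# Feature-path scales.  Between-case variation is dominated by one shared
# "parenchymal pattern" factor on which every feature loads (real texture
# banks behave this way: a density-like first component dwarfs the rest),
# plus small per-feature offsets and low-rank correlated visit noise.
PER_DIM_OFFSET_SD = 0.25      # sd of per-feature case offsets (beyond the factor)
AR_RHO = 0.9                  # visit-to-visit noise autocorrelation
AR_SD = 0.1                   # stationary sd of the AR(1) visit noise
AR_RANK = 3                   # rank of the shared visit-noise loadings
SENSITIVITY_RANGE = (0.5, 1.5)  # per-feature drift/factor sensitivity
IMAGE_MAX = 4095.0            # 12-bit intensity range


@dataclass
class CohortSpec:
    """Generator settings; defaults mirror the target study's structure."""

    n_cases: int = 99
    prevalence: float = 49 / 99
    seq_len_range: tuple[int, int] = (2, 9)
    interval_mean_years: float = 1.27
    interval_sd_years: float = 0.3
    interval_min_years: float = 0.5
    drift_per_year: float = 0.5
    field_effect: bool = True
    baseline_jitter: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        lo, hi = self.seq_len_range
        if lo > hi or lo < 1:
            raise ValueError("seq_len_range must be a valid (low, high) pair")
        if self.interval_mean_years <= 0 or self.interval_sd_years < 0:
            raise ValueError("interval parameters must be nonnegative (mean > 0)")
        if self.baseline_jitter < 0:
            raise ValueError("baseline_jitter must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class TextureParams:
    """Parameters of the parenchyma surrogate texture."""

    beta: float = 2.8            # spectral slope of the power-law field
    lump_density: float = 5e-4   # Gaussian blobs per pixel^2
    lump_amplitude: float = 200.0
    lump_radius_px: float = 12.0
    noise_sd: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 4.0:
            raise ValueError("beta must lie in [0, 4]")
        for name in ("lump_density", "lump_amplitude", "lump_radius_px", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if self.lump_radius_px <= 0:
            raise ValueError("lump_radius_px must be positive")


# ---------------------------------------------------------------------------
# Cohort structure
# ---------------------------------------------------------------------------

def _seq_len_probs(seq_len_range: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = seq_len_range
    support = np.arange(lo, hi + 1)
    inside = (SEQ_LEN_SUPPORT >= lo) & (SEQ_LEN_SUPPORT <= hi)
    if inside.any() and set(support) <= set(SEQ_LEN_SUPPORT[inside]):
        probs = SEQ_LEN_PROBS[inside]
    else:  # custom range outside the calibrated support: fall back to uniform
        probs = np.ones(len(support))
    return support, probs / probs.sum()


def _sample_intervals(n: int, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal inter-exam gaps (mean 1.27 y, floor 0.5 y by default)."""
    if spec.interval_sd_years == 0:
        return np.full(n, max(spec.interval_mean_years, spec.interval_min_years))
    a = (spec.interval_min_years - spec.interval_mean_years) / spec.interval_sd_years
    return sps.truncnorm.rvs(
        a, np.inf, loc=spec.interval_mean_years, scale=spec.interval_sd_years,
        size=n, random_state=rng,
    )


def _allocate_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact-count allocation: round(prevalence * n) malignant, shuffled."""
    n_pos = int(round(spec.prevalence * spec.n_cases))
    labels = np.array([1] * n_pos + [0] * (spec.n_cases - n_pos))
    rng.shuffle(labels)
    return labels


def _case_texture_params(
    spec: CohortSpec,
    label: int,
    affected: str,
    times: np.ndarray,
    rng: np.random.Generator,
) -> list[Exam]:
    """Per-exam left/right TextureParams with label-dependent drift."""
    base = TextureParams()
    beta0 = float(np.clip(
        base.beta + rng.normal(0.0, BETA_JITTER_SCALE * spec.baseline_jitter), 0.5, 4.0
    ))
    log_density0 = np.log(base.lump_density) + rng.normal(0.0, LUMP_JITTER_SD)
    exams = []
    for t in times:
        sides = {}
        for side in ("left", "right"):
            drifts = label == 1 and (side == affected or spec.field_effect)
            dt = float(t) if drifts else 0.0
            sides[side] = TextureParams(
                beta=float(np.clip(
                    beta0 + BETA_DRIFT_SCALE * spec.drift_per_year * dt, 0.5, 4.0
                )),
                lump_density=float(np.exp(
                    log_density0 + LUMP_DRIFT_SCALE * spec.drift_per_year * dt
                )),
                lump_amplitude=base.lump_amplitude,
                lump_radius_px=base.lump_radius_px,
                noise_sd=base.noise_sd,
            )
        exams.append(Exam(date_years=float(t), left=sides["left"], right=sides["right"]))
    return exams


def sample_cohort(spec: CohortSpec) -> list[Case]:
    """Draw a cohort of cases whose exam payloads are TextureParams.

    Deterministic given ``spec.seed``.  Future-malignant cases drift in beta
    and lump density by ``drift_per_year x elapsed years`` in the affected
    breast, and in the contralateral breast iff ``field_effect``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _allocate_labels(spec, rng)
    support, probs = _seq_len_probs(spec.seq_len_range)
    lengths = rng.choice(support, size=spec.n_cases, p=probs)
    cases = []
    for i in range(spec.n_cases):
        affected = "left" if rng.random() < 0.5 else "right"
        gaps = _sample_intervals(int(lengths[i]) - 1, spec, rng)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        label = "malignant" if labels[i] else "benign"
        exams = _case_texture_params(spec, int(labels[i]), affected, times, rng)
        cases.append(Case(f"case{i:04d}", label, affected, exams))
    return cases


# ---------------------------------------------------------------------------
# Texture rendering
# ---------------------------------------------------------------------------

def render_texture(
    params: TextureParams,
    size: tuple[int, int] = (512, 512),
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Render one parenchyma-surrogate patch.

    A Gaussian white-noise field is shaped in Fourier space to a radially
    averaged power spectrum proportional to ``f**-beta``, Poisson-placed
    Gaussian lumps and white read noise are added, and the result is min-max
    rescaled to the 12-bit range [0, 4095].  Deterministic given the RNG
    state.
    """
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)
    fx = np.fft.fftfreq(w)
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    amp = np.zeros_like(fr)
    nz = fr > 0
    amp[nz] = fr[nz] ** (-params.beta / 2.0)
    field = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    sd = field.std()
    if sd > 0:
        field = field / sd * 100.0  # nominal contrast before rescaling

    n_lumps = rng.poisson(params.lump_density * h * w)
    if n_lumps > 0 and params.lump_amplitude > 0:
        rows = rng.uniform(0, h, n_lumps)
        cols = rng.uniform(0, w, n_lumps)
        yy, xx = np.mgrid[0:h, 0:w]
        s2 = 2.0 * params.lump_radius_px**2
        for r0, c0 in zip(rows, cols):
            d2 = (yy - r0) ** 2 + (xx - c0) ** 2
            field += params.lump_amplitude * np.exp(-d2 / s2)

    if params.noise_sd > 0:
        field += rng.normal(0.0, params.noise_sd, (h, w))

    lo, hi = field.min(), field.max()
    if hi > lo:
        field = (field - lo) / (hi - lo) * IMAGE_MAX
    else:
        field = np.zeros_like(field)
    return field


def render_case(case: Case, size=(512, 512)) -> Case:
    """Replace TextureParams payloads with rendered patches (new Case).

    Rendering seeds are derived deterministically from the case id and exam
    index, so a cohort renders identically regardless of traversal order.
    """
    base = abs(hash(case.case_id)) % (2**31)
    exams = []
    for k, exam in enumerate(case.exams):
        rendered = {}
        for j, side in enumerate(("left", "right")):
            rng = np.random.default_rng((base + 1000 * k + j) % (2**31))
            rendered[side] = render_texture(exam.side(side), size=size, rng=rng)
        exams.append(Exam(exam.date_years, rendered["left"], rendered["right"]))
    return Case(case.case_id, case.label, case.affected_laterality, exams)


def write_cohort(spec: CohortSpec, outdir: str | Path, size=(512, 512)) -> Path:
    """Sample, render, and persist a cohort: 16-bit PNGs + manifest + spec JSON."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in sample_cohort(spec):
        rendered = render_case(case, size=size)
        for k, exam in enumerate(rendered.exams):
            for side in ("left", "right"):
                rel = f"images/{case.case_id}_e{k}_{side}.png"
                write_image_png16(outdir / rel, exam.side(side))
                rows.append({
                    "case_id": case.case_id,
                    "label": case.label,
                    "affected_laterality": case.affected_laterality,
                    "exam_index": k,
                    "exam_date": round(exam.date_years, 4),
                    "laterality": side,
                    "image_path": rel,
                })
    write_manifest(rows, outdir / "manifest.csv")
    (outdir / "cohort_spec.json").write_text(spec.to_json())
    return outdir / "manifest.csv"


# ---------------------------------------------------------------------------
# Feature-level fast path
# ---------------------------------------------------------------------------

def generate_feature_sequences(
    spec: CohortSpec, dim: int = 50, feature_seed: int | None = None
) -> list[Case]:
    """Cohort whose exam payloads are feature vectors (no image rendering).

    The model emulates the hypothesized field effect at the feature level.
    Each feature ``j`` has a fixed cohort-level sensitivity ``w_j`` (uniform
    in ``SENSITIVITY_RANGE``); the value of feature ``j`` of one breast at
    elapsed time ``t`` is

        x_j(t) = J * s * w_j  +  e_j  +  [G v_t]_j  +  delta * t * w_j * drifting

    where ``s ~ N(0,1)`` is the breast's shared parenchymal-pattern factor
    scaled by ``J = baseline_jitter``, ``e_j`` are small per-feature case
    offsets, ``v_t`` is a low-rank AR(1) visit-noise process, and
    ``delta = drift_per_year`` acts in future-malignant cases on the affected
    side (and the contralateral side iff ``field_effect``).

    Because the drift direction coincides with the shared factor's loading
    pattern and the factor's spread dwarfs the accumulated drift, no linear
    (or rank-based) read-out of a single timepoint separates the labels --
    the marginal at any one exam is label-uninformative by construction --
    while the within-case change over time separates them cleanly.

    Cohort *structure* (labels, lateralities, exam counts and dates) depends
    only on ``spec.seed``; the feature content additionally depends on
    ``feature_seed`` (default ``spec.seed + 1``), so several feature banks
    can be generated over one identical cohort.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(spec.seed)                # cohort structure
    rng_f = np.random.default_rng(
        spec.seed + 1 if feature_seed is None else feature_seed
    )
    w = rng_f.uniform(*SENSITIVITY_RANGE, dim)            # drift/factor loadings
    g = rng_f.normal(0.0, 1.0, (dim, AR_RANK))            # visit-noise loadings
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    labels = _allocate_labels(spec, rng)
    support, probs = _seq_len_probs(spec.seq_len_range)
    lengths = rng.choice(support, size=spec.n_cases, p=probs)
    cases = []
    for i in range(spec.n_cases):
        affected = "left" if rng.random() < 0.5 else "right"
        n_exams = int(lengths[i])
        gaps = _sample_intervals(n_exams - 1, spec, rng)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        label = int(labels[i])
        side_feats = {}
        for side in ("left", "right"):
            s = rng_f.normal()
            baseline = spec.baseline_jitter * s * w + rng_f.normal(0, PER_DIM_OFFSET_SD, dim)
            v = rng_f.normal(0.0, AR_SD, AR_RANK)
            x = np.empty((n_exams, dim))
            drifting = label == 1 and (side == affected or spec.field_effect)
            for t in range(n_exams):
                if t > 0:
                    v = AR_RHO * v + rng_f.normal(0.0, AR_SD * np.sqrt(1 - AR_RHO**2),
                                                  AR_RANK)
                x[t] = baseline + g @ v
                if drifting:
                    x[t] += spec.drift_per_year * times[t] * w
            side_feats[side] = x
        exams = [
            Exam(float(times[t]), side_feats["left"][t], side_feats["right"][t])
            for t in range(n_exams)
        ]
        cases.append(Case(
            f"case{i:04d}", "malignant" if label else "benign", affected, exams,
        ))
    return cases


def mean_interexam_interval(cases: list[Case]) -> float:
    """Mean of all consecutive exam-date differences across the cohort, in years."""
    gaps = []
    for case in cases:
        dates = [e.date_years for e in case.exams]
        gaps.extend(np.diff(dates))
    return float(np.mean(gaps))
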