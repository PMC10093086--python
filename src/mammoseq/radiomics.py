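"""Parenchymal texture radiomics: a fixed 50-feature bank on 512x512 ROIs.

The bank covers eight families, concatenated in a frozen registry order:

===========================  =====
box-counting fractal dim.      6
edge gradient (Sobel)          4
gray-level histogram          10
Fourier spectrum               2
NGTDM (Amadasun--King)         5
Minkowski (blanket) fract.     1
power-law spectral beta        8
GLCM (Haralick)               14
===========================  =====
Total                         50

Numerical conventions, applied everywhere: logarithms are base 2 with
``0*log(0) == 0``; denominators are guarded by ``EPS = 1e-12``; GLCMs use 16
gray levels, offset distance 1, the four axial/diagonal directions averaged,
symmetric, normalized to sum 1.  Gray-level quantization is linear min--max
binning of each ROI's own range, which makes every co-occurrence, NGTDM and
entropy feature invariant to additive intensity offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ROIPatch

EPS = 1e-12

N_GRAY_LEVELS = 16
GLCM_DISTANCE = 1
GLCM_ANGLES_DEG = (0, 45, 90, 135)

BOXCOUNT_SIZES = (2, 4, 8, 16, 32, 64, 128)
BLANKET_SCALES = tuple(range(1, 9))
PSD_MIN_ANNULUS = 3  # discard annuli closer than 3 samples to DC

CATEGORY_COUNTS = {
    "boxcount_fd": 6,
    "edge_gradient": 4,
    "histogram": 10,
    "fourier": 2,
    "ngtdm": 5,
    "minkowski_fd": 1,
    "powerlaw_beta": 8,
    "glcm": 14,
}

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)

FEATURE_REGISTRY: list[tuple[str, str]] = (
    [(f"bc_fd_{scale}_{mode}", "boxcount_fd")
     for mode in ("raw", "detrended") for scale in ("all", "fine", "coarse")]
    + [(f"edge_{s}", "edge_gradient") for s in ("mean", "sd", "skewness", "fraction")]
    + [(f"hist_{s}", "histogram")
       for s in ("mean", "sd", "skewness", "kurtosis", "median",
                 "p05", "p95", "entropy", "energy", "balance")]
    + [("fourier_rms", "fourier"), ("fourier_first_moment", "fourier")]
    + [(f"ngtdm_{s}", "ngtdm")
       for s in ("coarseness", "contrast", "busyness", "complexity", "strength")]
    + [("minkowski_fd", "minkowski_fd")]
    + [(f"beta_{w}_{band}", "powerlaw_beta")
       for w in ("hann", "none") for band in ("full", "low", "mid", "high")]
    + [(f"glcm_{s}", "glcm") for s in HARALICK_NAMES]
)

FEATURE_NAMES = tuple(name for name, _ in FEATURE_REGISTRY)
FEATURE_CATEGORIES = tuple(cat for _, cat in FEATURE_REGISTRY)
N_FEATURES = len(FEATURE_REGISTRY)
assert N_FEATURES == 50


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Ordered, named feature values with per-feature category tags."""

    values: np.ndarray
    names: tuple[str, ...]
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must be 1D and equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.categories:
            out[c] = out.get(c, 0) + 1
        return out


@dataclass
class GLCMMatrix:
    """Normalized gray-level co-occurrence matrix."""

    probs: np.ndarray
    n_levels: int
    distance_px: int = GLCM_DISTANCE
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n_levels, self.n_levels):
            raise ValueError("GLCM must be n_levels x n_levels")
        if np.any(self.probs < 0):
            raise ValueError("GLCM entries must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must sum to 1")


@dataclass
class RadialPSD:
    """Radially averaged 2D power spectrum (DC excluded)."""

    freq: np.ndarray  # cycles/pixel, ascending
    power: np.ndarray
    window: str = "hann"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq.shape != self.power.shape:
            raise ValueError("freq and power must have equal length")
        if np.any(self.freq <= 0):
            raise ValueError("freq must exclude DC and be positive")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be strictly ascending")


def _as_array(roi) -> np.ndarray:
    arr = roi.intensities if isinstance(roi, ROIPatch) else np.asarray(roi, dtype=float)
    return np.asarray(arr, dtype=float)


# ---------------------------------------------------------------------------
# Quantization and GLCM
# ---------------------------------------------------------------------------

def quantize(roi, n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Linear min--max binning of the ROI's own range into levels 0..L-1.

    The top bin is closed (the maximum maps to L-1); a constant ROI maps to
    level 0 everywhere.  Binning on the ROI's own range makes the result
    invariant to additive intensity shifts.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = _as_array(roi)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.int64)
    q = np.floor((arr - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(q, 0, n_levels - 1)


def compute_glcm(
    q: np.ndarray,
    distance_px: int = GLCM_DISTANCE,
    angles_deg: tuple[int, ...] = GLCM_ANGLES_DEG,
    symmetric: bool = True,
    n_levels: int | None = None,
) -> GLCMMatrix:
    """Co-occurrence counts accumulated over the given angles and normalized."""
    q = np.asarray(q)
    if q.size == 0:
        raise ValueError("empty grid")
    if not set(angles_deg) <= {0, 45, 90, 135}:
        raise ValueError("angles must be within {0, 45, 90, 135} degrees")
    from skimage.feature import graycomatrix

    L = int(n_levels if n_levels is not None else q.max() + 1)
    angles = [np.deg2rad(a) for a in angles_deg]
    counts = graycomatrix(
        q.astype(np.uint8), [distance_px], angles, levels=L,
        symmetric=symmetric, normed=False,
    ).astype(float)
    total = counts[:, :, 0, :].sum(axis=2)  # accumulate over angles
    probs = total / total.sum()
    return GLCMMatrix(probs, n_levels=L, distance_px=distance_px, symmetric=symmetric)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log(0) == 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick14(glcm: GLCMMatrix) -> np.ndarray:
    """The 14 Haralick statistics of a normalized GLCM, in registry order.

    Sum variance is taken about the sum average (the common reading of the
    original definition).  Degenerate marginals make correlation, IMC1 and
    the maximal correlation coefficient 0 by convention.
    """
    p = glcm.probs
    L = glcm.n_levels
    i = np.arange(L, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    np.add.at(psum, (I + J).astype(int), p)
    np.add.at(pdiff, np.abs(I - J).astype(int), p)
    ks = np.arange(2 * L - 1, dtype=float)
    kd = np.arange(L, dtype=float)

    energy = float((p**2).sum())
    contrast = float(((I - J) ** 2 * p).sum())
    if sigx > EPS and sigy > EPS:
        correlation = float(((I * J * p).sum() - mux * muy) / (sigx * sigy))
    else:
        correlation = 0.0
    variance = float(((I - mux) ** 2 * p).sum())
    idm = float((p / (1.0 + (I - J) ** 2)).sum())
    sum_average = float((ks * psum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    sum_entropy = float(-_xlog2(psum).sum())
    entropy = float(-_xlog2(p).sum())
    diff_mean = float((kd * pdiff).sum())
    difference_variance = float(((kd - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = float(-_xlog2(pdiff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    log_pxpy = np.where(pxpy > 0, np.log2(np.maximum(pxpy, EPS)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    if max(hx, hy) > EPS:
        imc1 = (entropy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    mcc = _max_correlation_coefficient(p, px, py)

    return np.array([
        energy, contrast, correlation, variance, idm,
        sum_average, sum_variance, sum_entropy, entropy,
        difference_variance, difference_entropy, imc1, imc2, mcc,
    ])


def _max_correlation_coefficient(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Haralick's Q matrix.

    Rows/columns with zero marginal probability are dropped; a Q smaller than
    2x2 (or a numerically failed eigendecomposition) returns 0.
    """
    keep = (px > EPS) & (py > EPS)
    if keep.sum() < 2:
        return 0.0
    sub = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    q = (sub / pxs[:, None]) @ (sub / pys[None, :]).T
    try:
        eig = np.linalg.eigvals(q)
    except np.linalg.LinAlgError:
        return 0.0
    eig = np.sort(np.real(eig))[::-1]
    second = max(0.0, float(eig[1]))
    return float(np.sqrt(second))


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm5(q: np.ndarray, neighborhood: int = 3) -> np.ndarray:
    """Amadasun--King NGTDM features: coarseness, contrast, busyness,
    complexity, strength.

    Only interior pixels (full neighborhoods) contribute.  ``s_i`` is the sum
    of absolute differences between level-``i`` pixels and their
    neighborhood mean (center excluded).  Coarseness of a perfectly uniform
    grid saturates at ``1/EPS``.
    """
    q = np.asarray(q, dtype=float)
    if neighborhood % 2 != 1 or neighborhood < 3:
        raise ValueError("neighborhood must be odd and >= 3")
    d = neighborhood // 2
    if min(q.shape) < neighborhood:
        raise ValueError("grid smaller than neighborhood")

    k2 = neighborhood * neighborhood
    window_sum = ndimage.uniform_filter(q, size=neighborhood, mode="constant") * k2
    a = (window_sum - q) / (k2 - 1)  # neighborhood mean, center excluded
    interior = (slice(d, q.shape[0] - d), slice(d, q.shape[1] - d))
    qi = q[interior].astype(int)
    diff = np.abs(q[interior] - a[interior])

    levels = int(q.max()) + 1
    n_i = np.bincount(qi.ravel(), minlength=levels).astype(float)
    s = np.bincount(qi.ravel(), weights=diff.ravel(), minlength=levels)
    n = qi.size
    p = n_i / n

    present = p > 0
    ng = int(present.sum())
    iv = np.arange(levels, dtype=float)

    ps = float((p * s).sum())
    coarseness = 1.0 / max(ps, EPS)

    if ng > 1:
        pi = p[present]
        ii = iv[present]
        dif2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dif2).sum() / (ng * (ng - 1)) * (s.sum() / n)
        )
        ipi = ii * pi
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / busy_den if busy_den > EPS else 0.0
        psum = pi[:, None] + pi[None, :]
        spart = (pi * s[present])[:, None] + (pi * s[present])[None, :]
        complexity = float((np.abs(ii[:, None] - ii[None, :]) * spart / (n * psum)).sum())
        strength = float((psum * dif2).sum()) / (EPS + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0

    return np.array([coarseness, contrast, busyness, complexity, strength])


# ---------------------------------------------------------------------------
# Histogram and edge-gradient families
# ---------------------------------------------------------------------------

def histogram10(roi, n_levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """First-order statistics of the intensity distribution.

    Order: mean, SD, skewness, excess kurtosis, median, p5, p95, gray-level
    entropy (on the quantized grid, bits), energy/uniformity, and histogram
    balance ``(p95 - median) / (median - p5)`` with an EPS guard.  Skewness
    and kurtosis of a constant ROI are defined as 0.
    """
    arr = _as_array(roi).ravel()
    mean = float(arr.mean())
    sd = float(arr.std())
    if sd > EPS:
        z = (arr - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
    else:
        skew = kurt = 0.0
    median = float(np.median(arr))
    p05 = float(np.percentile(arr, 5))
    p95 = float(np.percentile(arr, 95))
    q = quantize(arr.reshape(1, -1), n_levels)
    counts = np.bincount(q.ravel(), minlength=n_levels).astype(float)
    p = counts / counts.sum()
    entropy = float(-_xlog2(p).sum())
    energy = float((p**2).sum())
    lower = median - p05
    balance = (p95 - median) / lower if lower > EPS else 0.0
    return np.array([mean, sd, skew, kurt, median, p05, p95, entropy, energy, balance])


SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def edge_gradient4(roi) -> np.ndarray:
    """Sobel gradient-magnitude statistics: mean, SD, skewness, edge fraction.

    Edge fraction is the share of pixels whose gradient magnitude exceeds the
    Otsu threshold of the magnitude image (0 for a flat ROI).
    """
    arr = _as_array(roi)
    gx = ndimage.convolve(arr, SOBEL_X, mode="reflect")
    gy = ndimage.convolve(arr, SOBEL_X.T, mode="reflect")
    mag = np.hypot(gx, gy)
    mean = float(mag.mean())
    sd = float(mag.std())
    if sd > EPS:
        z = (mag - mean) / sd
        skew = float((z**3).mean())
    else:
        skew = 0.0
    if mag.max() - mag.min() > EPS:
        from skimage.filters import threshold_otsu

        frac = float((mag > threshold_otsu(mag)).mean())
    else:
        frac = 0.0
    return np.array([mean, sd, skew, frac])


# ---------------------------------------------------------------------------
# Spectral families
# ---------------------------------------------------------------------------

def radial_psd(roi, window: str = "hann") -> RadialPSD:
    """Radially averaged 2D power spectrum of a square ROI.

    The ROI is mean-subtracted, optionally Hann-windowed (separable), 2D-FFT
    transformed, and ``|F|^2 / N^2`` is azimuthally averaged into annuli one
    frequency sample wide.  With this normalization the total spectral power
    equals the windowed image's variance times ``N^2`` (Parseval).  DC is
    excluded; annuli run out to the Nyquist radius.
    """
    arr = _as_array(roi)
    n = arr.shape[0]
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("radial PSD requires a square ROI")
    x = arr - arr.mean()
    if window == "hann":
        w1 = np.hanning(n)
        x = x * np.outer(w1, w1)
        x = x - x.mean()
    elif window != "none":
        raise ValueError("window must be 'hann' or 'none'")
    f = np.fft.fft2(x)
    power = (np.abs(f) ** 2) / (n * n)

    fy = np.fft.fftfreq(n)
    fr = np.hypot(*np.meshgrid(fy, fy, indexing="ij"))
    r = np.rint(fr * n).astype(int)  # annulus index in frequency samples
    nmax = n // 2
    sel = (r >= 1) & (r <= nmax)
    sums = np.bincount(r[sel], weights=power[sel], minlength=nmax + 1)
    cnts = np.bincount(r[sel], minlength=nmax + 1)
    radial = sums[1:] / np.maximum(cnts[1:], 1)
    freq = np.arange(1, nmax + 1) / n
    return RadialPSD(freq, radial, window=window)


def _fit_band(psd: RadialPSD) -> np.ndarray:
    """Mask of annuli used for spectral fits (>= PSD_MIN_ANNULUS samples from DC)."""
    n_samples = np.rint(psd.freq / psd.freq[0]).astype(int)
    return n_samples >= PSD_MIN_ANNULUS


def fourier2(psd: RadialPSD) -> np.ndarray:
    """RMS spectral variation and first moment of the radial spectrum.

    ``R = sqrt(sum P(f))`` and ``M = sum f P(f) / sum P(f)`` over the fitted
    band; both are 0 for an all-zero spectrum.
    """
    band = _fit_band(psd)
    p = psd.power[band]
    f = psd.freq[band]
    total = float(p.sum())
    if total <= 0:
        return np.array([0.0, 0.0])
    rms = float(np.sqrt(total))
    moment = float((f * p).sum() / total)
    return np.array([rms, moment])


def fit_powerlaw_beta(psd: RadialPSD, band: str = "full") -> float:
    """beta = -slope of the least-squares line of log2 P vs log2 f.

    ``band`` selects the full usable range or its low/mid/high third, the
    thirds being equal sub-intervals of the log2-frequency range.
    """
    usable = _fit_band(psd) & (psd.power > 0)
    f = psd.freq[usable]
    p = psd.power[usable]
    if band != "full":
        lo, hi = np.log2(f[0]), np.log2(f[-1])
        edges = np.linspace(lo, hi, 4)
        idx = {"low": 0, "mid": 1, "high": 2}[band]
        lf = np.log2(f)
        sel = (lf >= edges[idx] - 1e-12) & (lf <= edges[idx + 1] + 1e-12)
        f, p = f[sel], p[sel]
    if len(f) < 8:
        raise ValueError(f"insufficient annuli ({len(f)}) in band {band!r}")
    slope = np.polyfit(np.log2(f), np.log2(p), 1)[0]
    return float(-slope)


def powerlaw8(roi) -> np.ndarray:
    """Eight power-law spectral slopes: {hann, none} x {full, low, mid, high}."""
    out = []
    for window in ("hann", "none"):
        psd = radial_psd(roi, window=window)
        for band in ("full", "low", "mid", "high"):
            out.append(fit_powerlaw_beta(psd, band))
    return np.array(out)


# ---------------------------------------------------------------------------
# Fractal families
# ---------------------------------------------------------------------------

def _box_counts(arr: np.ndarray, sizes=BOXCOUNT_SIZES) -> np.ndarray:
    """Differential box counts N(s) of the intensity surface.

    Intensity is rescaled so that the gray axis has the same extent as the
    image side; each s x s block contributes the number of s-high boxes
    spanned by its min and max.
    """
    n = arr.shape[0]
    lo, hi = arr.min(), arr.max()
    z = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo) * (n - 1)
    counts = []
    for s in sizes:
        m = n // s
        blocks = z[: m * s, : m * s].reshape(m, s, m, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        nz = np.floor(bmax / s) - np.floor(bmin / s) + 1
        counts.append(nz.sum())
    return np.asarray(counts, dtype=float)


def _fd_slope(sizes: np.ndarray, counts: np.ndarray) -> float:
    """Fractal dimension: slope of log N(s) vs log(1/s)."""
    return float(np.polyfit(np.log2(1.0 / sizes), np.log2(counts), 1)[0])


def boxcount6(roi, sizes=BOXCOUNT_SIZES) -> np.ndarray:
    """Differential box-counting dimensions of the intensity surface.

    Six values: fits over {all scales, fine half, coarse half} for the raw
    ROI and for a local-mean-subtracted (detrended) ROI.  A smooth surface
    gives values near 2; rougher surfaces approach 3.
    """
    arr = _as_array(roi)
    if min(arr.shape) < max(sizes):
        raise ValueError(f"ROI smaller than the largest box size {max(sizes)}")
    sizes = np.asarray(sizes, dtype=float)
    half = len(sizes) // 2
    out = []
    detrended = arr - ndimage.uniform_filter(arr, size=32, mode="reflect")
    for grid in (arr, detrended):
        counts = _box_counts(grid, sizes.astype(int))
        out.append(_fd_slope(sizes, counts))                      # all scales
        out.append(_fd_slope(sizes[: half + 1], counts[: half + 1]))  # fine
        out.append(_fd_slope(sizes[half:], counts[half:]))            # coarse
    return np.array(out)


def minkowski1(roi, scales=BLANKET_SCALES) -> float:
    """Blanket (morphological) fractal dimension of the intensity surface.

    Upper/lower blankets grow by unit dilation/erosion per scale; the surface
    area ``A(eps) = sum(u - l) / (2 eps)`` is fit as ``log A`` vs ``log eps``
    and FD = 2 - slope.  A constant ROI returns exactly 2.
    """
    arr = _as_array(roi)
    n = arr.shape[0]
    lo, hi = arr.min(), arr.max()
    z = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo) * (n - 1)
    cross = ndimage.generate_binary_structure(2, 1)
    u = z.copy()
    l = z.copy()
    areas = []
    for _ in scales:
        u = np.maximum(ndimage.grey_dilation(u, footprint=cross), u + 1.0)
        l = np.minimum(ndimage.grey_erosion(l, footprint=cross), l - 1.0)
        areas.append((u - l).sum())
    eps = np.asarray(scales, dtype=float)
    a = np.asarray(areas) / (2.0 * eps)
    slope = np.polyfit(np.log2(eps), np.log2(a), 1)[0]
    return float(2.0 - slope)


# ---------------------------------------------------------------------------
# Full bank
# ---------------------------------------------------------------------------

def extract_radiomics(roi) -> FeatureVector:
    """Compute the full 50-feature bank on a 512x512 ROI, in registry order."""
    arr = _as_array(roi)
    if arr.shape != (512, 512):
        raise ValueError(f"expected a 512x512 ROI, got {arr.shape}")
    q = quantize(arr)
    values = np.concatenate([
        boxcount6(arr),
        edge_gradient4(arr),
        histogram10(arr),
        fourier2(radial_psd(arr, window="hann")),
        ngtdm5(q.astype(float)),
        [minkowski1(arr)],
        powerlaw8(arr),
        haralick14(compute_glcm(q, n_levels=N_GRAY_LEVELS)),
    ])
    return FeatureVector(values, FEATURE_NAMES, FEATURE_CATEGORIES)


def registry_json() -> list[dict]:
    """The frozen feature registry as serializable records."""
    return [
        {"index": i, "name": name, "category": cat}
        for i, (name, cat) in enumerate(FEATURE_REGISTRY)
    ]
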