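"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plain, slow, loop-based reference code that
shares no helper with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Haralick statistics from a normalized co-occurrence matrix (loops, log2)
# ---------------------------------------------------------------------------

def haralick14_bruteforce(p: np.ndarray) -> np.ndarray:
    L = p.shape[0]
    px = [sum(p[i][j] for j in range(L)) for i in range(L)]
    py = [sum(p[i][j] for i in range(L)) for j in range(L)]
    mux = sum(i * px[i] for i in range(L))
    muy = sum(j * py[j] for j in range(L))
    sigx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(L)))
    sigy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(L)))

    def xlog2(v):
        return v * math.log2(v) if v > 0 else 0.0

    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    energy = sum(p[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(L) for j in range(L))
    if sigx > 1e-12 and sigy > 1e-12:
        corr = (sum(i * j * p[i][j] for i in range(L) for j in range(L))
                - mux * muy) / (sigx * sigy)
    else:
        corr = 0.0
    variance = sum((i - mux) ** 2 * p[i][j] for i in range(L) for j in range(L))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    sum_avg = sum(k * psum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(2 * L - 1))
    sum_ent = -sum(xlog2(v) for v in psum)
    entropy = -sum(xlog2(p[i][j]) for i in range(L) for j in range(L))
    dmean = sum(k * pdiff[k] for k in range(L))
    diff_var = sum((k - dmean) ** 2 * pdiff[k] for k in range(L))
    diff_ent = -sum(xlog2(v) for v in pdiff)

    hx = -sum(xlog2(v) for v in px)
    hy = -sum(xlog2(v) for v in py)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(L) for j in range(L) if px[i] * py[j] > 0
    )
    hxy2 = -sum(xlog2(px[i] * py[j]) for i in range(L) for j in range(L))
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    keep = [i for i in range(L) if px[i] > 1e-12 and py[i] > 1e-12]
    if len(keep) >= 2:
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k])
                    for k in keep
                )
        eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        mcc = math.sqrt(max(0.0, eig[1]))
    else:
        mcc = 0.0

    return np.array([energy, contrast, corr, variance, idm, sum_avg, sum_var,
                     sum_ent, entropy, diff_var, diff_ent, imc1, imc2, mcc])


# ---------------------------------------------------------------------------
# NGTDM by direct per-pixel neighborhood loops
# ---------------------------------------------------------------------------

def ngtdm5_bruteforce(q: np.ndarray, neighborhood: int = 3) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    d = neighborhood // 2
    h, w = q.shape
    levels = int(q.max()) + 1
    s = [0.0] * levels
    n_i = [0] * levels
    for r in range(d, h - d):
        for c in range(d, w - d):
            acc, cnt = 0.0, 0
            for dr in range(-d, d + 1):
                for dc in range(-d, d + 1):
                    if dr == 0 and dc == 0:
                        continue
                    acc += q[r + dr, c + dc]
                    cnt += 1
            lvl = int(q[r, c])
            s[lvl] += abs(q[r, c] - acc / cnt)
            n_i[lvl] += 1
    n = sum(n_i)
    p = [v / n for v in n_i]
    eps = 1e-12
    present = [i for i in range(levels) if p[i] > 0]
    ng = len(present)
    ps = sum(p[i] * s[i] for i in range(levels))
    coarseness = 1.0 / max(ps, eps)
    if ng > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ng * (ng - 1)) * (sum(s) / n)
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busyness = ps / busy_den if busy_den > eps else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (n * (p[i] + p[j]))
            for i in present for j in present
        )
        strength = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        ) / (eps + sum(s))
    else:
        contrast = busyness = complexity = strength = 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


# ---------------------------------------------------------------------------
# First-order statistics by direct formulas
# ---------------------------------------------------------------------------

def histogram10_bruteforce(arr: np.ndarray, n_levels: int = 16) -> np.ndarray:
    v = np.sort(np.asarray(arr, dtype=float).ravel())
    n = len(v)
    mean = float(sum(v) / n)
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / n)
    if sd > 1e-12:
        skew = sum(((x - mean) / sd) ** 3 for x in v) / n
        kurt = sum(((x - mean) / sd) ** 4 for x in v) / n - 3.0
    else:
        skew = kurt = 0.0
    median = float(np.percentile(v, 50))
    p05 = float(np.percentile(v, 5))
    p95 = float(np.percentile(v, 95))
    lo, hi = v[0], v[-1]
    if hi > lo:
        q = np.clip(np.floor((v - lo) / (hi - lo) * n_levels), 0, n_levels - 1)
    else:
        q = np.zeros(n)
    counts = [float((q == k).sum()) for k in range(n_levels)]
    probs = [c / n for c in counts]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    energy = sum(p * p for p in probs)
    balance = (p95 - median) / (median - p05) if (median - p05) > 1e-12 else 0.0
    return np.array([mean, sd, skew, kurt, median, p05, p95, entropy, energy, balance])


# ---------------------------------------------------------------------------
# AUC by exhaustive positive-negative pair counting
# ---------------------------------------------------------------------------

def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Spectral-synthesis fBm phantom (supersampled + decimated so lattice
# increments scale correctly) and periodogram slope regression
# ---------------------------------------------------------------------------

def fbm_surface(hurst: float, n: int, seed: int, oversample: int = 8) -> np.ndarray:
    big = n * oversample
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((big, big))
    f = np.fft.fftfreq(big)
    fr = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    amp = np.zeros_like(fr)
    nz = fr > 0
    amp[nz] = fr[nz] ** (-(2.0 * hurst + 2.0) / 2.0)
    z = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    return z[::oversample, ::oversample]


def periodogram_slope(img: np.ndarray, rmin: int = 3) -> float:
    """Independent log-log regression of the radially averaged periodogram."""
    x = img - img.mean()
    n = x.shape[0]
    power = np.abs(np.fft.fft2(x)) ** 2
    f = np.fft.fftfreq(n)
    r = np.rint(np.hypot(*np.meshgrid(f, f, indexing="ij")) * n).astype(int)
    lf, lp = [], []
    for k in range(rmin, n // 2 + 1):
        m = r == k
        if m.any():
            lf.append(math.log2(k / n))
            lp.append(math.log2(power[m].mean()))
    return float(-np.polyfit(lf, lp, 1)[0])
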