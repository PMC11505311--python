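"""Bispectral and nonlinear features of decomposed heartbeat modes.

Fifteen features per (beat, lead, mode): nine shape summaries of the
bispectral amplitude matrix (brightness, flatness, roll-off, two
normalized entropies, log-amplitude sums and diagonal moments), the peak
of a 16th-order Burg AR power spectral density, and five nonlinear
time-series measures (approximate, fuzzy, sample and permutation entropy,
plus Lempel-Ziv complexity).

All logarithms are natural; amplitudes inside logs are floored at
``LOG_EPS`` because the zero-padded triangle complement of the bispectral
quadrant contains exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bispectrum import BispectrumMatrix

LOG_EPS = 1e-12

FEATURE_NAMES = (
    "bispec_brightness",
    "bispec_flatness",
    "bispec_rolloff",
    "bispec_entropy",
    "bispec_sq_entropy",
    "sum_log_amp",
    "sum_log_diag",
    "diag_moment1",
    "diag_moment2",
    "psd_peak",
    "apen",
    "fuzzyen",
    "sampen",
    "permen",
    "lzc",
)


@dataclass
class FeatureVector:
    """Fifteen named feature values plus identifying keys."""

    values: dict[str, float]
    record_id: str = ""
    lead: str = ""
    beat_index: int = -1
    method: str = ""
    mode: int = -1
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# bispectral shape features


def bispectral_features(
    B: BispectrumMatrix, cutoff_hz: float = 120.0, beta: float = 0.95
) -> dict[str, float]:
    """Nine shape summaries of the bispectral amplitude matrix.

    brightness: fraction of total amplitude with both frequencies at or
    above the cutoff. flatness: geometric / arithmetic mean. roll-off: the
    largest frequency F (Hz) whose square region [0, F]^2 holds at most
    beta of the total amplitude. Entropies use amplitude (and squared
    amplitude) distributions over the whole quadrant. The diagonal moments
    are log-amplitude weighted sums over the main diagonal.
    """
    w = np.asarray(B.amplitudes, dtype=float)
    if cutoff_hz >= B.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {B.fs / 2}")
    total = w.sum()
    out: dict[str, float] = {}
    k = np.arange(w.shape[0])
    logw_diag = np.log(np.maximum(np.diag(w), LOG_EPS))
    out["sum_log_amp"] = float(np.log(np.maximum(w, LOG_EPS)).sum())
    out["sum_log_diag"] = float(logw_diag.sum())
    m1 = float((k * logw_diag).sum())
    out["diag_moment1"] = m1
    out["diag_moment2"] = float(((k - m1) ** 2 * logw_diag).sum())

    if total <= 0:  # degenerate all-zero matrix
        out.update(
            bispec_brightness=0.0,
            bispec_flatness=0.0,
            bispec_rolloff=0.0,
            bispec_entropy=0.0,
            bispec_sq_entropy=0.0,
        )
        return out

    fcut = B.freq_to_bin(cutoff_hz)
    out["bispec_brightness"] = float(w[fcut:, fcut:].sum() / total)

    geo = math.exp(float(np.mean(np.log(np.maximum(w, LOG_EPS)))))
    out["bispec_flatness"] = float(geo / np.mean(w))

    # cumulative sum over growing square regions [0, F] x [0, F]
    csq = w.cumsum(axis=0).cumsum(axis=1)
    square = np.diag(csq)
    below = np.nonzero(square <= beta * total)[0]
    out["bispec_rolloff"] = float(B.bin_to_freq(int(below[-1]))) if len(below) else 0.0

    p = w / total
    nz = p[p > 0]
    out["bispec_entropy"] = float(-(nz * np.log(nz)).sum())
    q = w**2 / (w**2).sum()
    nz = q[q > 0]
    out["bispec_sq_entropy"] = float(-(nz * np.log(nz)).sum())
    return out


# ---------------------------------------------------------------------------
# AR power spectral density peak


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR coefficients and residual variance by the Burg lattice recursion.

    Returns ``(rho, sigma2)`` with the convention
    x_t = sum_i rho_i x_{t-i} + e_t. The residual variance follows the
    textbook update sigma2_m = sigma2_{m-1} (1 - k_m^2) from
    sigma2_0 = mean(x^2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= order:
        raise ValueError(f"need more than {order} samples, got {n}")
    f = x.copy()
    b = x.copy()
    a = np.zeros(order + 1)
    a[0] = 1.0
    e = float(x @ x) / n
    for m in range(1, order + 1):
        fm = f[m:].copy()
        bm = b[m - 1 : n - 1].copy()
        denom = fm @ fm + bm @ bm
        if denom == 0:
            break
        k = -2.0 * float(fm @ bm) / float(denom)
        ext = np.append(a[:m], 0.0)
        a[: m + 1] = ext + k * ext[::-1]
        f[m:] = fm + k * bm
        b[m:] = bm + k * fm
        e *= 1.0 - k * k
    return -a[1:], e


def psd_peak_burg(
    x: np.ndarray, fs: float = 1000.0, order: int = 16, n_grid: int = 512
) -> tuple[float, float]:
    """Peak of the AR(order) Burg power spectral density.

    Returns ``(peak_value, peak_frequency_hz)`` on an ``n_grid``-point
    frequency grid spanning [0, fs/2].
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= order:
        raise ValueError(f"need more than {order} samples, got {len(x)}")
    if np.ptp(x) == 0:
        return 0.0, 0.0
    rho, sigma2 = burg_ar(x - x.mean(), order)
    # a near-perfect AR fit (e.g. a noiseless sinusoid) can drive the
    # residual variance to (numerically below) zero
    sigma2 = max(abs(float(sigma2)), np.finfo(float).tiny)
    freqs = np.linspace(0, fs / 2, n_grid)
    z = np.exp(-2j * np.pi * freqs[None, :] / fs * np.arange(1, order + 1)[:, None])
    denom = np.abs(1.0 - rho @ z) ** 2
    psd = sigma2 / denom
    i = int(np.argmax(psd))
    return float(psd[i]), float(freqs[i])


# ---------------------------------------------------------------------------
# nonlinear time-series features


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _chebyshev_matrix(templates: np.ndarray) -> np.ndarray:
    d = np.zeros((len(templates), len(templates)))
    for col in range(templates.shape[1]):
        np.maximum(d, np.abs(templates[:, col, None] - templates[None, :, col]), out=d)
    return d


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn = Phi^m(r) - Phi^(m+1)(r), self-matches included."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        d = _chebyshev_matrix(t)
        c = (d <= r).sum(axis=1) / len(t)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn = -ln(A/B), self-matches excluded, Chebyshev distance.

    Both template sets use the first N - m windows so every length-m
    template has a matching length-(m+1) continuation. Returns 0 (flagged
    degenerate upstream) when no matches exist at either length.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if r <= 0:
        return 0.0
    n_t = len(x) - m
    tm = _embed(x, m)[:n_t]
    tm1 = _embed(x, m + 1)
    dm = _chebyshev_matrix(tm)
    dm1 = _chebyshev_matrix(tm1)
    np.fill_diagonal(dm, np.inf)
    np.fill_diagonal(dm1, np.inf)
    b = float((dm <= r).sum())
    a = float((dm1 <= r).sum())
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def fuzzy_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None, n: float = 2.0
) -> float:
    """FuzzyEn with exponential membership exp(-(d/r)^n) on mean-removed
    templates; both template sets use the first N - m windows."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        t = _embed(x, mm)[: len(x) - m]
        t = t - t.mean(axis=1, keepdims=True)
        d = _chebyshev_matrix(t)
        sim = np.exp(-((d / r) ** n))
        np.fill_diagonal(sim, 0.0)
        return float(sim.sum() / (len(t) * (len(t) - 1)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return 0.0
    return float(np.log(p_m) - np.log(p_m1))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns.

    Shannon entropy of the ordinal-pattern distribution (ties broken by
    index order via stable argsort), normalized by ln(order!). A constant
    signal has a single pattern and entropy 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x) - (order - 1) * delay
    if n < 1:
        raise ValueError("signal too short for the requested order/delay")
    windows = np.stack([x[i * delay : i * delay + n] for i in range(order)], axis=1)
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(order))


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases in the exhaustive LZ76 parsing of a binary string.

    A phrase is counted when it first becomes irreproducible from the
    history (including overlap); a trailing phrase still reproducible when
    the string ends is not counted, so a constant string has count 1.
    """
    s = np.asarray(bits, dtype=np.uint8).tobytes()
    n = len(s)
    c = 0
    i = 0
    while i < n:
        l = 1
        while i + l <= n and s[i : i + l] in s[: i + l - 1]:
            l += 1
        if i + l <= n:
            c += 1
            i += l
        else:
            break
    return c


def lempel_ziv(x: np.ndarray) -> tuple[float, int]:
    """Normalized Lempel-Ziv (LZ76) complexity of the median-binarized signal.

    Values at or above the median map to 1; the binary string is parsed by
    :func:`lz76_phrase_count`. Returns ``(c * log2(n) / n, c)``, with the
    normalization chosen so random strings score near 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    c = lz76_phrase_count(x >= np.median(x))
    return c * math.log2(n) / n, c


def entropy_features(
    x: np.ndarray,
    m: int = 2,
    r: float | None = None,
    fuzzy_n: float = 2.0,
    perm_order: int = 3,
    perm_delay: int = 1,
) -> dict[str, float]:
    """ApEn, FuzzyEn, SampEn and PermEn with shared (m, r) parameters."""
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError(f"need at least {10 * m} samples, got {len(x)}")
    if r is None:
        r = 0.2 * np.std(x)
    if np.ptp(x) == 0:
        return {"apen": 0.0, "fuzzyen": 0.0, "sampen": 0.0, "permen": 0.0}
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    return {
        "apen": approximate_entropy(x, m, r),
        "fuzzyen": fuzzy_entropy(x, m, r, fuzzy_n),
        "sampen": sample_entropy(x, m, r),
        "permen": permutation_entropy(x, perm_order, perm_delay),
    }


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureConfig:
    nfft: int = 1024
    cutoff_hz: float = 120.0
    beta: float = 0.95
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    ar_order: int = 16
    psd_grid: int = 512
    n_modes: int = 5


def extract_all(
    beat,
    modeset,
    config: FeatureConfig = FeatureConfig(),
    fs: float = 1000.0,
    bispectra: list[BispectrumMatrix] | None = None,
) -> list[FeatureVector]:
    """Feature vectors for the first ``config.n_modes`` modes of one beat.

    Nonlinear features are computed on each mode's time series, bispectral
    features on that mode's bispectrum (supplied via ``bispectra`` or
    estimated here). Modes the decomposition did not produce are skipped.
    """
    from .bispectrum import bispectrum_direct

    out = []
    n_use = min(config.n_modes, modeset.n_modes)
    for k in range(n_use):
        mode = modeset.modes[k]
        degenerate = bool(np.ptp(mode) == 0)
        B = (
            bispectra[k]
            if bispectra is not None
            else bispectrum_direct(mode, nfft=config.nfft, fs=fs)
        )
        vals = bispectral_features(B, cutoff_hz=config.cutoff_hz, beta=config.beta)
        if degenerate:
            vals.update(psd_peak=0.0, apen=0.0, fuzzyen=0.0, sampen=0.0, permen=0.0)
            lz_norm = 0.0
        else:
            vals["psd_peak"] = psd_peak_burg(
                mode, fs=fs, order=config.ar_order, n_grid=config.psd_grid
            )[0]
            vals.update(
                entropy_features(
                    mode,
                    m=config.entropy_m,
                    r=config.entropy_r_factor * float(np.std(mode)),
                )
            )
            lz_norm, _ = lempel_ziv(mode)
        vals["lzc"] = lz_norm
        out.append(
            FeatureVector(
                values={k2: vals[k2] for k2 in FEATURE_NAMES},
                record_id=getattr(beat, "record_id", ""),
                lead=getattr(beat, "lead", ""),
                method=modeset.method,
                mode=k + 1,
                degenerate=degenerate,
            )
        )
    return out
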