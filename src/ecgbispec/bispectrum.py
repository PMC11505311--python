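"""Third-order cumulants and direct bispectrum estimation.

The bispectrum B(f1, f2) is the 2-D Fourier transform of the third-order
cumulant; its amplitude peaks where three spectral components at f1, f2 and
f1+f2 have phases that sum coherently (quadratic phase coupling), making it
the canonical detector of that structure and of non-Gaussianity.

The estimator here is the direct (periodogram-like) one on a single
segment: mean removal, Hann taper, zero-padding to nfft, and
B(i, j) = X(i) X(j) conj(X(i+j)) / nfft on the quadrant i, j <= nfft/2,
zeroed outside the triangle i + j <= nfft/2 where the product is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann


def third_order_cumulant(x: np.ndarray, tau1: int, tau2: int) -> float:
    """Biased third-order cumulant estimate at lags (tau1, tau2).

    Mean over valid n of x~(n) x~(n+tau1) x~(n+tau2) with x~ mean-removed,
    normalized by the full signal length (biased estimator).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = len(x)
    if abs(tau1) >= n or abs(tau2) >= n:
        raise ValueError(f"lags ({tau1}, {tau2}) out of range for length {n}")
    xc = x - x.mean()
    lo = max(0, -tau1, -tau2)
    hi = min(n, n - tau1, n - tau2)
    if hi <= lo:
        return 0.0
    idx = np.arange(lo, hi)
    return float(np.sum(xc[idx] * xc[idx + tau1] * xc[idx + tau2]) / n)


@dataclass
class BispectrumMatrix:
    """Bispectrum estimate B(f1, f2) on the discrete quadrant grid.

    ``values[i, j]`` (complex) covers grid indices 0..nfft/2 on both axes;
    ``amplitudes`` is its magnitude. Frequency resolution is fs/nfft Hz per
    bin. Entries outside the triangle i + j <= nfft/2 are zero. Detecting
    quadratic phase coupling against phase-randomized alternatives requires
    averaging the complex values over an ensemble (see
    :func:`average_bispectrum` with ``mode="complex"``): per-realization
    amplitudes are blind to phase coherence.
    """

    values: np.ndarray
    nfft: int
    fs: float

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def freq_resolution(self) -> float:
        return self.fs / self.nfft

    def freq_to_bin(self, f_hz: float) -> int:
        return int(round(f_hz / self.freq_resolution))

    def bin_to_freq(self, i: int) -> float:
        return i * self.freq_resolution

    def peak_location_hz(self) -> tuple[float, float]:
        """Frequencies (f1, f2) of the global amplitude maximum."""
        i, j = np.unravel_index(np.argmax(self.amplitudes), self.amplitudes.shape)
        return self.bin_to_freq(int(i)), self.bin_to_freq(int(j))


def bispectrum_direct(
    x: np.ndarray, nfft: int = 1024, fs: float = 1000.0
) -> BispectrumMatrix:
    """Direct single-segment bispectrum estimate of a signal.

    The signal is mean-removed, Hann-tapered and zero-padded to ``nfft``;
    B(i, j) = X(i) X(j) conj(X(i+j)) / nfft for i, j, i+j all <= nfft/2.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = len(x)
    if nfft < n:
        raise ValueError(f"nfft ({nfft}) must be >= signal length ({n})")
    xt = (x - x.mean()) * hann(n, sym=False)
    X = np.fft.fft(xt, nfft)
    half = nfft // 2
    idx = np.arange(half + 1)
    # X(i) X(j) on the quadrant; conj(X(i+j)) only where i+j <= nfft/2
    outer = X[idx][:, None] * X[idx][None, :]
    ij = idx[:, None] + idx[None, :]
    valid = ij <= half
    B = np.zeros((half + 1, half + 1), dtype=complex)
    B[valid] = outer[valid] * np.conj(X[ij[valid]]) / nfft
    return BispectrumMatrix(values=B, nfft=nfft, fs=fs)


def average_bispectrum(
    matrices: list[BispectrumMatrix], labels: list[str], mode: str = "amplitude"
) -> dict[str, BispectrumMatrix]:
    """Element-wise mean bispectrum per group label.

    ``mode="amplitude"`` (default) averages magnitudes, as for group-level
    amplitude comparison of beats; ``mode="complex"`` averages the complex
    values, which cancels incoherent phases and is the estimator that
    detects quadratic phase coupling across an ensemble.
    """
    if mode not in ("amplitude", "complex"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    if len(matrices) != len(labels):
        raise ValueError("one label per matrix required")
    if not matrices:
        raise ValueError("no matrices supplied")
    nffts = {m.nfft for m in matrices}
    if len(nffts) != 1:
        raise ValueError(f"matrices mix nfft values: {sorted(nffts)}")
    out: dict[str, BispectrumMatrix] = {}
    for group in dict.fromkeys(labels):
        if mode == "complex":
            members = [m.values for m, l in zip(matrices, labels) if l == group]
        else:
            members = [m.amplitudes for m, l in zip(matrices, labels) if l == group]
        out[group] = BispectrumMatrix(
            values=np.mean(members, axis=0).astype(complex),
            nfft=matrices[0].nfft,
            fs=matrices[0].fs,
        )
    return out
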