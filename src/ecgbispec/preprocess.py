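"""ECG denoising, R-peak detection and fixed-length beat segmentation.

Pipeline order: 50 Hz notch -> two-stage median baseline removal -> wavelet
threshold denoising -> Pan-Tompkins R-peak detection -> 601-sample beat
cutting (300 samples either side of the R peak; the first and last detected
beats are always discarded). Every stage before segmentation preserves
signal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, signal

from .ecg_io import EcgRecord

#: samples kept either side of the R peak; beats are PRE + POST + 1 long
PRE_SAMPLES = 300
POST_SAMPLES = 300
BEAT_LENGTH = PRE_SAMPLES + POST_SAMPLES + 1


@dataclass
class Beat:
    """A single-lead heartbeat segment of exactly 601 samples.

    The R peak sits at position 300 (0-based) of ``samples``;
    ``r_peak_index`` is its position in the source record.
    """

    record_id: str
    lead: str
    r_peak_index: int
    samples: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != BEAT_LENGTH:
            raise ValueError(
                f"beat must have {BEAT_LENGTH} samples, got {len(self.samples)}"
            )


def notch_filter(
    x: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase second-order IIR notch at f0 Hz (quality factor q)."""
    if not 0 < f0 < fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, {fs / 2}) Hz")
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def _odd_window(fs: float, seconds: float) -> int:
    w = int(round(seconds * fs))
    return w + 1 if w % 2 == 0 else w


def remove_baseline_median(x: np.ndarray, fs: float) -> np.ndarray:
    """Subtract the two-stage median-filter baseline estimate.

    The baseline is a 200 ms median filter followed by a 600 ms median
    filter — the first removes QRS complexes, the second P/T waves — so the
    remainder tracks only the slow wander.
    """
    x = np.asarray(x, dtype=float)
    w1 = _odd_window(fs, 0.200)
    w2 = _odd_window(fs, 0.600)
    if len(x) < w2:
        raise ValueError(f"signal length {len(x)} shorter than {w2}-sample window")
    baseline = ndimage.median_filter(x, size=w1, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=w2, mode="nearest")
    return x - baseline


def wavelet_denoise(x: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Soft-threshold wavelet denoising with the universal threshold.

    Noise scale sigma is estimated from the finest-level detail
    coefficients as MAD/0.6745; every detail level is soft-thresholded at
    sigma * sqrt(2 ln n).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        return x.copy()
    level = min(
        8,
        int(np.floor(np.log2(n))) - 2,
        pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len),
    )
    coeffs = pywt.wavedec(x, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    if thresh == 0:  # noise-free (e.g. all-zero) signal
        return x.copy()
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    return pywt.waverec(denoised, wavelet)[:n]


def detect_r_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection.

    Classic stages: 5-15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds with search-back
    and a 200 ms refractory period. Detections are refined to the local
    maximum of the band-passed signal within +/-50 ms.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < int(0.5 * fs):
        return np.array([], dtype=int)

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate peaks of the integrated waveform
    cand, _ = signal.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    spki = float(np.max(integ[: int(2 * fs)])) * 0.5 if len(integ) else 0.0
    npki = float(np.mean(integ[: int(2 * fs)])) * 0.5
    peaks: list[int] = []
    missed: list[int] = []
    rr_history: list[int] = []
    for c in cand:
        threshold = npki + 0.25 * (spki - npki)
        if integ[c] > threshold:
            if peaks and c - peaks[-1] < refractory:
                continue
            peaks.append(int(c))
            spki = 0.125 * integ[c] + 0.875 * spki
            if len(peaks) >= 2:
                rr_history.append(peaks[-1] - peaks[-2])
                rr_history = rr_history[-8:]
        else:
            missed.append(int(c))
            npki = 0.125 * integ[c] + 0.875 * npki
        # search-back: if no peak for 1.66x the running RR average, take the
        # best sub-threshold candidate in the gap at half threshold
        if rr_history and missed:
            rr_avg = float(np.mean(rr_history))
            if c - peaks[-1] > 1.66 * rr_avg:
                gap = [m for m in missed if peaks[-1] < m < c]
                if gap:
                    best = max(gap, key=lambda m: integ[m])
                    if integ[best] > npki + 0.125 * (spki - npki):
                        peaks.append(best)
                        peaks.sort()
                        spki = 0.25 * integ[best] + 0.75 * spki
                        missed = [m for m in missed if m > best]

    # refine each detection to the local max of the band-passed signal
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # de-duplicate refinements that collapsed within the refractory period
    if len(refined) > 1:
        keep = [refined[0]]
        for p in refined[1:]:
            if p - keep[-1] >= refractory:
                keep.append(p)
            elif bp[p] > bp[keep[-1]]:
                keep[-1] = p
        refined = np.asarray(keep, dtype=int)
    return refined


def segment_beats(
    x: np.ndarray,
    r_peaks: np.ndarray,
    *,
    record_id: str = "",
    lead: str = "",
    label: str = "",
) -> list[Beat]:
    """Cut 601-sample beats around interior R peaks.

    The first and last detected peaks are always dropped, as is any peak
    whose window would run off either end of the record. Fewer than three
    peaks therefore yield no beats.
    """
    x = np.asarray(x, dtype=float)
    r_peaks = np.sort(np.asarray(r_peaks, dtype=int))
    if len(r_peaks) < 3:
        return []
    beats = []
    for r in r_peaks[1:-1]:
        lo, hi = r - PRE_SAMPLES, r + POST_SAMPLES + 1
        if lo < 0 or hi > len(x):
            continue
        beats.append(
            Beat(
                record_id=record_id,
                lead=lead,
                r_peak_index=int(r),
                samples=x[lo:hi].copy(),
                label=label,
            )
        )
    return beats


def denoise(x: np.ndarray, fs: float, notch_hz: float = 50.0) -> np.ndarray:
    """Full denoising chain: notch -> median baseline -> wavelet."""
    y = notch_filter(x, fs, f0=notch_hz)
    y = remove_baseline_median(y, fs)
    return wavelet_denoise(y)


def extract_beats(
    record: EcgRecord,
    leads: list[str] | None = None,
    detection_lead: str = "II",
) -> dict[str, list[Beat]]:
    """Denoise a record, detect R peaks on one lead, cut beats on many.

    Detection runs on ``detection_lead`` (default II); the same peak indices
    then segment every requested lead, so beats are aligned across leads.
    """
    leads = list(record.lead_names) if leads is None else leads
    det = denoise(record.lead(detection_lead), record.fs)
    peaks = detect_r_peaks(det, record.fs)
    out: dict[str, list[Beat]] = {}
    for name in leads:
        clean = det if name == detection_lead else denoise(record.lead(name), record.fs)
        out[name] = segment_beats(
            clean,
            peaks,
            record_id=record.record_id,
            lead=name,
            label=record.label,
        )
    return out
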