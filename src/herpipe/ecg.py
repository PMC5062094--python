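"""ECG R-peak detection by QRS template matching, with IBI quality control.

Detection correlates the z-scored ECG with a QRS template (sliding
Pearson correlation) and places one peak per supra-threshold episode, at
the local maximum of the raw ECG within that episode.  The template is
either supplied or built automatically from the recording itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import AnalysisError, ValidationError


@dataclass
class QrsTemplate:
    """A QRS complex waveform, centred on the R deflection."""

    waveform: np.ndarray
    sample_rate: float
    origin: str = "auto"  # "auto" | "provided"

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        ms = 1000.0 * len(self.waveform) / self.sample_rate
        if not 40.0 <= ms <= 200.0:
            raise ValidationError(
                f"template length {ms:.0f} ms outside the 40-200 ms range"
            )


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak times with per-interval QC flags."""

    times: np.ndarray
    qc_flags: np.ndarray | None = None  # per-interval, set by qc_ibi

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("R-peak times must be strictly increasing")

    @property
    def ibi(self) -> np.ndarray:
        """Interbeat intervals in seconds (length n-1)."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return self.times.size


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise AnalysisError("no QRS-like activity: signal is flat")
    return (x - x.mean()) / sd


def sliding_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``template`` with every window of ``x``.

    Returns an array of length ``len(x) - len(template) + 1``; entry i is
    the correlation with x[i : i+m].  Zero-variance windows map to 0.
    """
    m = len(template)
    t = template - template.mean()
    t_norm = np.sqrt((t**2).sum())
    if t_norm == 0:
        raise ValidationError("template has zero variance")
    dot = scipy.signal.fftconvolve(x, t[::-1], mode="valid")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x**2)))
    wsum = csum[m:] - csum[:-m]
    wsum2 = csum2[m:] - csum2[:-m]
    wvar = wsum2 - wsum**2 / m
    wvar = np.maximum(wvar, 0.0)
    denom = np.sqrt(wvar) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, dot / denom, 0.0)
    return np.clip(corr, -1.0, 1.0)


def _provisional_peaks(z: np.ndarray, sample_rate: float) -> np.ndarray:
    """Robust amplitude heuristic for a first pass at R locations."""
    height = max(3.0, 0.5 * z.max())
    peaks, _ = scipy.signal.find_peaks(
        z, height=height, distance=int(0.3 * sample_rate)
    )
    if len(peaks) < 5:
        peaks, _ = scipy.signal.find_peaks(
            z, height=np.quantile(z, 0.999), distance=int(0.3 * sample_rate)
        )
    return peaks


def _average_around(x: np.ndarray, centers: np.ndarray, n: int) -> np.ndarray:
    half = n // 2
    segs = [
        x[c - half : c - half + n]
        for c in centers
        if c - half >= 0 and c - half + n <= len(x)
    ]
    if not segs:
        raise AnalysisError("no QRS-like activity: no usable template segments")
    return np.mean(segs, axis=0)


def build_template(
    ecg: np.ndarray,
    sample_rate: float,
    length_ms: float = 120.0,
    seed: int | None = None,  # kept for interface symmetry; construction is deterministic
) -> QrsTemplate:
    """Build a patient-specific QRS template from the recording.

    Provisional peaks are found with a robust amplitude heuristic, the
    signal is averaged +/- length_ms/2 around them, and the procedure is
    iterated once using template-based detection for refinement.  The
    result is centred on the R deflection and unit-normalized (peak 1).
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 30 * sample_rate:
        raise AnalysisError("need at least 30 s of ECG to build a template")
    z = _zscore(ecg)
    n = int(round(length_ms * sample_rate / 1000.0))
    peaks = _provisional_peaks(z, sample_rate)
    if len(peaks) == 0:
        raise AnalysisError("no QRS-like activity: no provisional peaks found")
    wave = _average_around(z, peaks, n)

    # one refinement pass: detect with the provisional template, re-average
    tpl = _center_and_normalize(wave, n // 2)
    series = detect_r_peaks(ecg, QrsTemplate(tpl, sample_rate, "auto"), threshold=0.7)
    if len(series) >= 5:
        centers = np.round(series.times * sample_rate).astype(int)
        wave = _average_around(z, centers, n)
    return QrsTemplate(_center_and_normalize(wave, n // 2), sample_rate, "auto")


def _center_and_normalize(wave: np.ndarray, half: int) -> np.ndarray:
    shift = half - int(np.argmax(np.abs(wave)))
    wave = np.roll(wave, shift)
    peak = np.abs(wave).max()
    if peak == 0:
        raise AnalysisError("no QRS-like activity: flat template")
    return wave / peak


def detect_r_peaks(
    ecg: np.ndarray, template: QrsTemplate, threshold: float = 0.7
) -> RPeakSeries:
    """One R-peak per episode of supra-threshold template correlation.

    The correlation trace defines episodes (contiguous runs above
    ``threshold``); within each episode the peak is placed at the local
    maximum of the ECG itself, not of the correlation.  Detection is
    invariant to global scaling of the ECG because both signal and
    template are correlation-normalized.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly inside (0, 1)")
    ecg = np.asarray(ecg, dtype=float)
    z = _zscore(ecg)
    corr = sliding_correlation(z, template.waveform)
    above = corr > threshold
    if not above.any():
        warnings.warn("no supra-threshold correlation episode found", stacklevel=2)
        return RPeakSeries(times=np.empty(0))
    idx = np.flatnonzero(above)
    gap = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], gap + 1))
    run_ends = np.concatenate((gap, [len(idx) - 1]))
    center = int(np.argmax(np.abs(template.waveform)))
    times = []
    for s, e in zip(run_starts, run_ends):
        lo, hi = idx[s], idx[e]
        # matched-filter estimate of the R latency within the episode:
        # the correlation local maximum, with parabolic sub-sample
        # interpolation (the raw-signal argmax jitters with noise)
        j = lo + int(np.argmax(corr[lo : hi + 1]))
        frac = 0.0
        if 0 < j < len(corr) - 1:
            y0, y1, y2 = corr[j - 1], corr[j], corr[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                frac = float(np.clip((y0 - y2) / (2 * denom), -0.5, 0.5))
        times.append((j + center + frac) / template.sample_rate)
    times = np.unique(times)
    return RPeakSeries(times=np.asarray(times))


def qc_ibi(peaks: RPeakSeries, k: float = 5.0) -> RPeakSeries:
    """Flag interbeat intervals outside median +/- k * MAD.

    Flags mark suspect intervals (e.g. missed beats); no peak is ever
    dropped.  Intervals shorter than 0.25 s are always flagged.
    """
    if len(peaks) < 3:
        raise AnalysisError("need at least 3 peaks for IBI quality control")
    ibi = peaks.ibi
    med = np.median(ibi)
    mad = np.median(np.abs(ibi - med))
    tol = k * max(mad, 1e-6)
    flags = (np.abs(ibi - med) > tol) | (ibi < 0.25)
    return replace(peaks, qc_flags=flags)
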