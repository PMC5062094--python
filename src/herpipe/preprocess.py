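"""Continuous-recording preprocessing and heartbeat-locked epoching.

The canonical order of operations is: band-pass filter -> downsample ->
bipolar re-reference -> epoch extraction around R-peaks -> artifact
rejection -> per-trial averaging.  Each step records itself in the
recording's provenance list so downstream result files can report the
exact processing chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .errors import AnalysisError, ValidationError

#: default epoch window relative to the R-peak, in ms
EPOCH_WINDOW_MS = (-100.0, 600.0)
#: default minimum lead time between an R-peak and the stimulus, in ms
MIN_LEAD_MS = 700.0


@dataclass
class ContinuousRecording:
    """Uniformly sampled multichannel signal with channel metadata.

    ``data`` is (n_channels, n_samples) in recording units.  ``montage``
    is ``"referential"`` or ``"bipolar"``; in a bipolar montage channel
    labels are ``"A-B"`` pairs of adjacent same-shaft contacts.
    ``shaft`` assigns each channel to an electrode shaft name.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    montage: str = "referential"
    shaft: list[str] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a (channels, samples) matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError("channel_labels length must match data rows")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.montage not in ("referential", "bipolar"):
            raise ValidationError(f"unknown montage {self.montage!r}")
        if self.shaft is not None and len(self.shaft) != self.data.shape[0]:
            raise ValidationError("shaft assignment length must match channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.data[idx]


@dataclass
class Exclusion:
    """One rejected (epoch, channel) pair with the triggering rule."""

    epoch_index: int
    trial_id: int
    channel: str
    reason: str  # "amplitude" | "range"


@dataclass
class HEREpochs:
    """Heartbeat-locked epochs: (n_epochs, n_channels, n_samples).

    ``time_ms`` runs from the window start to end inclusive (default
    -100..600 ms, i.e. 701 samples at 1000 Hz).  ``trial_ids`` maps each
    epoch to its trial; ``retained`` is a boolean (epoch, channel) mask
    updated by :func:`reject_artifacts`.
    """

    data: np.ndarray
    time_ms: np.ndarray
    trial_ids: np.ndarray
    peak_times: np.ndarray
    channel_labels: list[str]
    sample_rate: float
    retained: np.ndarray = None  # type: ignore[assignment]
    excluded: list[Exclusion] = field(default_factory=list)
    incomplete_trials: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.retained is None:
            self.retained = np.ones(self.data.shape[:2], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def site_index(self, channel: str) -> int:
        try:
            return self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"no channel labelled {channel!r}") from None


@dataclass
class TrialHER:
    """One averaged heartbeat-evoked response per trial per channel."""

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    time_ms: np.ndarray
    trial_ids: np.ndarray
    channel_labels: list[str]
    sample_rate: float
    epochs_per_trial: np.ndarray  # (n_trials, n_channels) retained-epoch counts
    dropped_trials: list[int] = field(default_factory=list)

    def site(self, channel: str) -> np.ndarray:
        """(n_trials, n_samples) matrix for one recording site."""
        try:
            idx = self.channel_labels.index(channel)
        except ValueError:
            raise KeyError(f"no channel labelled {channel!r}") from None
        return self.data[:, idx, :]


def bandpass(
    rec: ContinuousRecording, low: float = 0.5, high: float = 25.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass; removes DC by construction."""
    nyq = rec.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValidationError(
            f"invalid band ({low}, {high}) Hz for sample rate {rec.sample_rate}"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    out = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(
        rec,
        data=out,
        provenance=rec.provenance + [f"bandpass({low},{high},order={order})"],
    )


def downsample(rec: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Anti-aliased resampling to ``target_rate`` (polyphase)."""
    if target_rate > rec.sample_rate:
        raise ValidationError("upsampling is not supported")
    if target_rate == rec.sample_rate:
        return rec
    from fractions import Fraction

    frac = Fraction(target_rate / rec.sample_rate).limit_denominator(1000)
    out = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(
        rec,
        data=out,
        sample_rate=target_rate,
        provenance=rec.provenance + [f"downsample({target_rate})"],
    )


def to_bipolar(rec: ContinuousRecording) -> ContinuousRecording:
    """Re-reference each contact to its next neighbour on the same shaft.

    A shaft of n contacts yields n-1 bipolar channels labelled "A-B";
    single-contact shafts contribute nothing.  Channel order within a
    shaft follows the input order (assumed anatomical along the shaft).
    """
    if rec.montage != "referential":
        raise ValidationError("recording is already bipolar")
    if rec.shaft is None:
        raise ValidationError("bipolar montage requires a shaft assignment")
    rows, labels, shafts = [], [], []
    seen: dict[str, list[int]] = {}
    for i, s in enumerate(rec.shaft):
        seen.setdefault(s, []).append(i)
    for s, idxs in seen.items():
        if len(idxs) < 2:
            warnings.warn(
                f"shaft {s!r} has a single contact; no bipolar channel emitted",
                stacklevel=2,
            )
        for a, b in zip(idxs[:-1], idxs[1:]):
            rows.append(rec.data[a] - rec.data[b])
            labels.append(f"{rec.channel_labels[a]}-{rec.channel_labels[b]}")
            shafts.append(s)
    if not rows:
        raise AnalysisError("no shaft has two or more contacts")
    return ContinuousRecording(
        data=np.array(rows),
        sample_rate=rec.sample_rate,
        channel_labels=labels,
        montage="bipolar",
        shaft=shafts,
        provenance=rec.provenance + ["to_bipolar"],
    )


def select_prestim_peaks(
    peak_times: np.ndarray,
    stim_onset: float,
    n_peaks: int = 2,
    min_lead_ms: float = MIN_LEAD_MS,
) -> np.ndarray:
    """Last ``n_peaks`` R-peak times at least ``min_lead_ms`` before the stimulus."""
    peak_times = np.asarray(peak_times, dtype=float)
    eligible = peak_times[peak_times <= stim_onset - min_lead_ms / 1000.0 + 1e-12]
    return eligible[-n_peaks:]


def extract_her_epochs(
    rec: ContinuousRecording,
    peak_times: np.ndarray,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    min_lead_ms: float = MIN_LEAD_MS,
    n_peaks: int = 2,
) -> HEREpochs:
    """Epoch the recording around the last ``n_peaks`` R-peaks preceding
    each non-skipped stimulus by at least ``min_lead_ms``.

    Trials with fewer than ``n_peaks`` eligible peaks, or whose epoch
    would run off the recording, are listed in ``incomplete_trials``
    rather than raising (incompleteness is data, not an error).
    """
    fs = rec.sample_rate
    pre = int(round(-window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    n_samp = pre + post + 1
    time_ms = (np.arange(n_samp) - pre) * 1000.0 / fs

    epochs, ids, ptimes, incomplete = [], [], [], []
    for row in trials.itertuples(index=False):
        if getattr(row, "skipped", 0):
            continue
        sel = select_prestim_peaks(peak_times, row.stim_onset_s, n_peaks, min_lead_ms)
        if len(sel) < n_peaks:
            incomplete.append(int(row.trial_id))
            continue
        ok = True
        starts = []
        for t in sel:
            c = int(round(t * fs))
            if c - pre < 0 or c + post >= rec.n_samples:
                ok = False
                break
            starts.append(c - pre)
        if not ok:
            incomplete.append(int(row.trial_id))
            continue
        for t, s in zip(sel, starts):
            epochs.append(rec.data[:, s : s + n_samp])
            ids.append(int(row.trial_id))
            ptimes.append(t)

    data = np.array(epochs) if epochs else np.empty((0, rec.n_channels, n_samp))
    return HEREpochs(
        data=data,
        time_ms=time_ms,
        trial_ids=np.array(ids, dtype=int),
        peak_times=np.array(ptimes, dtype=float),
        channel_labels=list(rec.channel_labels),
        sample_rate=fs,
        incomplete_trials=incomplete,
    )


def _sliding_range(x: np.ndarray, win: int) -> np.ndarray:
    """Max minus min over every fully contained window of ``win`` samples."""
    if x.shape[-1] < win:
        return (x.max(axis=-1) - x.min(axis=-1))[..., None]
    v = np.lib.stride_tricks.sliding_window_view(x, win, axis=-1)
    return v.max(axis=-1) - v.min(axis=-1)


def reject_artifacts(
    epochs: HEREpochs,
    abs_limit: float = 200.0,
    range_limit: float = 300.0,
    range_window_ms: float = 20.0,
) -> HEREpochs:
    """Flag epochs whose amplitude or local dynamic range is excessive.

    An (epoch, channel) pair is excluded iff any sample exceeds
    ``abs_limit`` in absolute value, or any ``range_window_ms`` interval
    has max-min >= ``range_limit``.  Thresholds are in recording units;
    the defaults mirror the conventional 200/300 values.  Nothing is
    dropped from the arrays -- ``retained`` is updated and every
    exclusion is logged with its reason.
    """
    if abs_limit <= 0 or range_limit <= 0:
        raise ValidationError("rejection limits must be positive")
    if epochs.n_epochs == 0:
        return epochs
    win = int(round(range_window_ms * epochs.sample_rate / 1000.0)) + 1
    amp_bad = np.abs(epochs.data).max(axis=-1) > abs_limit
    rng_bad = _sliding_range(epochs.data, win).max(axis=-1) >= range_limit
    retained = ~(amp_bad | rng_bad)
    excluded = list(epochs.excluded)
    for e, c in zip(*np.nonzero(~retained)):
        reason = "amplitude" if amp_bad[e, c] else "range"
        excluded.append(
            Exclusion(int(e), int(epochs.trial_ids[e]), epochs.channel_labels[c], reason)
        )
    return replace(epochs, retained=epochs.retained & retained, excluded=excluded)


def average_trial_her(
    epochs: HEREpochs, require_full: bool = False, n_peaks: int = 2
) -> TrialHER:
    """Average retained epochs within each trial: one HER per trial per site.

    Trials with zero retained epochs on a channel are dropped for all
    channels and logged in ``dropped_trials``.  With ``require_full``,
    trials missing any epoch on any channel are dropped too (strict
    mode); the default keeps single-epoch trials.
    """
    if epochs.n_epochs == 0:
        raise AnalysisError("no epochs to average")
    uniq = np.unique(epochs.trial_ids)
    n_ch = epochs.data.shape[1]
    rows, counts, kept, dropped = [], [], [], []
    for tid in uniq:
        m = epochs.trial_ids == tid
        sub = epochs.data[m]  # (k, ch, t)
        ret = epochs.retained[m]  # (k, ch)
        cnt = ret.sum(axis=0)
        if (cnt == 0).any() or (require_full and (cnt < n_peaks).any()):
            dropped.append(int(tid))
            continue
        w = ret[:, :, None].astype(float)
        rows.append((sub * w).sum(axis=0) / cnt[:, None])
        counts.append(cnt)
        kept.append(int(tid))
    if not rows:
        raise AnalysisError(
            "all trials lost to artifact rejection; nothing to analyse"
        )
    return TrialHER(
        data=np.array(rows),
        time_ms=epochs.time_ms,
        trial_ids=np.array(kept, dtype=int),
        channel_labels=list(epochs.channel_labels),
        sample_rate=epochs.sample_rate,
        epochs_per_trial=np.array(counts, dtype=int),
        dropped_trials=dropped,
    )
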