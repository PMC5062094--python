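"""Synthetic session generator.

Produces complete sessions -- an ECG channel with realistic QRS/T
morphology and heart-rate variability, neural channels carrying a
heartbeat-locked evoked component whose amplitude covaries with
continuous per-trial ratings, a trial table, and a ground-truth record
-- so every downstream stage can be tested against known parameters.

Conventions baked into the generator:

* ratings live on a latent Gaussian mapped to [0, 1] through its CDF
  (so each marginal is uniform and the rating SD is 1/sqrt(12));
* the heartbeat-locked component is a Gaussian bump whose peak amplitude
  on each beat is ``baseline + coupling_beta * rating`` of the trial the
  beat precedes;
* RR intervals are i.i.d. Gaussian around ``mean_rr``, truncated at
  +/- 3 SD, with no rating coupling;
* an optional cardiac-field artifact is strictly confined to < 300 ms
  after each R-peak;
* an optional slow, stimulus-locked drift with rating-proportional
  amplitude provides a *non* heartbeat-locked confound for testing the
  surrogate control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import ContinuousRecording, select_prestim_peaks

RATING_SD = 1.0 / math.sqrt(12.0)  # SD of a uniform [0,1] rating


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults give a plausible session."""

    n_trials: int = 40
    fixation_range: tuple[float, float] = (13.5, 29.9)
    sample_rate: float = 1000.0
    mean_rr: float = 0.85
    rr_jitter_sd: float = 0.05
    rt_interval: float = 0.269
    her_latency_ms: float = 425.0
    her_width_ms: float = 50.0  # FWHM of the Gaussian bump
    her_baseline: float = 1.0
    coupling_beta: float = 0.0
    coupling_window_ms: tuple[float, float] = (400.0, 450.0)
    scales: tuple[str, ...] = ("I", "Me")
    coupling_scale: str | None = None  # default: first scale
    inter_scale_r: float = 0.6
    artifact_rate: float = 0.0
    artifact_amplitude: float = 500.0
    cfa_amplitude: float = 0.0
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    ecg_noise_sd: float = 0.05
    n_neural: int = 2
    post_stim_gap: float = 2.0
    lead_in: float = 5.0
    drift_beta: float = 0.0
    drift_center_s: float = 1.5  # bump peak, seconds before the stimulus
    drift_width_s: float = 1.0  # bump SD
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ValidationError:
            return ValidationError(f"SimConfig.{name}: {why}")

        if self.n_trials < 1:
            raise bad("n_trials", "must be >= 1")
        lo, hi = self.fixation_range
        if lo < 1.0 or hi < lo:
            raise bad("fixation_range", "lower bound must be >= 1 s and <= upper")
        if self.sample_rate <= 0:
            raise bad("sample_rate", "must be positive")
        if not 0.4 <= self.mean_rr <= 1.5:
            raise bad("mean_rr", "must lie in [0.4, 1.5] s")
        w0, w1 = self.coupling_window_ms
        if not (-100.0 <= w0 <= w1 <= 600.0):
            raise bad("coupling_window_ms", "must lie within [-100, 600] ms")
        if abs(self.inter_scale_r) > 1:
            raise bad("inter_scale_r", "must lie in [-1, 1]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise bad("artifact_rate", "must lie in [0, 1]")
        if len(self.scales) < 1:
            raise bad("scales", "need at least one scale")
        if self.coupling_scale is not None and self.coupling_scale not in self.scales:
            raise bad("coupling_scale", f"unknown scale {self.coupling_scale!r}")
        if self.n_neural < 1:
            raise bad("n_neural", "need at least one neural channel")


@dataclass
class GroundTruth:
    """Oracle record written alongside each simulated session."""

    true_r_times: np.ndarray
    true_coupling_window_ms: tuple[float, float]
    true_beta: float
    implied_r: float
    ratings: pd.DataFrame  # per-trial latent rating values per scale
    selected_pairs: dict[int, list[float]]  # trial_id -> the two analysed R times
    corrupted_epochs: list[tuple[int, float]] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "true_r_times": [float(t) for t in self.true_r_times],
            "true_coupling_window_ms": list(self.true_coupling_window_ms),
            "true_beta": self.true_beta,
            "implied_r": self.implied_r,
            "ratings": self.ratings.to_dict(orient="list"),
            "selected_pairs": {str(k): v for k, v in self.selected_pairs.items()},
            "corrupted_epochs": [[t, r] for t, r in self.corrupted_epochs],
        }


def implied_r(beta: float, config: SimConfig) -> float:
    """Per-sample correlation implied by a coupling slope at the kernel peak.

    r = beta * sigma_rating / sqrt(beta^2 sigma_rating^2 + sigma_noise^2)
    for a single raw epoch sample at the bump peak.
    """
    s = beta * RATING_SD
    return s / math.sqrt(s * s + config.noise_sd**2)


def beta_for_implied_r(r: float, config: SimConfig) -> float:
    """Coupling slope that yields per-sample correlation ``r`` (see implied_r)."""
    if not -1 < r < 1:
        raise ValidationError("implied r must lie strictly inside (-1, 1)")
    return (config.noise_sd / RATING_SD) * r / math.sqrt(1.0 - r * r)


def simulate_ratings(
    n_trials: int,
    scales: tuple[str, ...] = ("I", "Me"),
    inter_scale_r: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Continuous [0, 1] ratings with a Gaussian-copula correlation structure.

    All pairs of scales share correlation ``inter_scale_r`` on the latent
    Gaussian; the probit map to [0, 1] preserves it to a very good
    approximation (exactly at r in {-1, 0, 1}).
    """
    if n_trials < 3:
        raise ValidationError("need at least 3 trials for downstream correlation")
    if abs(inter_scale_r) > 1:
        raise ValidationError("|inter_scale_r| must be <= 1")
    k = len(scales)
    if k > 1 and inter_scale_r < -1.0 / (k - 1):
        raise ValidationError("equicorrelation matrix not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k > 1 and abs(inter_scale_r) == 1.0:
        z0 = rng.standard_normal(n_trials)
        z = np.column_stack(
            [z0] + [np.copysign(1.0, inter_scale_r) * z0 for _ in range(k - 1)]
        )
    else:
        cov = np.full((k, k), float(inter_scale_r))
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n_trials, method="cholesky")
    from scipy.stats import norm

    u = norm.cdf(z)
    return pd.DataFrame(u, columns=list(scales))


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    x = rng.normal(0.0, sd, size)
    return np.clip(x, -3 * sd, 3 * sd)


def _gauss_add(sig: np.ndarray, fs: float, center_s: float, sd_s: float, amp: float) -> None:
    """Add amp * N(center, sd) bump to ``sig`` in place (support +/- 4 SD)."""
    lo = max(0, int(math.floor((center_s - 4 * sd_s) * fs)))
    hi = min(len(sig), int(math.ceil((center_s + 4 * sd_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sd_s) ** 2)


def ecg_waveform_times() -> list[tuple[float, float, float]]:
    """(offset_s, sd_s, amplitude) of the P/Q/R/S deflections, R at 0."""
    return [
        (-0.180, 0.025, 0.12),  # P
        (-0.022, 0.006, -0.15),  # Q
        (0.000, 0.008, 1.00),  # R
        (0.022, 0.007, -0.20),  # S
    ]


def synth_qrs_shape(sample_rate: float, length_ms: float = 120.0) -> np.ndarray:
    """The noise-free QRS complex used by the simulator (R at the centre)."""
    n = int(round(length_ms * sample_rate / 1000.0))
    t = (np.arange(n) - n // 2) / sample_rate
    w = np.zeros(n)
    for off, sd, amp in ecg_waveform_times():
        if abs(off) < length_ms / 2000.0 + 0.05:
            w += amp * np.exp(-0.5 * ((t - off) / sd) ** 2)
    return w


def _one_over_f_noise(
    rng: np.random.Generator, n: int, exponent: float, sd: float
) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, normalized to the requested SD."""
    white = rng.standard_normal(n)
    if exponent == 0 or sd == 0:
        return white * sd
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero; DC handled below
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _her_kernel_sd_s(config: SimConfig) -> float:
    return config.her_width_ms / 1000.0 / 2.3548200450309493  # FWHM -> SD


def simulate_session(
    config: SimConfig,
) -> tuple[ContinuousRecording, pd.DataFrame, GroundTruth]:
    """Simulate a full session (ECG + neural channels + trials + truth).

    Deterministic given ``config`` (including its seed).  Guarantees at
    least two R-peaks preceding every stimulus by >= 700 ms: stimulus
    onsets are pushed later when the heartbeat draw leaves too few
    eligible peaks (rare with fixations of a few seconds or more).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate

    ratings = simulate_ratings(
        max(config.n_trials, 3), config.scales, config.inter_scale_r, rng
    ).iloc[: config.n_trials]
    ratings.insert(0, "trial_id", np.arange(config.n_trials))
    scale = config.coupling_scale or config.scales[0]

    # --- trial timing ------------------------------------------------------
    lo, hi = config.fixation_range
    fixations = rng.uniform(lo, hi, config.n_trials)
    stim, t_cursor = [], config.lead_in
    for f in fixations:
        stim.append(t_cursor + f)
        t_cursor = t_cursor + f + config.post_stim_gap
    stim = np.array(stim)

    # --- heartbeat times ---------------------------------------------------
    total = stim[-1] + config.post_stim_gap + 1.0
    n_beats = int(total / (config.mean_rr - 3 * config.rr_jitter_sd)) + 4
    rr = config.mean_rr + _truncated_normal(rng, config.rr_jitter_sd, n_beats)
    r_times = 0.5 + np.cumsum(rr) - rr[0]
    r_times = r_times[r_times < total - 0.8]

    # enforce >= 2 eligible peaks before each stimulus (shift stim later if not)
    for i in range(config.n_trials):
        while len(select_prestim_peaks(r_times, stim[i])) < 2:
            shift = config.mean_rr
            stim[i:] += shift

    total = stim[-1] + config.post_stim_gap + 1.0
    n_samples = int(round(total * fs))

    # assign each beat to the upcoming stimulus (rating it couples to)
    beat_trial = np.searchsorted(stim, r_times)  # == n_trials past the last stim
    rating_of_beat = np.full(len(r_times), np.nan)
    in_session = beat_trial < config.n_trials
    rating_of_beat[in_session] = ratings[scale].to_numpy()[beat_trial[in_session]]

    # --- ECG channel -------------------------------------------------------
    ecg = _one_over_f_noise(rng, n_samples, 0.0, config.ecg_noise_sd)
    for tb in r_times:
        for off, sd, amp in ecg_waveform_times():
            _gauss_add(ecg, fs, tb + off, sd, amp)
        _gauss_add(ecg, fs, tb + config.rt_interval, 0.05, 0.30)  # T wave

    # --- neural channels ---------------------------------------------------
    k_sd = _her_kernel_sd_s(config)
    k_lat = config.her_latency_ms / 1000.0
    neural = np.empty((config.n_neural, n_samples))
    for ch in range(config.n_neural):
        sig = _one_over_f_noise(rng, n_samples, config.noise_exponent, config.noise_sd)
        for tb, rat in zip(r_times, rating_of_beat):
            amp = config.her_baseline
            if not np.isnan(rat):
                amp += config.coupling_beta * rat
            _gauss_add(sig, fs, tb + k_lat, k_sd, amp)
            if config.cfa_amplitude:
                _add_cfa(sig, fs, tb, config.cfa_amplitude)
        if config.drift_beta:
            for s_on, rat in zip(stim, ratings[scale].to_numpy()):
                _gauss_add(
                    sig,
                    fs,
                    s_on - config.drift_center_s,
                    config.drift_width_s,
                    config.drift_beta * (rat - 0.5),
                )
        neural[ch] = sig

    # --- per-trial analysed pairs & optional corruption --------------------
    selected_pairs: dict[int, list[float]] = {}
    for i in range(config.n_trials):
        selected_pairs[i] = [float(t) for t in select_prestim_peaks(r_times, stim[i])]

    corrupted: list[tuple[int, float]] = []
    if config.artifact_rate > 0:
        all_pairs = [(tid, t) for tid, pair in selected_pairs.items() for t in pair]
        n_corrupt = int(round(config.artifact_rate * len(all_pairs)))
        pick = rng.choice(len(all_pairs), size=n_corrupt, replace=False)
        for j in sorted(pick):
            tid, tpk = all_pairs[j]
            c = int(round((tpk + 0.2) * fs))
            neural[:, c : c + int(0.03 * fs)] += config.artifact_amplitude
            corrupted.append((tid, tpk))

    data = np.vstack([ecg[None, :], neural])
    labels = ["ECG"] + [f"SITE{i + 1}" for i in range(config.n_neural)]
    rec = ContinuousRecording(
        data=data,
        sample_rate=fs,
        channel_labels=labels,
        montage="bipolar",  # neural channels emulate already re-referenced sites
        shaft=None,
        provenance=[f"simulate_session(seed={config.seed})"],
    )

    trials = pd.DataFrame({"trial_id": np.arange(config.n_trials), "stim_onset_s": stim})
    for s in config.scales:
        trials[f"{s}_rating"] = ratings[s].to_numpy()
    trials["skipped"] = 0

    truth = GroundTruth(
        true_r_times=r_times,
        true_coupling_window_ms=config.coupling_window_ms,
        true_beta=config.coupling_beta,
        implied_r=implied_r(config.coupling_beta, config),
        ratings=ratings,
        selected_pairs=selected_pairs,
        corrupted_epochs=corrupted,
    )
    return rec, trials, truth


def _add_cfa(sig: np.ndarray, fs: float, r_time: float, amplitude: float) -> None:
    """Residual cardiac-field artifact: biphasic, hard-zero beyond +300 ms."""
    lo = int(round(r_time * fs))
    hi = min(len(sig), lo + int(0.295 * fs))
    if hi <= lo or lo < 0:
        return
    t = np.arange(hi - lo) / fs
    shape = np.exp(-0.5 * ((t - 0.08) / 0.04) ** 2) - 0.5 * np.exp(
        -0.5 * ((t - 0.18) / 0.05) ** 2
    )
    sig[lo:hi] += amplitude * shape


def simulate_group_her(
    n_subjects: int,
    effect_size: float = 0.0,
    effect_window_ms: tuple[float, float] = (384.0, 480.0),
    time_ms: np.ndarray | None = None,
    noise_sd: float = 1.0,
    smooth_ms: float = 30.0,
    sample_rate: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject 'high'/'low' condition-average HER traces.

    ``effect_size`` is Cohen's d of the high-low difference at the centre
    of ``effect_window_ms``.  Returns (high, low, time_ms) with high/low
    of shape (n_subjects, n_time).  Noise is temporally smoothed white
    noise so cluster extents behave like filtered electrophysiology.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if time_ms is None:
        time_ms = np.arange(-100.0, 600.0 + 1e-9, 1000.0 / sample_rate)
    t = np.asarray(time_ms, dtype=float)
    c = 0.5 * (effect_window_ms[0] + effect_window_ms[1])
    sd = (effect_window_ms[1] - effect_window_ms[0]) / 4.0
    bump = np.exp(-0.5 * ((t - c) / sd) ** 2)

    def smooth_noise(shape):
        x = rng.standard_normal(shape)
        w = int(round(smooth_ms / (1000.0 / sample_rate)))
        if w > 1:
            kern = np.hanning(w)
            kern /= kern.sum()
            x = np.apply_along_axis(np.convolve, -1, x, kern, mode="same")
            x /= x.std()
        return x * noise_sd

    erp = 0.5 * np.sin(2 * np.pi * (t - t[0]) / 700.0)  # shared background ERP
    delta = effect_size * noise_sd * math.sqrt(2.0)  # d on the paired difference
    high = erp + 0.5 * delta * bump + smooth_noise((n_subjects, t.size))
    low = erp - 0.5 * delta * bump + smooth_noise((n_subjects, t.size))
    return high, low, t


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["fixation_range"] = list(d["fixation_range"])
    d["coupling_window_ms"] = list(d["coupling_window_ms"])
    d["scales"] = list(d["scales"])
    return d
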