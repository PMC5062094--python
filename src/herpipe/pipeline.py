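"""Convenience wiring of the single-session analysis chain.

These helpers run the canonical stage order (filter -> epoch -> reject ->
average -> cluster test) with one call each; the CLI and the test
battery both build on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ecg import RPeakSeries, build_template, detect_r_peaks, qc_ibi
from .io import analyzable_ratings
from .preprocess import (
    ContinuousRecording,
    TrialHER,
    average_trial_her,
    bandpass,
    extract_her_epochs,
    reject_artifacts,
)
from .singletrial import ClusterResult, cluster_permutation_correlation


def detect_peaks(
    rec: ContinuousRecording, ecg_channel: str = "ECG", threshold: float = 0.7
) -> RPeakSeries:
    """Template-matching R-peak detection with IBI QC on one channel."""
    sig = rec.channel(ecg_channel)
    tpl = build_template(sig, rec.sample_rate)
    return qc_ibi(detect_r_peaks(sig, tpl, threshold))


def analyze_session(
    rec: ContinuousRecording,
    peak_times: np.ndarray,
    trials: pd.DataFrame,
    scale: str,
    site: str,
    band: tuple[float, float] = (0.5, 25.0),
    order: int = 4,
    window_ms: tuple[float, float] = (300.0, 600.0),
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
    abs_limit: float = 200.0,
    range_limit: float = 300.0,
    range_window_ms: float = 20.0,
    min_lead_ms: float = 700.0,
) -> tuple[TrialHER, np.ndarray, ClusterResult]:
    """Filter, epoch, reject, average, and run the cluster permutation test.

    Returns (trial_her, aligned ratings, cluster result) for ``site``.
    """
    frec = bandpass(rec, band[0], band[1], order)
    ep = extract_her_epochs(frec, peak_times, trials, min_lead_ms=min_lead_ms)
    ep = reject_artifacts(ep, abs_limit, range_limit, range_window_ms)
    her = average_trial_her(ep)
    ratings = analyzable_ratings(trials, scale, her.trial_ids)
    result = cluster_permutation_correlation(
        her.site(site), ratings, her.time_ms, window_ms, cluster_alpha, n_perm, seed
    )
    return her, ratings, result
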