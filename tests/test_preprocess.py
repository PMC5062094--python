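"""Tests for filtering, re-referencing, epoching, rejection, averaging."""

import numpy as np
import pandas as pd
import pytest

from herpipe import (
    AnalysisError,
    ContinuousRecording,
    ValidationError,
    average_trial_her,
    bandpass,
    downsample,
    extract_her_epochs,
    reject_artifacts,
    select_prestim_peaks,
    simulate_session,
    to_bipolar,
)
from herpipe.preprocess import HEREpochs
from conftest import fast_config


def _rec(data, fs=1000.0, labels=None, **kw):
    data = np.atleast_2d(data)
    labels = labels or [f"C{i}" for i in range(data.shape[0])]
    return ContinuousRecording(data=data, sample_rate=fs, channel_labels=labels, **kw)


def _trials(stims, skipped=None):
    n = len(stims)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "stim_onset_s": stims,
            "I_rating": np.linspace(0.1, 0.9, n),
            "skipped": skipped if skipped is not None else np.zeros(n, dtype=int),
        }
    )


# ------------------------------------------------------------------ bandpass

def test_bandpass_stops_50hz():
    t = np.arange(20_000) / 1000.0
    rec = _rec(np.sin(2 * np.pi * 50 * t))
    out = bandpass(rec, 0.5, 25.0, 4)
    mid = slice(5000, 15000)  # avoid filtfilt edge transients
    assert np.sqrt((out.data[0, mid] ** 2).mean()) < 0.01 * np.sqrt(
        (rec.data[0, mid] ** 2).mean()
    )


def test_bandpass_passes_10hz():
    t = np.arange(20_000) / 1000.0
    rec = _rec(np.sin(2 * np.pi * 10 * t))
    out = bandpass(rec, 0.5, 25.0, 4)
    mid = slice(5000, 15000)
    ratio = np.sqrt((out.data[0, mid] ** 2).mean()) / np.sqrt(
        (rec.data[0, mid] ** 2).mean()
    )
    assert abs(ratio - 1.0) < 0.05


def test_bandpass_removes_dc():
    rec = _rec(np.full(10_000, 3.7))
    out = bandpass(rec, 0.5, 25.0, 4)
    assert np.abs(out.data).max() < 1e-6


@pytest.mark.parametrize("band", [(0.0, 25.0), (30.0, 25.0), (0.5, 600.0)])
def test_bandpass_invalid_band(band):
    rec = _rec(np.zeros(1000) + np.arange(1000))
    with pytest.raises(ValidationError):
        bandpass(rec, *band)


def test_bandpass_records_provenance():
    rec = _rec(np.random.default_rng(0).normal(size=5000))
    assert "bandpass(0.5,25.0,order=4)" in bandpass(rec).provenance


# ---------------------------------------------------------------- downsample

def test_downsample_4000_to_1000():
    rec = _rec(np.random.default_rng(0).normal(size=40_000), fs=4000.0)
    out = downsample(rec, 1000.0)
    assert abs(out.n_samples - 10_000) <= 1
    assert out.sample_rate == 1000.0


def test_downsample_identity():
    rec = _rec(np.arange(1000, dtype=float))
    assert downsample(rec, 1000.0) is rec


def test_downsample_preserves_5hz_amplitude():
    t = np.arange(40_000) / 4000.0
    rec = _rec(np.sin(2 * np.pi * 5 * t), fs=4000.0)
    out = downsample(rec, 1000.0)
    mid = slice(2000, 8000)
    amp = np.sqrt(2) * np.sqrt((out.data[0, mid] ** 2).mean())
    assert abs(amp - 1.0) < 0.02


def test_upsampling_refused():
    rec = _rec(np.zeros(100))
    with pytest.raises(ValidationError):
        downsample(rec, 2000.0)


# ------------------------------------------------------------------- bipolar

def test_bipolar_rejects_common_mode_exactly():
    common = np.random.default_rng(0).normal(size=5000)
    rec = _rec(
        np.tile(common, (4, 1)), labels=["A1", "A2", "A3", "A4"],
        shaft=["A"] * 4,
    )
    out = to_bipolar(rec)
    assert out.montage == "bipolar"
    assert np.abs(out.data).max() == 0.0
    assert out.channel_labels == ["A1-A2", "A2-A3", "A3-A4"]


def test_bipolar_channel_count():
    rng = np.random.default_rng(1)
    rec = _rec(rng.normal(size=(8, 2000)), labels=[f"A{i}" for i in range(8)],
               shaft=["A"] * 8)
    assert to_bipolar(rec).n_channels == 7


def test_bipolar_attenuates_shared_cardiac_artifact():
    rng = np.random.default_rng(2)
    artifact = 100.0 * np.sin(2 * np.pi * 1.2 * np.arange(20_000) / 1000.0)
    data = rng.normal(size=(4, 20_000)) + artifact  # shared across contacts
    rec = _rec(data, labels=["A1", "A2", "A3", "A4"], shaft=["A"] * 4)
    out = to_bipolar(rec)
    rms = lambda x: np.sqrt((x**2).mean())
    assert rms(out.data) < 0.05 * rms(rec.data)


def test_bipolar_single_contact_shaft_warns():
    rec = _rec(np.zeros((3, 1000)) + np.arange(1000), labels=["A1", "A2", "B1"],
               shaft=["A", "A", "B"])
    with pytest.warns(UserWarning, match="single contact"):
        out = to_bipolar(rec)
    assert out.channel_labels == ["A1-A2"]


def test_bipolar_requires_shaft_assignment():
    rec = _rec(np.zeros((2, 100)) + 1.0)
    with pytest.raises(ValidationError):
        to_bipolar(rec)


# ------------------------------------------------------------------ epoching

def brute_force_pair(peak_times, stim, min_lead_s=0.7):
    eligible = sorted(t for t in peak_times if t <= stim - min_lead_s)
    return eligible[-2:]


def test_peak_selection_honours_min_lead():
    peaks = np.array([7.6, 8.4, 9.2, 9.4])
    sel = select_prestim_peaks(peaks, 10.0)
    # 9.4 s peak leads by only 600 ms -> excluded; pair is (8.4, 9.2)
    assert np.array_equal(sel, [8.4, 9.2])
    assert list(sel) == brute_force_pair(peaks, 10.0)


def test_peak_selection_matches_brute_force_randomized(rng):
    for _ in range(50):
        peaks = np.sort(rng.uniform(0, 20, size=rng.integers(3, 25)))
        peaks = peaks[np.diff(peaks, prepend=-1) > 1e-3]
        stim = rng.uniform(1, 21)
        assert list(select_prestim_peaks(peaks, stim)) == brute_force_pair(peaks, stim)


def test_extract_epoch_geometry():
    rng = np.random.default_rng(3)
    rec = _rec(rng.normal(size=(1, 15_000)))
    ep = extract_her_epochs(rec, np.array([8.0, 8.8]), _trials([10.0]))
    assert ep.data.shape == (2, 1, 701)  # 701 samples at 1000 Hz
    assert ep.time_ms[0] == -100.0 and ep.time_ms[-1] == 600.0
    c = int(8.0 * 1000)
    assert np.array_equal(ep.data[0, 0], rec.data[0, c - 100 : c + 601])


def test_extract_skipped_trial_emits_nothing():
    rec = _rec(np.zeros((1, 15_000)) + 1.0)
    ep = extract_her_epochs(
        rec, np.array([7.0, 8.0, 8.8]), _trials([10.0], skipped=[1])
    )
    assert ep.n_epochs == 0


def test_extract_incomplete_trial_recorded_not_raised():
    rec = _rec(np.zeros((1, 15_000)) + 1.0)
    ep = extract_her_epochs(rec, np.array([9.5]), _trials([10.0]))
    assert ep.n_epochs == 0
    assert ep.incomplete_trials == [0]


def test_extract_translation_equivariance():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(1, 30_000))
    shift = 5000  # 5 s in samples
    shifted = np.concatenate([np.zeros((1, shift)), base], axis=1)
    ep0 = extract_her_epochs(_rec(base), np.array([8.0, 8.8]), _trials([10.0]))
    ep1 = extract_her_epochs(
        _rec(shifted), np.array([13.0, 13.8]), _trials([15.0])
    )
    assert np.array_equal(ep0.data, ep1.data)


# ----------------------------------------------------------------- rejection

def _epochs_from_matrix(mat):
    mat = np.asarray(mat, dtype=float)[:, None, :]
    n = mat.shape[0]
    return HEREpochs(
        data=mat,
        time_ms=np.arange(mat.shape[2]) - 100.0,
        trial_ids=np.arange(n),
        peak_times=np.zeros(n),
        channel_labels=["SITE1"],
        sample_rate=1000.0,
    )


def sliding_range_oracle(x, win):
    """Brute-force max-min over every win-sample window, 1-sample step."""
    return max(
        x[i : i + win].max() - x[i : i + win].min()
        for i in range(len(x) - win + 1)
    )


def test_reject_amplitude_rule():
    e = np.zeros(701)
    e[350] = 250.0
    ep = reject_artifacts(_epochs_from_matrix([e]), abs_limit=200.0)
    assert not ep.retained[0, 0]
    assert ep.excluded[0].reason == "amplitude"


def test_reject_range_rule_boundary():
    ramp_300 = np.zeros(701)
    ramp_300[100:121] = np.linspace(-150, 150, 21)  # 300 units across 20 ms
    ramp_299 = np.zeros(701)
    ramp_299[100:121] = np.linspace(-149.5, 149.5, 21)
    ep = reject_artifacts(_epochs_from_matrix([ramp_300, ramp_299]))
    assert not ep.retained[0, 0] and ep.excluded[0].reason == "range"
    assert ep.retained[1, 0]
    # agree with the brute-force sliding oracle at the 1-sample step
    assert sliding_range_oracle(ramp_300, 21) >= 300
    assert sliding_range_oracle(ramp_299, 21) < 300


def test_reject_matches_sliding_oracle_randomized(rng):
    mats = rng.normal(scale=80.0, size=(40, 701))
    ep = reject_artifacts(_epochs_from_matrix(mats), abs_limit=250.0,
                          range_limit=300.0)
    for i in range(40):
        amp_bad = np.abs(mats[i]).max() > 250.0
        rng_bad = sliding_range_oracle(mats[i], 21) >= 300.0
        assert ep.retained[i, 0] == (not (amp_bad or rng_bad))


def test_reject_all_zero_epochs_retained():
    ep = reject_artifacts(_epochs_from_matrix(np.zeros((5, 701))))
    assert ep.retained.all()
    assert ep.excluded == []


def test_reject_order_invariance(rng):
    mats = rng.normal(scale=120.0, size=(30, 701))
    fwd = reject_artifacts(_epochs_from_matrix(mats))
    perm = rng.permutation(30)
    rev = reject_artifacts(_epochs_from_matrix(mats[perm]))
    assert np.array_equal(fwd.retained[perm, 0], rev.retained[:, 0])


def test_reject_invalid_limits():
    with pytest.raises(ValidationError):
        reject_artifacts(_epochs_from_matrix(np.zeros((1, 701))), abs_limit=-1)


# ----------------------------------------------------------------- averaging

def test_average_identical_epochs_idempotent(rng):
    e = rng.normal(size=701)
    ep = _epochs_from_matrix([e, e])
    ep.trial_ids = np.array([0, 0])
    her = average_trial_her(ep)
    assert np.allclose(her.data[0, 0], e)
    assert her.epochs_per_trial[0, 0] == 2


def test_average_cancellation(rng):
    e = rng.normal(size=701)
    ep = _epochs_from_matrix([e, -e])
    ep.trial_ids = np.array([0, 0])
    her = average_trial_her(ep)
    assert np.allclose(her.data[0, 0], 0.0)


def test_average_drops_fully_rejected_trials(rng):
    mats = rng.normal(size=(4, 701))
    ep = _epochs_from_matrix(mats)
    ep.trial_ids = np.array([0, 0, 1, 1])
    ep.retained[2:, 0] = False
    her = average_trial_her(ep)
    assert list(her.trial_ids) == [0]
    assert her.dropped_trials == [1]


def test_average_all_rejected_refuses(rng):
    ep = _epochs_from_matrix(rng.normal(size=(2, 701)))
    ep.retained[:] = False
    with pytest.raises(AnalysisError, match="all trials"):
        average_trial_her(ep)


def test_rejection_bookkeeping_matches_generator():
    cfg = fast_config(
        n_trials=20, fixation_range=(6.0, 8.0), artifact_rate=0.1,
        artifact_amplitude=800.0, seed=21,
    )
    rec, trials, truth = simulate_session(cfg)
    frec = bandpass(rec)
    ep = extract_her_epochs(frec, truth.true_r_times, trials)
    ep = reject_artifacts(ep)
    her = average_trial_her(ep)
    corrupted_trials = {tid for tid, _ in truth.corrupted_epochs}
    excluded_trials = {x.trial_id for x in ep.excluded if x.channel != "ECG"}
    assert corrupted_trials == excluded_trials
    # trials keep their HER unless both of their epochs were corrupted
    both = {
        tid for tid in corrupted_trials
        if sum(t == tid for t, _ in truth.corrupted_epochs) == 2
    }
    assert set(her.dropped_trials) == both
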