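"""Surrogate-heartbeat control.

Demonstrates that a HER-rating correlation is locked to heartbeats: the
pair of pre-stimulus R-peak timings of trial i is reassigned to trial j
(a random bijection of trials per surrogate), epochs are re-extracted at
the reassigned timings, the same rejection and averaging are applied,
and the extreme cluster statistic is recomputed.  Ratings never move --
only heartbeat timings do.  Timings are transferred relative to each
trial's stimulus onset so surrogate epochs stay inside their trial's
fixation period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .cluster import Cluster, extreme_cluster_sums, find_clusters, mc_pvalue, t_from_r
from .errors import AnalysisError
from .preprocess import (
    EPOCH_WINDOW_MS,
    MIN_LEAD_MS,
    ContinuousRecording,
    _sliding_range,
    select_prestim_peaks,
)
from .singletrial import DEFAULT_WINDOW_MS, _window_mask, _zscore_cols


@dataclass
class SurrogateResult:
    observed_extreme: float
    observed_cluster: Cluster
    null_extremes: np.ndarray
    n_perm: int
    p_mc: float
    tail: str  # "max" for a positive observed cluster, "min" for negative
    seed: int | None
    n_redraws: int


def _epoch_matrix(
    sig: np.ndarray, times: np.ndarray, fs: float, pre: int, post: int
) -> np.ndarray:
    centers = np.round(np.asarray(times) * fs).astype(int)
    idx = centers[:, None] + np.arange(-pre, post + 1)[None, :]
    return sig[idx]


def _stat_for_times(
    sig: np.ndarray,
    pair_times: np.ndarray,  # (n_trials, 2)
    ratings: np.ndarray,
    fs: float,
    pre: int,
    post: int,
    wmask: np.ndarray,
    wtime: np.ndarray,
    cluster_alpha: float,
    abs_limit: float,
    range_limit: float,
    range_win: int,
    tail_sign: int | None,
):
    """HER -> correlation -> extreme cluster sum, for one timing assignment.

    Returns (extreme_sum, clusters); extreme is 0 when no cluster forms.
    With ``tail_sign`` fixed, only that tail's extreme is reported.
    """
    n_t = pair_times.shape[0]
    ep = _epoch_matrix(sig, pair_times.ravel(), fs, pre, post)  # (2n, T)
    bad = (np.abs(ep).max(axis=1) > abs_limit) | (
        _sliding_range(ep, range_win).max(axis=1) >= range_limit
    )
    keep = ~bad.reshape(n_t, 2)
    cnt = keep.sum(axis=1)
    ok = cnt > 0
    if ok.sum() < 4:
        raise AnalysisError("fewer than 4 trials survive artifact rejection")
    w = keep[:, :, None].astype(float)
    her = (ep.reshape(n_t, 2, -1) * w).sum(axis=1)[ok] / cnt[ok, None]
    y = ratings[ok]
    n = her.shape[0]
    yz = (y - y.mean()) / y.std()
    xz = _zscore_cols(her[:, wmask])
    r = np.clip(yz @ xz / n, -1.0, 1.0)
    t = t_from_r(r, n)
    t_crit = float(scipy.stats.t.ppf(1 - cluster_alpha / 2, n - 2))
    clusters = find_clusters(t, t_crit, wtime)
    mx, mn = extreme_cluster_sums(t[None, :], t_crit)
    if tail_sign is None:
        extreme = mx[0] if abs(mx[0]) >= abs(mn[0]) else mn[0]
    else:
        extreme = mx[0] if tail_sign > 0 else mn[0]
    return float(extreme), clusters


def surrogate_heartbeat_test(
    rec: ContinuousRecording,
    peak_times: np.ndarray,
    trials: pd.DataFrame,
    scale: str,
    channel: str,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
    epoch_window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    min_lead_ms: float = MIN_LEAD_MS,
    abs_limit: float = 200.0,
    range_limit: float = 300.0,
    range_window_ms: float = 20.0,
    estimator: str = "plus_one",
    max_redraw: int = 100,
) -> SurrogateResult:
    """Monte Carlo p of the observed extreme cluster under surrogate heartbeats.

    The observed analysis is reproduced internally (identity assignment);
    its largest-|sum t| cluster fixes the tail: the smallest surrogate
    sums are collected when the observed cluster is negative, the largest
    when positive.  Permutations that would push an epoch across its
    trial's stimulus or off the recording are re-drawn (counted in
    ``n_redraws``), preserving ``n_perm``.
    """
    fs = rec.sample_rate
    sig = rec.channel(channel)
    pre = int(round(-epoch_window_ms[0] * fs / 1000.0))
    post = int(round(epoch_window_ms[1] * fs / 1000.0))

    stims, offsets, ratings, prev_stim = [], [], [], []
    last_stim = 0.0
    for row in trials.itertuples(index=False):
        if row.skipped:
            last_stim = row.stim_onset_s
            continue
        sel = select_prestim_peaks(peak_times, row.stim_onset_s, 2, min_lead_ms)
        if len(sel) == 2:
            stims.append(row.stim_onset_s)
            offsets.append(sel - row.stim_onset_s)
            ratings.append(getattr(row, f"{scale}_rating"))
            prev_stim.append(last_stim)
        last_stim = row.stim_onset_s
    n_t = len(stims)
    if n_t < 4:
        raise AnalysisError("fewer than 4 analysable trials")
    stims = np.array(stims)
    offsets = np.array(offsets)  # (n_t, 2), all <= -0.7
    ratings = np.array(ratings, dtype=float)
    prev_stim = np.array(prev_stim)

    args = dict(
        fs=fs,
        pre=pre,
        post=post,
        cluster_alpha=cluster_alpha,
        abs_limit=abs_limit,
        range_limit=range_limit,
        range_win=int(round(range_window_ms * fs / 1000.0)) + 1,
    )
    time_full = (np.arange(pre + post + 1) - pre) * 1000.0 / fs
    wmask = _window_mask(time_full, window_ms)
    wtime = time_full[wmask]

    observed_extreme, clusters = _stat_for_times(
        sig, stims[:, None] + offsets, ratings,
        wmask=wmask, wtime=wtime, tail_sign=None, **args,
    )
    if not clusters:
        raise AnalysisError(
            "no candidate clusters in the original analysis; "
            "the surrogate control requires an observed cluster"
        )
    obs_cluster = max(clusters, key=lambda c: abs(c.sum_t))
    sign = obs_cluster.sign
    tail = "max" if sign > 0 else "min"

    def valid(perm: np.ndarray) -> np.ndarray:
        new_times = stims[:, None] + offsets[perm]  # (n_t, 2)
        lo_ok = (new_times.min(axis=1) - pre / fs) >= prev_stim
        in_rec = ((new_times.min(axis=1) * fs - pre) >= 0) & (
            (new_times.max(axis=1) * fs + post) < rec.n_samples
        )
        return lo_ok & in_rec

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_redraws = 0
    for k in range(n_perm):
        perm = rng.permutation(n_t)
        bad = ~valid(perm)
        attempts = 0
        while bad.any() and attempts < max_redraw:
            where = np.flatnonzero(bad)
            perm[where] = perm[rng.permutation(where)] if where.size > 1 else perm[where]
            if where.size == 1:  # a lone invalid assignment: swap with a random trial
                j = int(rng.integers(n_t))
                perm[where[0]], perm[j] = perm[j], perm[where[0]]
            bad = ~valid(perm)
            attempts += 1
            n_redraws += 1
        if bad.any():  # fall back to self-assignment for stubborn trials
            where = np.flatnonzero(bad)
            for j in where:
                src = np.flatnonzero(perm == j)[0]
                perm[src], perm[j] = perm[j], j
        null[k], _ = _stat_for_times(
            sig, stims[:, None] + offsets[perm], ratings,
            wmask=wmask, wtime=wtime, tail_sign=sign, **args,
        )

    p = mc_pvalue(observed_extreme, null, sign, estimator)
    return SurrogateResult(
        observed_extreme=observed_extreme,
        observed_cluster=obs_cluster,
        null_extremes=null,
        n_perm=n_perm,
        p_mc=p,
        tail=tail,
        seed=seed,
        n_redraws=n_redraws,
    )
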