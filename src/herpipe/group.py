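"""Group-level median-split HER comparison.

Each subject contributes a pair of condition-average HER traces ("high"
vs "low", from a median split of that subject's ratings); a per-sample
paired t-test across subjects is clustered over time and assessed with a
within-subject sign-flip permutation distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .cluster import extreme_cluster_sums, find_clusters, mc_pvalue
from .errors import AnalysisError, ValidationError
from .singletrial import ClusterResult, DEFAULT_WINDOW_MS, _window_mask, bonferroni


@dataclass
class GroupHerSet:
    """Per-subject pair of condition-average HER traces on a shared axis."""

    high: np.ndarray  # (n_subjects, n_samples)
    low: np.ndarray
    time_ms: np.ndarray
    scale: str = ""

    def __post_init__(self) -> None:
        self.high = np.asarray(self.high, dtype=float)
        self.low = np.asarray(self.low, dtype=float)
        if self.high.shape != self.low.shape:
            raise ValidationError("high and low traces must share shape")
        if self.high.shape[1] != len(self.time_ms):
            raise ValidationError("traces must share the time axis")

    @property
    def n_subjects(self) -> int:
        return self.high.shape[0]


def median_split(ratings: np.ndarray) -> np.ndarray:
    """Label each trial "high" (> median) or "low" (< median).

    Trials tied at the median are assigned alternately, in trial order,
    to whichever group is currently smaller (ties broken toward "high"),
    so the final counts differ by at most one.  The split depends only on
    rating ranks, hence is invariant under monotone transforms.
    """
    r = np.asarray(ratings, dtype=float)
    if r.size < 4:
        raise AnalysisError("need at least 4 trials for a median split")
    if np.all(r == r[0]):
        raise AnalysisError("constant ratings cannot be median split")
    med = np.median(r)
    labels = np.empty(r.size, dtype=object)
    labels[r > med] = "high"
    labels[r < med] = "low"
    n_high = int((r > med).sum())
    n_low = int((r < med).sum())
    for i in np.flatnonzero(r == med):
        if n_high <= n_low:
            labels[i] = "high"
            n_high += 1
        else:
            labels[i] = "low"
            n_low += 1
    return labels.astype(str)


def group_cluster_ttest(
    group: GroupHerSet,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    cluster_alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = 0,
    exact: bool = False,
    n_scales: int = 1,
    estimator: str = "plus_one",
) -> ClusterResult:
    """Cluster-based paired t-test of high vs low condition traces.

    Permutations flip each subject's condition sign independently
    (exchangeability within subject only).  ``exact=True`` enumerates all
    2^n sign patterns.  ``n_scales`` applies a Bonferroni factor to the
    Monte Carlo p-values (x2 when both rating scales are tested).
    """
    s = group.n_subjects
    if s < 5 and not exact:
        raise ValidationError("need at least 5 subjects")
    diff = group.high - group.low
    time_ms = np.asarray(group.time_ms, dtype=float)
    wmask = _window_mask(time_ms, window_ms)
    wtime = time_ms[wmask]
    d = diff[:, wmask]
    # same arithmetic as the permutation path below, so an identity sign
    # pattern ties the observed statistic exactly
    ss = (d**2).sum(axis=0)
    m0 = d.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = m0 / np.sqrt((ss - s * m0**2) / (s - 1) / s)
    t_crit = float(scipy.stats.t.ppf(1 - cluster_alpha / 2, s - 1))
    clusters = find_clusters(t_obs, t_crit, wtime)
    if not clusters:
        return ClusterResult(
            [], cluster_alpha, 0, window_ms, seed,
            status="no candidate clusters", t_crit=t_crit,
        )

    if exact:
        if s > 16:
            raise ValidationError("exact enumeration limited to n <= 16 subjects")
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=s)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice((1.0, -1.0), size=(n_perm, s))
    m = flips @ d / s
    with np.errstate(invalid="ignore", divide="ignore"):
        tmat = m / np.sqrt((ss - s * m**2) / (s - 1) / s)
    null_max, null_min = extreme_cluster_sums(tmat, t_crit)
    for c in clusters:
        nulls = null_max if c.sign > 0 else null_min
        c.p_mc = mc_pvalue(c.sum_t, nulls, c.sign, estimator)
        c.p_corrected = bonferroni(c.p_mc, n_scales)
    return ClusterResult(
        clusters, cluster_alpha, len(flips), window_ms, seed,
        t_crit=t_crit, null_max=null_max, null_min=null_min,
    )
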