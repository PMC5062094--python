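"""Single-trial HER-rating correlation statistics.

Per-timepoint Pearson correlation between trial HER amplitude and
ratings, cluster-based permutation significance restricted to a post
R-peak window (default 300-600 ms), Bonferroni correction across
recording sites, and the heart-rate confound check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .cluster import Cluster, extreme_cluster_sums, find_clusters, mc_pvalue, t_from_r
from .errors import AnalysisError, ValidationError

DEFAULT_WINDOW_MS = (300.0, 600.0)


@dataclass
class CorrTimeCourse:
    """Pearson r and its t-statistic at every sample of the epoch."""

    r: np.ndarray
    t: np.ndarray
    n_trials: int
    time_ms: np.ndarray


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_alpha: float
    n_perm: int
    window_ms: tuple[float, float]
    seed: int | None
    status: str = "ok"  # "ok" | "no candidate clusters"
    t_crit: float = float("nan")
    null_max: np.ndarray | None = None
    null_min: np.ndarray | None = None

    def significant_clusters(
        self, alpha: float = 0.05, tail_corrected: bool = True
    ) -> list[Cluster]:
        """Clusters significant at two-tailed level ``alpha``.

        ``p_mc`` is a per-tail probability (each cluster is compared only
        to its own-sign extreme distribution, as reported); declaring
        two-tailed significance therefore compares it against alpha/2
        (the standard correct-tail convention), which calibrates the
        family-wise null rate at alpha.  ``tail_corrected=False`` uses
        the literal per-tail comparison p_mc < alpha.
        """
        thr = alpha / 2 if tail_corrected else alpha
        return [c for c in self.clusters if c.p_mc is not None and c.p_mc < thr]


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = np.nan
    return z


def correlation_timecourse(
    her: np.ndarray, ratings: np.ndarray, time_ms: np.ndarray
) -> CorrTimeCourse:
    """Across-trials Pearson correlation at each time sample.

    ``her`` is (n_trials, n_samples); ``ratings`` is aligned per trial.
    Both are z-scored before the product (numerically irrelevant to r,
    enforced for fidelity).  Samples where the HER has zero variance
    across trials yield NaN, never a silent zero.
    """
    her = np.asarray(her, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    n = her.shape[0]
    if n < 4:
        raise AnalysisError("need at least 4 trials to correlate")
    if ratings.shape != (n,):
        raise ValidationError("ratings must align one-to-one with trials")
    if ratings.std() == 0:
        raise AnalysisError("ratings have zero variance; correlation undefined")
    y = (ratings - ratings.mean()) / ratings.std()
    x = _zscore_cols(her)
    r = y @ x / n
    r = np.clip(r, -1.0, 1.0)
    return CorrTimeCourse(r=r, t=t_from_r(r, n), n_trials=n, time_ms=np.asarray(time_ms))


def _window_mask(time_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    w0, w1 = window_ms
    if w0 < time_ms[0] - 1e-9 or w1 > time_ms[-1] + 1e-9:
        raise ValidationError(
            f"window {window_ms} ms outside epoch time axis "
            f"[{time_ms[0]}, {time_ms[-1]}] ms"
        )
    return (time_ms >= w0 - 1e-9) & (time_ms <= w1 + 1e-9)


def _permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator, exact: bool
) -> np.ndarray:
    if exact:
        if math.factorial(n) > 50_000:
            raise ValidationError("exact enumeration is only supported for n <= 8")
        return np.array(list(itertools.permutations(range(n))), dtype=int)
    return np.array([rng.permutation(n) for _ in range(n_perm)], dtype=int)


def cluster_permutation_correlation(
    her: np.ndarray,
    ratings: np.ndarray,
    time_ms: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    cluster_alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = 0,
    exact: bool = False,
    estimator: str = "plus_one",
) -> ClusterResult:
    """Cluster-based permutation test of the HER-rating correlation.

    Samples inside ``window_ms`` whose correlation t exceeds the
    two-tailed critical value at ``cluster_alpha`` are clustered by
    temporal adjacency; each cluster's summed t is compared with the
    distribution of extreme (max positive / min negative, own tail)
    cluster sums obtained by shuffling the ratings across trials
    ``n_perm`` times.  With ``exact=True`` all n! permutations are
    enumerated instead (n <= 8).
    """
    if n_perm < 100 and not exact:
        raise ValidationError("n_perm must be at least 100")
    tc = correlation_timecourse(her, ratings, time_ms)
    n = tc.n_trials
    wmask = _window_mask(np.asarray(time_ms, dtype=float), window_ms)
    wtime = np.asarray(time_ms, dtype=float)[wmask]
    t_crit = float(scipy.stats.t.ppf(1 - cluster_alpha / 2, n - 2))

    clusters = find_clusters(tc.t[wmask], t_crit, wtime)
    if not clusters:
        return ClusterResult(
            [], cluster_alpha, 0 if exact else n_perm, window_ms, seed,
            status="no candidate clusters", t_crit=t_crit,
        )

    rng = np.random.default_rng(seed)
    perms = _permutation_indices(n, n_perm, rng, exact)
    y = np.asarray(ratings, dtype=float)
    yz = (y - y.mean()) / y.std()
    xz = _zscore_cols(np.asarray(her, dtype=float)[:, wmask])
    rmat = np.clip(yz[perms] @ xz / n, -1.0, 1.0)
    tmat = t_from_r(rmat, n)
    null_max, null_min = extreme_cluster_sums(tmat, t_crit)

    for c in clusters:
        nulls = null_max if c.sign > 0 else null_min
        c.p_mc = mc_pvalue(c.sum_t, nulls, c.sign, estimator)
    return ClusterResult(
        clusters, cluster_alpha, len(perms), window_ms, seed,
        t_crit=t_crit, null_max=null_max, null_min=null_min,
    )


def bonferroni(p_mc: float, n_tests: int) -> float:
    """min(1, p * n_tests); accounts for the number of sites/scales tested."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return min(1.0, p_mc * n_tests)


def apply_bonferroni(result: ClusterResult, n_tests: int) -> ClusterResult:
    for c in result.clusters:
        if c.p_mc is not None:
            c.p_corrected = bonferroni(c.p_mc, n_tests)
    return result


def heart_rate_control(
    rr_per_trial: np.ndarray, ratings: np.ndarray
) -> dict[str, float]:
    """Pearson correlation between the pre-stimulus RR interval and ratings.

    Returns {r, t, df, p} with t = r sqrt(df) / sqrt(1 - r^2), df = n - 2,
    two-sided p.  A null result here rules out heart rate as a confound
    of the HER-rating correlation.
    """
    rr = np.asarray(rr_per_trial, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if rr.shape != y.shape:
        raise ValidationError("rr_per_trial and ratings must align")
    n = rr.size
    if n < 4:
        raise AnalysisError("need at least 4 trials")
    if rr.std() == 0 or y.std() == 0:
        raise AnalysisError("zero-variance input; correlation undefined")
    r = float(np.corrcoef(rr, y)[0, 1])
    df = n - 2
    t = float(t_from_r(np.array(r), n))
    p = float(2 * scipy.stats.t.sf(min(abs(t), 1e300), df))
    return {"r": r, "t": t, "df": df, "p": p}


def rr_before_stimulus(
    peak_times: np.ndarray, stim_onsets: np.ndarray, min_lead_ms: float = 700.0
) -> np.ndarray:
    """Interval between the two analysed R-peaks preceding each stimulus."""
    from .preprocess import select_prestim_peaks

    out = np.full(len(stim_onsets), np.nan)
    for i, s in enumerate(np.asarray(stim_onsets, dtype=float)):
        sel = select_prestim_peaks(peak_times, s, 2, min_lead_ms)
        if len(sel) == 2:
            out[i] = sel[1] - sel[0]
    return out
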