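"""Temporal clustering primitives shared by the permutation tests.

A cluster is a maximal run of contiguous samples whose t-statistic
exceeds the critical value, all of one sign, characterized by the sum of
its t-values.  NaN statistics are sub-threshold and break clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: finite stand-in for an infinite t (|r| == 1)
T_CAP = 1e12


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # inclusive
    sum_t: float
    sign: int
    p_mc: float | None = None
    p_corrected: float | None = None


def t_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Student t of a Pearson correlation with n-2 df; |r|=1 capped at T_CAP."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    t = np.where(np.isclose(np.abs(r), 1.0), np.sign(r) * T_CAP, t)
    return t


def find_clusters(t: np.ndarray, t_crit: float, time_ms: np.ndarray) -> list[Cluster]:
    """Maximal same-sign supra-threshold runs, with their summed t."""
    t = np.asarray(t, dtype=float)
    out: list[Cluster] = []
    for sign, mask in ((1, t > t_crit), (-1, t < -t_crit)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        gaps = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], gaps + 1))
        ends = np.concatenate((gaps, [idx.size - 1]))
        for s, e in zip(starts, ends):
            a, b = int(idx[s]), int(idx[e])
            out.append(
                Cluster(
                    start_ms=float(time_ms[a]),
                    end_ms=float(time_ms[b]),
                    start_idx=a,
                    end_idx=b,
                    sum_t=float(t[a : b + 1].sum()),
                    sign=sign,
                )
            )
    out.sort(key=lambda c: c.start_idx)
    return out


def _max_run_sums(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-row maximum of run-sums of ``vals`` over contiguous True runs.

    Rows without any run yield 0 (the permutation convention: a
    permutation producing no cluster contributes a null statistic of 0).
    """
    p, t = vals.shape
    fm = np.zeros((p, t + 1), dtype=bool)
    fm[:, :t] = mask
    fv = np.zeros((p, t + 1))
    fv[:, :t] = np.where(mask, vals, 0.0)
    flat_m = fm.ravel()
    flat_v = fv.ravel()
    d = np.diff(flat_m.astype(np.int8), prepend=np.int8(0))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    cs = np.concatenate(([0.0], np.cumsum(flat_v)))
    sums = cs[ends] - cs[starts]
    rows = starts // (t + 1)
    out = np.zeros(p)
    np.maximum.at(out, rows, sums)
    return out


def extreme_cluster_sums(tmat: np.ndarray, t_crit: float) -> tuple[np.ndarray, np.ndarray]:
    """(max positive, min negative) cluster sum per row of a (P, T) t matrix."""
    tmat = np.asarray(tmat, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = tmat > t_crit
        neg = tmat < -t_crit
    max_pos = _max_run_sums(tmat, pos)
    min_neg = -_max_run_sums(-tmat, neg)
    return max_pos, min_neg


def mc_pvalue(
    observed: float,
    null_extremes: np.ndarray,
    sign: int,
    estimator: str = "plus_one",
) -> float:
    """Monte Carlo p of an observed cluster sum against its own-tail nulls.

    Ties count as "at least as extreme".  ``plus_one`` (default) adds the
    observed statistic to the null set, avoiding p = 0; ``proportion``
    is the raw fraction.
    """
    null_extremes = np.asarray(null_extremes, dtype=float)
    n = null_extremes.size
    hits = int(
        (null_extremes >= observed).sum() if sign > 0 else (null_extremes <= observed).sum()
    )
    if estimator == "plus_one":
        return (hits + 1) / (n + 1)
    if estimator == "proportion":
        return hits / n if hits else 1.0 / (n + 1)
    raise ValueError(f"unknown estimator {estimator!r}")
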