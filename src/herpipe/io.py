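"""Tabular and HDF5 readers/writers plus run manifests.

File dialects
-------------
* trials: TSV with columns ``trial_id``, ``stim_onset_s``,
  ``<scale>_rating`` per scale, ``skipped`` (0/1); ratings in [0, 1].
* peaks: TSV with column ``time_s`` (plus ``ibi_s``/``qc_flag`` after QC).
* epochs: HDF5 with per-channel trial x time matrices, the time axis,
  and the exclusion table.
* clusters / time courses / surrogate distributions: TSV.
* manifests: JSON, one per pipeline stage, referencing input hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .ecg import RPeakSeries
from .errors import FileFormatError, ValidationError
from .preprocess import Exclusion, HEREpochs, TrialHER
from .singletrial import ClusterResult


def read_trials(path: str, scales: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a trial table.

    Skipped trials are carried through (downstream stages exclude them);
    an out-of-range or missing rating on a non-skipped trial is an error
    that names the offending row.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("trial_id", "stim_onset_s", "skipped"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column {col!r}")
    rating_cols = [c for c in df.columns if c.endswith("_rating")]
    if scales is not None:
        missing = [s for s in scales if f"{s}_rating" not in df.columns]
        if missing:
            raise FileFormatError(f"{path}: missing rating column(s) for {missing}")
        rating_cols = [f"{s}_rating" for s in scales]
    if not rating_cols:
        raise FileFormatError(f"{path}: no <scale>_rating columns found")
    for col in rating_cols:
        vals = df[col]
        live = df["skipped"] == 0
        bad_na = live & vals.isna()
        if bad_na.any():
            row = int(np.flatnonzero(bad_na)[0])
            raise ValidationError(f"{path}: missing rating {col!r} on row {row}")
        bad = live & ((vals < 0) | (vals > 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path}: rating {col!r} out of [0, 1] on row {row} ({vals.iloc[row]})"
            )
    return df


def write_trials(path: str, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.10g")


def analyzable_ratings(trials: pd.DataFrame, scale: str, trial_ids: np.ndarray) -> np.ndarray:
    """Ratings of ``scale`` aligned to ``trial_ids``; skipped trials refuse."""
    col = f"{scale}_rating"
    if col not in trials.columns:
        raise ValidationError(f"no ratings for scale {scale!r}")
    sub = trials.set_index("trial_id").loc[list(trial_ids)]
    if (sub["skipped"] != 0).any():
        raise ValidationError("requested ratings include skipped trials")
    return sub[col].to_numpy(dtype=float)


def write_peaks(path: str, peaks: RPeakSeries) -> None:
    df = pd.DataFrame({"time_s": peaks.times})
    if peaks.qc_flags is not None:
        df["ibi_s"] = np.concatenate([peaks.ibi, [np.nan]])
        df["qc_flag"] = np.concatenate([peaks.qc_flags.astype(int), [0]])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peaks(path: str) -> RPeakSeries:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise FileFormatError(f"{path}: missing column 'time_s'")
    flags = df["qc_flag"].to_numpy(dtype=bool)[:-1] if "qc_flag" in df.columns else None
    return RPeakSeries(times=df["time_s"].to_numpy(dtype=float), qc_flags=flags)


def write_epochs_h5(path: str, her: TrialHER, epochs: HEREpochs | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = her.sample_rate
        f.attrs["channel_labels"] = her.channel_labels
        f.create_dataset("time_ms", data=her.time_ms)
        g = f.create_group("trial_her")
        g.create_dataset("data", data=her.data)
        g.create_dataset("trial_ids", data=her.trial_ids)
        g.create_dataset("epochs_per_trial", data=her.epochs_per_trial)
        g.create_dataset("dropped_trials", data=np.array(her.dropped_trials, dtype=int))
        if epochs is not None:
            e = f.create_group("exclusions")
            ex = epochs.excluded
            e.create_dataset("epoch_index", data=np.array([x.epoch_index for x in ex]))
            e.create_dataset("trial_id", data=np.array([x.trial_id for x in ex]))
            e.create_dataset(
                "channel",
                data=np.array([x.channel for x in ex], dtype=h5py.string_dtype()),
            )
            e.create_dataset(
                "reason",
                data=np.array([x.reason for x in ex], dtype=h5py.string_dtype()),
            )
            e.create_dataset(
                "incomplete_trials", data=np.array(epochs.incomplete_trials, dtype=int)
            )


def read_epochs_h5(path: str) -> TrialHER:
    with h5py.File(path, "r") as f:
        g = f["trial_her"]
        return TrialHER(
            data=g["data"][()],
            time_ms=f["time_ms"][()],
            trial_ids=g["trial_ids"][()],
            channel_labels=[
                s.decode() if isinstance(s, bytes) else s
                for s in f.attrs["channel_labels"]
            ],
            sample_rate=float(f.attrs["sample_rate"]),
            epochs_per_trial=g["epochs_per_trial"][()],
            dropped_trials=[int(x) for x in g["dropped_trials"][()]],
        )


def write_exclusions_tsv(path: str, excluded: list[Exclusion]) -> None:
    pd.DataFrame([asdict(x) for x in excluded]).to_csv(path, sep="\t", index=False)


def write_clusters_tsv(
    path: str, result: ClusterResult, site: str = "", scale: str = ""
) -> None:
    rows = [
        {
            "site": site,
            "scale": scale,
            "start_ms": c.start_ms,
            "end_ms": c.end_ms,
            "sum_t": c.sum_t,
            "sign": c.sign,
            "p_mc": c.p_mc,
            "p_corrected": c.p_corrected,
            "status": result.status,
        }
        for c in result.clusters
    ] or [
        {
            "site": site, "scale": scale, "start_ms": np.nan, "end_ms": np.nan,
            "sum_t": np.nan, "sign": 0, "p_mc": np.nan, "p_corrected": np.nan,
            "status": result.status,
        }
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_timecourse_tsv(path: str, time_ms, r, t, site: str = "", scale: str = "") -> None:
    pd.DataFrame(
        {"site": site, "scale": scale, "time_ms": time_ms, "r": r, "t": t}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str,
    stage: str,
    params: dict,
    inputs: list[str] | None = None,
    seeds: dict | None = None,
    timestamp: bool = True,
) -> dict:
    """Write a JSON run manifest tying outputs to inputs and parameters.

    Result files are deterministic under fixed seeds; wall-clock
    timestamps live only here (disable with ``timestamp=False`` when
    byte-identical manifests are needed).
    """
    manifest = {
        "stage": stage,
        "software": f"herpipe {__version__}",
        "params": params,
        "seeds": seeds or {},
        "inputs": {p: file_sha256(p) for p in (inputs or [])},
    }
    if timestamp:
        manifest["created_unix"] = time.time()
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")
    return manifest
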