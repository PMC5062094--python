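# herpipe

Heartbeat-evoked response (HER) analysis pipeline for electrophysiology
with a simultaneous ECG channel:

- **R-peak detection** by sliding Pearson correlation of the z-scored ECG
  with a patient-specific QRS template, plus interbeat-interval QC;
- **preprocessing**: zero-phase Butterworth band-pass (0.5–25 Hz by
  default), anti-aliased downsampling, bipolar re-referencing along
  electrode shafts;
- **heartbeat-locked epoching**: −100…600 ms epochs around the two
  R-peaks preceding each stimulus by ≥ 700 ms, amplitude/dynamic-range
  artifact rejection, one averaged HER per trial and recording site;
- **single-trial statistics**: per-timepoint Pearson correlation between
  HER amplitude and continuous trial ratings, cluster-based permutation
  test restricted to 300–600 ms post R-peak (10 000 rating shuffles by
  default, max/min cluster-sum null distributions), Bonferroni
  correction across sites, heart-rate confound check;
- **surrogate-heartbeat control**: reassigns each trial's pair of
  heartbeat timings to another trial (stimulus-relative), re-runs
  epoching/rejection/statistics, and tests whether the observed extreme
  cluster survives — distinguishing heartbeat-locked effects from slow
  rating-correlated activity;
- **group-level analysis**: median split of ratings into high/low
  condition averages per subject, cluster-based paired t-test with
  within-subject sign-flip permutations;
- **synthetic session generator** producing ECG with realistic QRS/T
  morphology and heart-rate variability, neural channels with 1/f
  background noise, a heartbeat-locked evoked component whose amplitude
  covaries with ratings by a configurable slope (with a closed-form
  implied per-sample correlation), optional cardiac-field artifact
  (strictly < 300 ms post R), epoch corruption, and a non-heartbeat-
  locked slow drift confound — all with ground truth for testing.

Reported cluster `p_mc` values are per-tail Monte Carlo probabilities
(each cluster compared to its own-sign extreme distribution). Declaring
two-tailed significance at level α uses the standard correct-tail
convention `p_mc < α/2` (`ClusterResult.significant_clusters`), which
calibrates the family-wise null rate at α.

## CLI

Every subcommand writes a JSON run manifest (parameters, seeds, input
SHA-256 hashes) next to its outputs; result files are byte-identical
under fixed `--seed`.

```sh
herpipe simulate  --seed 1 --out sim/ --n-trials 40 --coupling-r -0.5
herpipe rpeaks     --recording sim/recording.edf --out peaks.tsv --threshold 0.7
herpipe preprocess --recording sim/recording.edf --peaks peaks.tsv \
                   --trials sim/trials.tsv --out epochs.h5
herpipe analyze    --epochs epochs.h5 --trials sim/trials.tsv \
                   --scale I --window 300 600 --n-perm 10000 --seed 1 --out res/
herpipe surrogate  --recording sim/recording.edf --peaks peaks.tsv \
                   --trials sim/trials.tsv --scale I --site SITE1 \
                   --n-perm 1000 --seed 1 --out surr
herpipe group      --traces group_traces.tsv --n-scales 2 --out grp
herpipe report     --clusters res/clusters_SITE1_I.tsv --surrogate surr.json
```

File dialects: continuous data as EDF (ECG channel labelled `ECG`,
neural sites `SITE1…`); trials as TSV (`trial_id`, `stim_onset_s`,
`<scale>_rating`, `skipped`); peaks as TSV (`time_s`, IBI QC flags);
epochs as HDF5; clusters/time courses/surrogate nulls as TSV; manifests
and summaries as JSON.

## Python API sketch

```python
import herpipe as hp

cfg = hp.SimConfig(n_trials=40, coupling_beta=hp.beta_for_implied_r(-0.5, hp.SimConfig()), seed=1)
rec, trials, truth = hp.simulate_session(cfg)
peaks = hp.detect_peaks(rec)                      # template matching + IBI QC
her, ratings, result = hp.analyze_session(rec, peaks.times, trials, "I", "SITE1")
for c in result.significant_clusters():
    print(c.start_ms, c.end_ms, c.sum_t, c.p_mc)
surr = hp.surrogate_heartbeat_test(hp.bandpass(rec), peaks.times, trials, "I", "SITE1")
```
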