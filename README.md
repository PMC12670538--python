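# striosync

Analysis pipeline for T-maze visual-discrimination electrophysiology in
rats: behavioral learning stages, trajectory judgment points, striatal /
thalamic / cortical unit characterization, 4 Hz and theta LFP
synchronization, and spike phase locking — together with a synthetic
session generator that gives every estimator a ground-truth recovery test.

## The scientific problem

Rats learning a two-choice visual discrimination in a T-maze commit to an
arm somewhere along a wide central "judgment zone". As learning
progresses, success rate rises, reaction time falls, and the trajectory
bifurcation point moves earlier. Simultaneous recordings from posterior
striatum (pStr), visual thalamus (dLGN) and visual cortex (VC) pose
questions this package operationalizes:

* **Where is the judgment point?** The earliest normalized distance at
  which left- vs right-choice trajectories differ, decided by a
  permutation test with pointwise and *globally corrected* significance
  bands: labels are permuted (5000 times), per-position null quantile
  bands are built, and the band level is widened until at most 5% of null
  datasets exit it anywhere.
* **What are the learning stages?** Ward hierarchical clustering of
  (success rate, reaction time) over consecutive session triplets into
  early / middle / late, ordered behaviorally.
* **What kind of unit is this?** Spike width at one third of the
  trough-to-peak amplitude, mean rate, and PROP(ISI>2s) classify units
  into regular-spiking (putative projection neurons), fast-spiking
  (putative interneurons) and tonically active cells; rate maps are
  occupancy-normalized on normalized distance, stimulus selectivity uses
  the permutation bands, and spatial information is the Skaggs per-spike
  quantity `I = Σ_i p_i (λ_i/λ̄) log2(λ_i/λ̄)` in bits/spike.
* **How synchronized are the regions?** Morlet wavelet power and smoothed
  magnitude-squared wavelet coherence in the 2–5 Hz ("4 Hz") and 6–10 Hz
  (theta) bands; Kendall's tau between band amplitude and running speed.
* **Do spikes lock to the oscillation?** Per-spike Hilbert phases against
  any region's band-limited LFP; Rayleigh statistic `Z = R²/n`; fractions
  of locked units with exact Clopper–Pearson intervals; `log Z`
  distributions compared across stages by Kolmogorov–Smirnov.

Conventions: phases are degrees in [0, 360) with 0° at the oscillation
peak and 180° at the trough; positions are normalized distance in [0, 1]
over 50 bins; all timestamps are seconds on one session clock. See
`docs/methods.md` for the full model and estimator documentation.

## Worked example

The numbered drivers under `analysis/` simulate a 9-session cohort
(success 0.55 → 0.95, reaction time 3.5 → 1.5 s, trajectory bifurcation at
0.5, late-stage pStr–dLGN 4 Hz coherence raised 0.3 → 0.6, units locked to
the dLGN 4 Hz rhythm at 300°) and run each pipeline stage over it:

```bash
python analysis/01_simulate.py            # sessions -> scratch/sessions/
python analysis/02_behavior_stages.py     # -> results/sessions.csv
python analysis/03_unit_characterization.py
python analysis/04_lfp_synchronization.py
python analysis/05_phase_locking.py
```

Output of `02_behavior_stages.py` (abridged):

```
 session_index  success_rate  reaction_time_median  judgment_distance  stage
             0          0.60                  3.58               0.51  early
             4          0.75                  2.46               0.53 middle
             8          0.95                  1.52               0.53   late
judgment distance (programmed 0.5): mean 0.520
stages: ['early', 'early', 'early', 'middle', 'middle', 'middle',
         'late', 'late', 'late']
```

The detected judgment points sit within one bin of the programmed
bifurcation, and the stage clustering recovers the programmed learning
plateaus exactly. Downstream, `03` reports 98.8% RS/FS label accuracy
against ground truth and median spatial information 1.30 bits/spike for
tuned RS units vs 0.09 for untuned FS units; `04` recovers the staged
pStr–dLGN 4 Hz coherence as 0.32 / 0.43 / 0.57 (programmed
0.3 / 0.4 / 0.6) with theta coherence flat; `05` reports the locked
fraction per stage with Clopper–Pearson intervals and a median preferred
phase of 300.2° against the programmed 300°.

A `striosync` CLI wraps the same pipeline
(`striosync simulate|stages|units|lfp|phase|report`, with `--config`,
`--seed`, `--out`).

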