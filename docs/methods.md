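# Methods

This note documents the models, estimators, conventions and numerical
choices implemented in `striosync`, and what the synthetic-data tests do
and do not establish about real recordings.

## Setting

The package analyzes sessions from a T-maze visual-discrimination task in
rats: in a wide central "judgment zone", two monitors show a white (Stim 1)
or black (Stim 2) cue; the animal runs forward and commits to the left
(Stim 1) or right (Stim 2) arm for a water reward. Recorded quantities per
session are trial events from infrared sensors (zone entry, zone exit,
reward-port arrival), head tracking, spike times plus mean waveforms of
sorted units in posterior striatum (pStr), visual thalamus (dLGN) and
visual cortex (VC), and LFPs from the same regions at 1.25 kHz.

Because traversal durations vary (coefficient of variation about 18%),
position-resolved quantities are expressed on **normalized distance**: 0 at
the judgment-zone entry sensor, 1 at the exit sensor, discretized into 50
half-open bins `[i/50, (i+1)/50)` (the last bin closed). Phases are degrees
in [0, 360), cosine-referenced: 0° at an oscillation peak, 180° at the
trough. Preferred-phase values are meaningful only relative to this
convention.

## Permutation-band inference (`resampling`)

The shared inferential engine tests where two families of curves (left vs
right lateral trajectories; Stim 1 vs Stim 2 rate curves; early vs late
population curves) differ, treating trials (or units) as exchangeable.

Given curves `x_1..x_n` on a common grid and two-level labels, the observed
statistic is the per-position difference of level means. Labels are
permuted (`n_perm = 5000` by default) and the difference recomputed; the
observed assignment is a member of the null set, so pointwise p-values are
rational counts `2k/N` with `N = n_perm + 1` and can never be zero. Ties
are counted into both tails, which can only widen bands. Significance is
declared at `p <= alpha` (`alpha = 0.05`).

The **pointwise band** is the per-position empirical `(alpha/2,
1 - alpha/2)` quantile band of the null differences. The **global band**
corrects for the family of positions: for each null dataset the minimal
pointwise p attained anywhere is recorded, and the band level is lowered to
the largest achievable `alpha' <= alpha` at which no more than a fraction
`alpha` of null datasets exits the band anywhere. The achieved familywise
level is reported (`global_alpha_achieved`) rather than pretending `alpha`
is met exactly on the discrete grid of attainable levels. Both masks
(pointwise and global) are always reported; downstream "significant"
decisions (judgment point, stimulus selectivity, stage contrasts) use the
global mask.

A discreteness consequence worth knowing: with `P` effectively independent
positions the smallest attainable familywise level is about
`1 - (1 - 2/N)^P`. At `n_perm = 1000` and 50 noisy positions this exceeds
5%, so the global band becomes empty (no rejections — conservative, never
anticonservative). The default `n_perm = 5000` resolves 50 bins
comfortably. An exhaustive mode enumerates all `C(n, n_A)` assignments
(capped at 10^6) and is the oracle the Monte-Carlo engine is tested
against.

The **judgment point** is the earliest grid position opening a run of at
least `k = 3` consecutive globally significant bins (the run length is a
config knob; a single isolated bin is not a divergence). Judgment time is
the median latency from zone entry to the first crossing of that position.

## Behavior (`behavior`)

Reaction time is `t_choice - t_entry` (zone entry to reward-port arrival);
success rate is the fraction of correct trials. Running speed is the
per-step travel distance over the time step, smoothed with a Gaussian
kernel of sigma = 2 samples; smoothing never crosses tracking gaps.

Learning stages are found by agglomerative clustering (Ward linkage,
Euclidean distance) of (success rate, median reaction time) over
consecutive session sets (disjoint triplets by default; sliding windows by
flag). Features are z-scored before clustering — they are incommensurate
(unitless vs seconds) — with a flag to disable. The tree is cut at three
clusters, and clusters are mapped to early/middle/late by *behavior*
(descending mean reaction time: early = slowest), never by dendrogram leaf
order, which is arbitrary.

Sample skewness is the moment estimator `g1 = m3 / m2^(3/2)` (no bias
correction), with D'Agostino's skewness test as the companion symmetry
test.

## Unit characterization (`units`)

**Spike width** is the time the mean waveform spends below one third of the
trough-to-peak amplitude: with baseline `b` (pre-trough median), trough `v`
and post-trough peak `p`, the level is `b - (p - v)/3` and the width is the
contiguous duration around the trough below that level, with the two
crossings located by linear interpolation (so widths are not quantized to
the sample period). **PROP(ISI>2s)** is the summed duration of inter-spike
intervals longer than 2 s divided by total recording time; for fewer than
two spikes it is reported as 1.0 with a warning (the whole record is one
long gap) — a convention, not a claim about how ambiguous units should be
treated.

Classification is rule-based with config-exposed thresholds (defaults
`w0 = 0.55 ms`, `r0 = 2 Hz`, `p0 = 0.05`, calibrated on the synthetic
population; the real-data boundary values are free parameters): FS if the
spike is narrow (`width < w0`) and fast (`rate >= r0`); TAN (tonically
active, putative cholinergic) if the spike is broad and PROP(ISI>2s) is
below `p0`; everything else RS (putative medium spiny neuron). TANs are
merged into FS by default, mirroring the treatment of that small
population. Mean rate for classification is computed over the whole
session, not zone-restricted.

**Rate maps** divide in-zone spike counts by occupancy time per
normalized-distance bin (spikes are assigned the bin of the nearest
tracking sample); `rate x occupancy = count` holds exactly per bin, and
zero-occupancy bins are masked, not zero-filled. **Stimulus selectivity**
runs the permutation-band test on per-trial rate curves labeled Stim 1/2; a
unit is selective if any position is globally significant.

**Spatial information** is the occupancy-weighted per-spike information
(Skaggs form), `I = sum_i p_i (r_i/R) log2(r_i/R)` in bits/spike, over
occupied bins, with `p_i` occupancy probability and `R` the
occupancy-weighted mean rate. This is the standard quantity carrying the
bits/spike unit; a binned full mutual information would need a different
contract (it is not provided). `I` is invariant to uniform rate rescaling
and zero iff the map is flat over occupied bins.

## LFP (`lfp`)

Band-limited signals use an order-3 Butterworth filter applied
forward-backward (zero phase), bands 2–5 Hz ("4 Hz") and 6–10 Hz (theta);
instantaneous phase and envelope come from the Hilbert analytic signal.

Time-frequency quantities use the continuous Morlet transform
(center-frequency parameter `omega0 = 6`), computed through PyWavelets'
`cmor` wavelet, which is L2-normalized across scale — white noise has flat
expected power over frequency in this convention, and amplitudes scale
quadratically into power. The cone of influence (one e-folding time
`sqrt(2) * s` per edge, `s = omega0 / 2 pi f`) is masked from every band
mean.

Wavelet coherence is `|S(Wa conj Wb)|^2 / (S|Wa|^2 S|Wb|^2)` with the
smoothing operator S a Gaussian over time of sigma = 6 oscillation cycles
at each frequency, then a 3-scale boxcar. The smoothing extent is the
bias/variance dial of this estimator: with these defaults the zero-
coherence bias is about 0.09 and programmed coherences 0.6/1.0 are
recovered as 0.60/0.97 on 10-minute traces. Band means of coherence are
computed on an in-band scale grid so the scale boxcar does not mix the
neighboring band (theta leaking into the 5 Hz edge would otherwise bias
the 4 Hz mean downward). For band-mean purposes traces are FIR-decimated
to 125 Hz first; all analysis bands sit far below the decimated Nyquist.

Amplitude–speed coupling is Kendall's tau-b between a band envelope and
running speed after resampling both to a common 10 Hz grid over their
overlapping support.

## Phase locking (`phaselock`)

Spike phases are nearest-sample lookups on the Hilbert phase of the
reference region's band-limited LFP, restricted by default to judgment-zone
epochs (whole-session by flag; the epoch choice is a documented option
because the source analyses' epoch is a free parameter). The Rayleigh
statistic is `Z = R^2 / n` with `R` the resultant length of the unit phase
vectors, `p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))` (the standard
approximation), and the preferred phase is the resultant direction. Units
with fewer than 50 in-epoch spikes are marked unreliable (threshold
config-exposed; no principled value exists, 50 keeps the Rayleigh
approximation and the phase estimate stable).

Population summaries report, per stage and reference region, the fraction
of units with `p < 0.05` with exact Clopper–Pearson 95% intervals, the
empirical distribution of `log Z` compared across stages by two-sample
Kolmogorov–Smirnov tests, and circular preferred-phase histograms (18 bins,
per-unit max normalization by default).

One property of this analysis (inherent, not a bug): spike phases of a
*narrowband* reference sampled by temporally clustered spikes are mildly
dependent, so the Rayleigh test runs slightly hot — the measured null flag
rate is ~5–7% at nominal 5%. The acceptance checks bound it at
`0.05 + 2 SE`.

## Group comparisons (`stats_util`)

An omnibus ANOVA (one-way, repeated-measures, or two-way with type-II sums
of squares via statsmodels) gates nonparametric post-hocs: Wilcoxon
signed-rank within subjects, rank-sum between groups. No further
multiple-testing correction is applied beyond the gate — deliberately, to
match the contract of the reports this package produces. All tests are
two-tailed.

## Synthetic sessions (`synth`)

The generator realizes the structures the analyses assume, with every
parameter recorded as ground truth:

* **Behavior** — equiprobable stimuli; choice correct with the session's
  programmed probability (default learning curve: success 0.5 → 0.95,
  reaction time 4 → 1.5 s, saturating over ~29 sessions with time constant
  8); traversal durations log-normal with CV 0.18 around the stage mean;
  trajectories identical in expectation before the programmed bifurcation
  distance (default 0.5) and linearly diverging after it to ±15 maze units
  at the end of a 100-unit zone, plus i.i.d. Gaussian tracking noise
  (default SD 0.5 units at 50 Hz).
* **LFP** — each region is `a_r s4 + b_r p4_r + theta_r (1 + g v(t)) +
  noise`, where `s4` and `p4_r` are unit-variance white-noise processes
  band-passed to 2–5 Hz (order-3 Butterworth, forward-backward; narrowband
  noise, not sinusoids, so coherence and phase estimates are
  nondegenerate), `theta_r` likewise in 6–10 Hz with amplitude multiplied
  by `1 + g * speed`, and the mixing weights `a_r` are solved from the
  three pairwise 4 Hz coherence targets, including a small correction for
  the in-band white-noise floor. Targets violating the positive-
  semidefiniteness of the implied 3x3 coherency structure are rejected.
* **Spikes** — inhomogeneous Poisson by exact thinning of a dominating
  homogeneous process, intensity `r0 * tuning(position) * stim_gain(trial)
  * exp(kappa cos(phase - preferred)) / I0(kappa)`; the position tuning is
  a Gaussian bump normalized to mean 1 over the zone so `r0` stays the
  baseline rate, the stimulus gain applies during Stim 1 zone epochs, and
  the phase factor references the band phase of a chosen region's generated
  LFP. Intensities above 500 Hz are rejected as mis-set gains. Mean
  waveforms are triangular troughs whose width-at-one-third is set
  analytically per class (RS ~0.9 ms, FS ~0.3 ms, with jitter), plus an
  after-bump and small noise. Default RS rates are sparse (0.5–2 Hz,
  matching striatal projection neurons) — this matters because the
  tonically-active rule keys on the scarcity of long ISI gaps.

Fixing the seed fixes every generated byte; per-session streams are spawned
from `(seed, session_index)`.

**What the generator does not emulate:** 1/f background spectra (the noise
floor is white and a free parameter, not a claim about recordings), spike
sorting artifacts and waveform drift, theta phase precession,
cross-frequency coupling, behavioral lapses/omissions, and electrode-level
volume conduction. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative assumptions, not robustness to
every property of real tissue.

## Problem sizes used in tests and the acceptance script

Simulations are scaled to desk size as the package's own test conditions:
judgment recovery over 50–100 sessions of 40 trials; familywise type-I
over 500 null datasets at `n_perm = 1000` (the scan itself shows ~0
rejections because of the discreteness described above); coherence
recovery on 10-minute traces and an 8-subject stage cohort on 3-minute
traces; classification over ~50–150 units; phase locking over 100–500
units of ~200–400 spikes. The batch pipeline in the analysis drivers uses
9 sessions of 20 trials.

## Known limitations

* The global band correction assumes exchangeability of trials between
  levels; trial-order drift within a session is not modeled.
* Rate-map bins a trial never visits are zero-filled when building
  per-trial curves for the selectivity test (the engine needs complete
  curves); with monotone traversals this is rare.
* The Rayleigh null inflation for narrowband references discussed above.
* `two_way_anova` fits fixed effects only; repeated-measures structure in
  two-factor designs is not modeled.
* The CLI's per-stage subcommands run the full dependency chain up to
  their outputs rather than caching intermediate stages.
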