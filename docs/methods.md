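# Methods

## The model

`driftrace` implements a two-component race-to-threshold model of binary
choices that separates *deliberate* (value-guided) from *arbitrary*
(whim-like) decisions, together with the EEG analysis operators needed to
compare the model's movement-locked prediction with readiness-potential
(RP) measurements.

The elementary unit is a leaky stochastic accumulator integrated with
explicit Euler–Maruyama at a fixed step:

    x[i+1] = x[i] + (I − k·x[i])·Δt + c·ξ_i·√Δt,    x[0] = 0

with drift rate `I` (1/s), leak `k` (1/s), noise scale `c` (1/√s),
standard-normal deviates `ξ`, and `Δt = 1 ms`. A decision occurs at the
first sample where the activation reaches the threshold `θ = 0.3`.

Each *choice* is a race between two such accumulators — one for the
alternative rated higher in a prior preference-rating session (the
*congruent* option) and one for the lower-rated (*incongruent*) option.
Each *trial* couples two races:

* a **value (Region X) pair** that decides deliberate trials, and
* a **noise (SMA) pair** — the simulated generator of the signal under
  electrode Cz — that decides arbitrary trials.

During deliberate trials the SMA pair integrates *without* a threshold
(the decision is completed elsewhere), with its drift rates divided by
1.45 (the measured ratio of Cz activity to mean scalp activity) and the
same leak and noise as the deciding pair's condition entry. Its activity
is read out up to the moment the value pair crosses. Because threshold
crossing in the SMA is then statistically independent of movement onset,
time-locking SMA activity to the decision produces only a weak trend —
whereas in arbitrary trials, where the SMA pair itself decides, the same
time-locking produces the classic ramp-to-threshold RP shape. That
dissociation is the scientific point of the model.

Assumptions worth stating: accumulators start at 0 at stimulus onset; the
four accumulators of a trial consume mutually independent noise streams;
there is no across-trial drift variability and no collapsing bound; a tie
at the identical crossing sample (probability of order Δt) is broken by a
fair coin from the trial's seed stream. Trials with no crossing before
`t_max = 20 s` (the behavioural response deadline) are flagged undecided
and excluded from RT/consistency summaries with a logged count.

### Published parameter values

The deciding pair's best-fitting values per condition (threshold fixed at
0.3; deliberate rows are the value pair, arbitrary rows the SMA pair):

| condition        | I_congruent | I_incongruent | k    | c    |
|------------------|------------:|--------------:|-----:|-----:|
| deliberate easy  | 0.23        | 0.06          | 0.52 | 0.08 |
| deliberate hard  | 0.18        | 0.09          | 0.53 | 0.11 |
| arbitrary easy   | 0.24        | 0.21          | 0.53 | 0.22 |
| arbitrary hard   | 0.22        | 0.20          | 0.54 | 0.23 |

A second, nearly equivalent error minimum exists for deliberate-hard at
(0.15, 0.07, 0.21, 0.09); the search can legitimately return either basin.

### Numerics

The update rule is a linear (AR(1)) recurrence, so whole batches of
trials are integrated with `scipy.signal.lfilter` along time, in chunks
of 2000 steps with early stopping once a run's race is decided. This is
exact (identical to the sample-by-sample loop) and is what makes the
grid-search fit tractable. The noiseless special case has the closed-form
first-passage time t* = −ln(1 − θk/I)/k, used as an independent oracle in
the tests; Euler discretisation agrees within 2Δt across the tested grid.

## Fitting

Per condition the fit targets are (a) the cumulative RT distribution,
summarised by a 2-parameter gamma CDF, and (b) the consistency score
(fraction of congruent choices). The gamma is fitted by minimising the
summed squared deviation between its CDF and the empirical CDF on a fixed
0–20 s grid at 1 ms spacing (Nelder–Mead on log-parameters from moment
starts; the SSE objective is evaluated on a uniform 10-fold subsample of
the grid — a Riemann-sum approximation either way — which leaves the
argmin unchanged at the optimizer tolerance). The RT error is one minus
the intersection-over-union of the two gamma-fitted CDF *curves* (areas
under the pointwise min and max on the grid); the consistency error is
the absolute difference of consistencies; the overall error is their
mean. The CDF (not PDF) reading of the overlap and the 1 ms grid are
package choices where the procedure leaves room.

The search is an exhaustive, iteratively zooming grid: four free
parameters — `I_congruent` ∈ [0.05, 0.4], `I_incongruent` expressed as a
fraction ∈ [0.2, 1] of `I_congruent` (the fraction axis stays relative at
every level), `k` ∈ [0.2, 0.55], `c` ∈ [0.01, 0.3] — each sampled at 5
equally spaced points, 1000 simulated trials per grid entry, zooming to
the interval between the argmin's neighbours until every range is below
0.025 or the error is below 0.025. Entries share common random numbers
to damp simulation noise between neighbours; an argmin on a box boundary
logs a warning. `search_trace` records ranges, best entry and errors per
level.

**Identifiability.** The error surface has a flat ridge in the (I, k)
plane: pairs with equal noiseless first-passage time produce RT
distributions that differ by less than the per-entry simulation noise
(~0.002–0.005 at 1000 runs/entry), especially for noise-dominated
(arbitrary-type) targets. Parameter recovery is therefore sharp for the
drifts' scale, the congruent/incongruent ratio and the noise scale, while
the leak coordinate is only constrained jointly with the drift. The
tests check exactly that: coordinate recovery for the identified
parameters, ridge (crossing-time) equivalence for the leak.

## Model RP prediction

For each decided trial the two SMA traces are averaged pointwise (an
electrode sees both) and the last 2000 samples (2 s) strictly before the
crossing form the epoch; trials that decide earlier than 2 s are padded
at the head with missing values, which do not contribute to the average.
The per-sample mean over trials is flipped vertically (negativity up, as
RPs are plotted) and reported in accumulator activation units — no
rescaling to µV and no smoothing in computation. The per-sample count of
contributing trials is reported alongside; it is non-decreasing toward
the crossing, and the value at the crossing sits strictly between −θ and
0 (every winner ends at threshold; the loser dilutes the average).

## ERP pipeline

* **Window convention.** All windows are half-open in samples,
  `[start, end)`; a response-locked [−2, 0.2) s epoch at 512 Hz spans
  1126 samples. The same convention applies to baselines and stat
  windows.
* **Filters.** Zero-phase FIR via `mne.filter`: 0.1 Hz high-pass
  (transition 0.1 Hz; a 0.01 Hz variant is available), 59–61 Hz notch
  (transition 1 Hz at the edges), optional 25 Hz low-pass used as
  anti-aliasing before the trend regressions. Corners at or above
  Nyquist are rejected.
* **Artifacts.** A sample is bad if any channel exceeds ±100 µV, moves
  more than 100 µV peak-to-peak within a 200 ms window, or stays within
  0.5 µV peak-to-peak across a 100 ms window (the flatline rule is read
  as peak-to-peak range; an absolute-amplitude reading is the noted
  alternative). Bad samples are dilated by 150 ms on both sides and mask
  all channels.
* **Trial exclusion.** Wrong-key presses, RT < 200 ms, RT > 10 s, then a
  single (non-iterated) ±3 SD rule on the survivors, per subject ×
  condition.
* **Epoching.** Response- or stimulus-locked; baseline = per-trial,
  per-channel mean over (−1000, −500) ms relative to the stimulus by
  default (a response-locked baseline variant is available), subtracted
  once — the operation is idempotent. Trials overlapping the artifact
  mask or the recording edges are dropped with reason codes; epoch
  counts plus reason counts always equal the input trial count.
* **RP / LRP.** RP: per subject × condition, trial-average Cz waveform
  averaged over the last 500 ms before the response; subjects under 30
  kept trials in a cell are flagged. LRP: per subject, mean C3−C4
  difference in left-hand trials minus the same in right-hand trials
  (exactly antisymmetric under hand-label exchange), summarised over the
  same window.

## Statistics

* **Trend regressions.** Average-level: OLS slope of the subject-average
  waveform against time over the last 1000 ms, after the 25 Hz low-pass
  and 10-fold decimation (every 10th sample; decimation also restores
  approximate residual independence given the 1/f spectrum).
  Single-trial: the same design fitted per trial by IRLS with Tukey
  bisquare weights (max 50 iterations, tolerance 1e-6, OLS fallback with
  a warning), with a one-sided per-subject test of negative mean slope,
  Bonferroni-corrected.
* **Cluster permutation.** One-sample t across subjects per sample;
  maximal runs with |t| > 2 form clusters with mass = Σt; the null is
  built from random per-subject sign flips (default 1000 permutations;
  two-tailed, positive and negative clusters pooled against the max-|mass|
  distribution); p = (count + 1)/(n_perm + 1), so p ≥ 1/(n_perm+1).
  Type-I error is calibrated to 0.05 ± 0.02 over 500 iid-Gaussian null
  datasets in the acceptance suite.
* **Saccades.** Radial signal = mean of the 4 EOG channels band-passed
  30–100 Hz; a saccade is a maximal run of samples deviating from the
  median by more than 2.5 *standardized IQRs* (IQR × 0.7413, i.e. ~2.5
  robust SDs — the factor is the package's reading of "standardized")
  for more than 2 ms; detections closer than 50 ms merge; counts are
  taken over the last 500 ms before each response.
* **Consistency grade.** Mean of per-trial indicators that the chosen
  alternative was the higher-rated one; tied ratings (impossible under
  the pairing rule) are excluded with a warning.

## Synthetic data generator

The generator produces the study conditions end to end: 18 subjects,
2 × 2 conditions (deliberate/arbitrary × easy/hard), 90 trials per
condition; ratings of 50 items on a 1–7 scale with *hard* pairs exactly
1 point apart and *easy* pairs ≥ 4 apart; gamma RTs (shape 6, a
realistic single-trial RT skew) with condition means 2.13 / 2.52 / 0.98
/ 1.00 s; congruent-choice probabilities 0.99 / 0.83 / 0.54 / 0.49;
balanced response hands; 512 Hz EEG (Cz, C3, C4, Fz, Pz + 4 EOG) with
1/f-shaped noise (exponent 1, 10 µV RMS — typical ongoing-EEG scale).

Injected structure: a linear RP ramp from 0 at −1.2 s to −2.5 µV at the
response (quadratic variant behind a switch; a 0.2 s release back to
baseline avoids a step edge) at Cz with a 0.4 spatial falloff on the
other scalp channels, in **arbitrary trials only**; a lateralized
−1 µV ramp over the final 0.3 s on the electrode contralateral to the
response hand (left hand → C4); saccades as 10 ms, 45 Hz bursts on all
four EOG channels at 3.3/s (after refractory merging and detection this
yields mean counts near 1.7 per 500 ms window, the observed scale);
occasional 60 µV blink transients on the vertical EOG pair and rare
±120 µV artifact spikes that exercise the rejection rules. Trials are
laid out with uniform 1–1.5 s fixation, the response after the trial's
RT, and 1 s of post-response screen.

What the generator does **not** emulate: biophysical head geometry or
realistic scalp topography (the spatial falloff is a free parameter, not
a claim), blink/saccade morphology beyond band-limited transients,
channel-count realism (64-channel montages), non-stationary noise, or
any dependence of the EEG on decision difficulty. Passing tests
therefore show that the analysis operators recover what the generator
puts in at realistic SNR — not that real recordings would behave
identically.

## Problem sizes used by the test suite

Simulation sizes are chosen to keep the full suite comfortably
repeatable on a single CPU: behaviour-moment checks use 2500 trials per
condition; race symmetry uses 10,000 races; parameter-recovery property
tests use a 1-level search at 300 runs/entry on three random truths
(with `t_max` = 4 s for noise-dominated targets, where RTs concentrate
near 1 s); the acceptance recovery test uses the published 5-point,
1000-runs/entry schedule on a 2-level zoom with `t_max` = 8 s; cluster
calibration uses 500 null datasets at 500 permutations; the end-to-end
test runs the full generator defaults (18 × 360 trials). Each choice is
stated where it is used.

## Known limitations

* The race tie-break (fair coin) and loser-trace truncation at the
  winner's crossing are conventions; both affect nothing at the reported
  precision.
* The value pair is not simulated during arbitrary trials by default
  (it is outcome-irrelevant there); a flag exposes it.
* The gamma-CDF overlap error saturates for grossly wrong parameters,
  so the grid search's outer boxes carry little gradient information —
  the published initial ranges matter.
* The arbitrary-hard published entry has the congruent drift above the
  incongruent one, so the simulated congruent win fraction sits slightly
  above 0.5 while the observed consistency is 0.49; the model can
  approach that value only to within its published consistency error
  plus sampling noise.
* EDF input is not supported; EEG travels as the documented HDF5
  container.
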