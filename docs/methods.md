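# Methods

## Scope and data model

The package analyses two kinds of data from an optogenetic fear-extinction
experiment. The electrophysiology arm works on sorted single-unit spike
trains (seconds from recording start) recorded while 473-nm light pulses
stimulate opsin-expressing axon terminals; the behaviour arm works on
per-animal, per-stage percent-freezing tables from fear-renewal designs.
Raw signal processing (filtering, thresholding, spike sorting) and video
freezing scoring are upstream of this package and out of scope: the inputs
are NeuroSuite-style `.res`/`.clu` spike files (one integer sample index per
line; `.clu` carries a cluster-count header; clusters 0 and 1 are noise and
multi-unit buckets and are dropped by default), pulse-onset CSVs, and
freezing CSVs.

The default sampling rate is 32 556 samples/s. Time is always seconds with
0 at recording start; peri-event quantities are milliseconds relative to
pulse onset.

## Stimulation protocol

One trial is a 5-min baseline followed by 20-Hz pulse trains of 0.5, 1, 5,
and 15 s, each presented once per trial in seed-determined random order and
separated by 30-s gaps, i.e. 10 + 20 + 100 + 300 = 430 pulses per trial.
Pulse width defaults to 10 ms: the pulse offset sits at 10 ms, which is why
the 12-ms test window covers both onset and offset responses. Monosynaptic
onset responses are expected within ~2 ms of the pulse; rebound firing
shortly after the offset.

## The jitter-surrogate responsiveness test

Per unit, the pooled PETH counts spikes in 1-ms half-open bins of relative
time in [0, 12) ms; at 20 Hz the display windows ([-25, 50) ms by default)
of consecutive pulses overlap, and a spike is counted relative to every
pulse whose window contains it. Each of 100 surrogates displaces every
spike by an independent shift of magnitude U(1, 10) ms; the per-bin
threshold is the nearest-rank 99th percentile of the 100 surrogate counts
(the 99th order statistic), and a bin is significant when the observed
count *strictly* exceeds it, so ties go to non-significance. A unit is
responsive when at least one test bin is significant. No correction is
applied across the 12 bins.

Numerical and design choices:

* **Jitter sign.** Shifts are signed (± with equal probability) by default;
  a positive-only mode is available (`jitter_sign="positive"`), since a
  one-sided displacement is the literal reading of "adding a random shift",
  but it moves the surrogate histograms systematically rightward. Both
  modes are tested.
* **Which spikes are jittered.** All of them, conceptually. A spike whose
  distance to every pulse exceeds jitter_high + test window cannot reach a
  test bin under any admissible shift, so the implementation leaves such
  spikes in place and draws shifts only for the candidates; this is an
  exact shortcut (verified in tests against fully jittered trains), not an
  approximation, and every surrogate train conserves the spike count.
* **Chance level is not 1% per unit.** The observed count exceeds the 99th
  order statistic of 100 exchangeable surrogates with probability up to
  2/101 per bin (reduced by integer-count ties to ~1.5% in practice), and
  12 uncorrected bins are tested, so a stationary unit is called responsive
  with probability ~15-20%. This is a property of the published procedure,
  not a defect of the implementation, and it is why the chance calibration
  below exists. Per-unit detection *decisions* are therefore only
  interpretable relative to that calibration.

Responsive units are typed: *excited* when the earliest significant bin
starts before the pulse offset (10 ms); a later significant bin is an
*inhibited-rebound* response only when the mean firing rate during the
pulse ([0, 10) ms bins) is below the pre-onset baseline rate ([-25, 0) ms
bins), and late excess firing without suppression is still excitation.

z-scored PETHs use the pre-onset bins as baseline (mean/SD of per-bin
rates, sample SD); units with zero baseline SD get a flat z of 0 and a
flag. Population matrices stack responders first, ordered by the latency of
the first significant bin.

## Chance calibration by ISI shuffling

For each of `n_shuffles` replicates (default 100), every unit's inter-spike
interval sequence is randomly permuted — preserving rate, ISI distribution
and burst structure while destroying alignment to the stimulation timeline
— and the full jitter test is re-run. The replicate-wise responsive
fractions estimate the detector's chance level c. The chance-corrected
estimate of the truly stimulus-locked fraction inverts the mixture
observed = θ + (1 − θ)c, i.e. θ̂ = (observed − c)/(1 − c)
(`ShuffleResult.excess_fraction`). Observed-vs-chance fractions across
recording sites are compared with a Wilcoxon signed-rank test (zero
differences dropped; exact null below 26 non-zero pairs, normal
approximation above; the reported statistic is the sum of positive ranks); a
plain sign test is available behind a flag. Sites (animal × penetration)
are the pairing unit because they are the independent replicates of the
acute experiment.

The shuffle pins the first and last spike times exactly and reconstructs
interior times from permuted-ISI prefix sums; float accumulation limits the
ISI-multiset reproduction to ~1e-13 s, far below the sampling resolution.

## Behavioural statistics

Stage values are per-animal means over raw epochs (e.g. "CS 1-4" is the
mean over the first four tone presentations of a session); an animal
missing an epoch is excluded from that stage with a warning. The extinction
criterion is the first day whose CS 1-4 mean is strictly below 60%, and an
animal is retained only if that day is at most 7.

Group comparisons are pooled-variance Student t-tests with
df = n1 + n2 − 2 — the printed df of the published comparisons (12 for
7 + 7) identifies the pooled-variance rather than the Welch form — applied
as planned, uncorrected tests at the stimulation timepoints. Bonferroni and
Holm adjustments are implemented and reported on request, but off by
default to mirror the planned-comparison design. The two control groups
(control virus; opsin without laser) are pooled only when no shared stage
differs at α = 0.05; with six stages and truly identical controls this rule
declines to pool in roughly a quarter of experiments, which is a property
of the rule itself.

Degenerate inputs: identical groups give t = 0, p = 1; zero pooled variance
with unequal means is rejected as degenerate rather than reported as
infinite t.

## Synthetic data: what it emulates and what it does not

* **Background spiking** is a gamma renewal process (ISI shape 1 = Poisson,
  <1 bursty). Population rates are log-uniform over 1-10 Hz and shapes
  uniform over 0.5-1.5 — heterogeneity typical of cortical recordings under
  anaesthesia. It does not model slow non-stationarities (up/down states),
  refractory interactions with injected spikes, or common drive between
  units; the jitter test is insensitive to slow structure by construction,
  so passing tests speak to millisecond-scale locking, not to robustness
  against, e.g., state transitions time-locked to stimulation.
* **Injected responses.** Excited units add, per pulse with probability
  `per_pulse_response_prob` (default 0.3), one spike at onset + 1.5 ms with
  0.2-ms Gaussian latency jitter (truncated positive), keeping the response
  mostly inside one 1-ms bin, like the sharp empirical PETH peaks.
  Inhibited-rebound units delete background spikes within the pulse with
  probability 1 − suppression_factor (default suppression 0.1) and add a
  rebound spike uniformly within 2 ms after the offset, keeping the rebound
  inside the 12-ms window.
* **Freezing tables** draw per-animal stage values from a Normal with
  between-animal SD 10% clipped to [0, 100] (simpler than a beta model and
  adequate for t-statistics); the opsin group's mean drops by
  `laser_stage_delta` (default 20 points) at laser-on stages only, and the
  two control groups share means by construction. Default group sizes are
  10/9/9 (opsin / control virus / opsin-no-laser), matching the retained
  cohort of the renewal experiment the defaults emulate. The generator
  emits stage-level percentages directly and does not model the
  time-sampling video scoring.

All generators are pure functions of (parameters, seed); seeds for
sub-streams are spawned from the master seed, so any replicate is
reproducible in isolation.

## Problem sizes used in the shipped checks

The acceptance checks run one 430-pulse protocol with: 800 stationary 5-Hz
Poisson units and 40 shuffle replicates for the specificity check; a
2000-unit population (8% excited, 4% inhibited-rebound, response
probability 0.3) with 8 shuffle replicates for the recovery check — the
chance-corrected fraction estimate carries ~1 percentage point of
realization noise at that size; 1000 simulated null experiments (and 300
with a 20-point laser-stage effect) for the behavioural calibration. The
`scripts/acceptance.py` run uses 600 null units / 25 replicates and the
same 2000-unit recovery population.

## Known limitations

* The jitter test's pointwise thresholds make single-unit verdicts
  anticonservative in isolation; only chance-calibrated population
  statements are supported.
* Latency information is limited to the first significant 1-ms bin; no
  sub-bin latency estimation, and no spike-transmission inference.
* The ISI shuffle assumes within-unit stationarity of the ISI sequence at
  the session scale; strongly drifting units would make the chance estimate
  conservative.
* `read_res_clu` trusts the declared sampling rate; an incorrect rate
  rescales all latencies silently.
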