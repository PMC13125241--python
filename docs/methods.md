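# Methods

This note records the models behind each stage, the parameters that
matter, and the choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task engine

The task runs in discrete ticks (`tick_ms = 50`) in canonical coordinates:
the avatar's exit at position 0, the corridor extending to
`corridor_length = 200` units, the threat patrolling near the far end.
Only relative speeds matter for the chase/strike logic; the defaults are 2
units/tick for both avatar and pacing threat.

**Attack hazard.** The per-tick attack probability is
`h(d) = hazard_max · BetaCDF(1 − d/L; α, β)` — a beta distribution over
proximity. The CDF form guarantees monotone non-increase in distance and a
[0, hazard_max] range for any admissible shape parameters. Defaults
`α = 6, β = 2, hazard_max = 0.015` were calibrated once against the task's
documented operating point: with the reference threshold agent they
produce roughly 50 attacks per 240-trial session, a mean turnaround
distance of ~35-40 units (~17-20% of the corridor), and attacks that are
genuinely rare beyond ~100 units. Flatter shapes (mass at low proximity)
make attacks so frequent that attack-triggered flight dominates every
behavioral statistic, which contradicts the intended regime where most
turnarounds are voluntary.

**Chase/strike.** Attack outcomes come from a balanced, seeded
chase/strike sequence held at session level and consumed in
attack-trigger order, so the realized split is ~50% no matter when attacks
fire. The strike's capture guarantee is enforced constructively: the
nominal multiplier is 2.5x, and if the geometry at any tick would let a
fleeing avatar reach the exit first, the strike speed for that tick is
raised (5% margin) so capture still occurs. Chases move at patrol speed,
so immediate flight preserves the gap and escapes.

**Counterbalancing.** Each 20-trial block fully crosses avatar side (2) x
threat starting direction (2) x dot-size pattern (4 fixed patterns, two
ending large, two ending small) for its 16 conflict trials, and stratifies
4 conflict-free trials (side x last-dot size) into the block. Dot
positions are evenly spaced with ±5-unit seeded jitter; the patrol zone
starts a jittered ~20-unit buffer beyond the last dot. Session generation
is a pure function of (config, seed).

**Reference agent.** `ThresholdPolicy` approaches until the threat is
within a distance threshold (40 units; 10 units tighter when the deepest
reward is large), flees at attack onset, and treats the turn as a
commitment — once fleeing it does not re-approach. Without commitment an
agent dithers at the threshold boundary, accumulating hazard exposure
until an attack is nearly certain; the committed form is what produces
the documented behavioral regime. Multiple-turn behavior remains available
through custom policies, and the logs record every turn (the final one is
the decision to avoid).

## Synthetic LFP

Each channel is `snr · envelope(t) · oscillator + background (+ bursts)`.

- **Theta oscillator**: AR(2) with spectral peak at 5 Hz and pole radius
  0.95 — a stochastic narrowband process, not a sinusoid, so coherence
  between independent channels fluctuates and permutation nulls are
  meaningful.
- **Background**: spectrally shaped Gaussian noise with 1/f exponent 1.0,
  unit variance.
- **Couplings**: the target channel receives a `gain`-weighted copy of the
  source oscillator delayed by `lag_ms`, added before amplitude
  scheduling. Zero-lag volume conduction is modelled separately by
  `inject_zero_lag_mixing`, an instantaneous invertible mixing of the
  finished signals.
- **Amplitude schedule**: the theta envelope takes the `approach`
  multiplier between movement onset and turnaround and the `avoid`
  multiplier elsewhere, with 200-ms raised-cosine transitions.
- **HFA bursts**: 80-120 Hz band-passed noise under a 300-ms raised-cosine
  window, anchored to a named event.

Trial segments are `[ITI | trial]` with a 1.5-s default ITI; all event
times are stored in ms from segment start. Supported rates are 512, 1000
and 2000 Hz (the two acquisition dialects plus a fast default for
fixtures). Fixture effect sizes (coupling gain 0.8 at 25 ms, 2:1 theta
schedule, burst amplitude 4) are chosen for reliable recovery at desk
scale — 40 trials, a few channels — and documented as such; they are not
estimates of real-data effect sizes. What passing tests show is that the
chain detects structure of this strength and stays calibrated in its
absence; real recordings add nonstationarity, artifacts and far smaller
effects that the generator deliberately does not model (no biophysics, no
epileptiform activity).

## Spectral stage

Continuous data are zero-phase low-pass filtered at 150 Hz (4th-order
Butterworth, forward-backward) and notch-filtered at 60 and 120 Hz.
Bipolar referencing subtracts adjacent contacts. Epochs lock to trial
onset, movement onset, turnaround, attack onset or trial end.

The TFR uses Morlet wavelets on 80 log-spaced frequencies 1-150 Hz with
matched log-spaced cycles 2-30; short epochs use a band-restricted subset
of the same bank (`band_freqs`). Samples within half a wavelet support of
an epoch edge are flagged and excluded from baselines and statistics.
Power is natural-log transformed (the base is immaterial after z-scoring)
and z-scored per channel and frequency against an ITI baseline — by
default the final 1000 ms of the ITI, pooled across trials. Theta averages
the 3-8 Hz frequencies; HFA averages seven 20-Hz sub-bands (70-90 …
130-150 Hz, 10-Hz step) before averaging across sub-bands, limiting the
1/f-driven low-frequency bias of one wide band. Band power is
block-averaged to 20 Hz, which also reconciles the 512/2000 Hz acquisition
dialects after power estimation.

## Connectivity

Connectivity is estimated over time but across trials: at each timepoint
of the 100-Hz resampled epoch, per-trial Morlet cross-spectra (theta
subset of the standard bank) combine into |imaginary coherence|, pairwise
phase consistency, or the debiased squared weighted phase-lag index,
computed per frequency and then band-averaged. Magnitude coherence is also
available (`metric="coh"`) as the volume-conduction-sensitive contrast; it
is not used for inference.

Significance: trial labels of one channel are shuffled (`n_perm`, 1000 at
full scale), giving a one-sided (elevated) p per timepoint, BH-FDR
corrected across timepoints; a pair is flagged when a **contiguous** run
of corrected-significant timepoints spans ≥100 ms (10 samples at 100 Hz).
Contiguity is a package decision — the duration rule could also count
total significant time, and a flag exposes that variant. FDR is applied
within pair (across timepoints), not pooled across pairs.

Trial-level coupling uses amplitude-envelope correlation instead (per-trial
Pearson r of two band-power envelopes over the approach window, excluding
the pre-movement period), because across-trial coherence has no
single-trial analogue; r is Fisher-z transformed and standardized within
pair.

## Directionality

**Net time-reversed Granger.** At every timepoint in the final 1500 ms
before the turn, a bivariate VAR(12) is fit by pooled OLS on a centered
310-ms sliding window across trials (≈ 1200 rows per fit at 40 trials,
comfortably above the 8x-n-lags floor). The innovation covariance and
transfer function give frequency-resolved Granger scores both ways
(Geweke's spectral decomposition), averaged over 3-8 Hz. The same score
computed on time-reversed epochs is subtracted:

    net(a,b) = [GC(a→b) − GC(b→a)] − [GC_rev(a→b) − GC_rev(b→a)]

This grouping makes the score antisymmetric under swapping the pair and
implements the time-reversal control (a direction driven only by an SNR
gradient flips with the signal and cancels). A literal left-to-right
reading of the net score without the grouping is available behind
`literal_eq=True` for comparison; it is not antisymmetric and is not the
default. Time reversal is applied to the whole trial epoch and the
mirrored window read off, which equals reversing within the window except
for the lag-context samples at its edge. Permutation significance shuffles
one channel's trial labels, tests |net| two-sidedly per timepoint, applies
BH-FDR, and requires more than 500 ms (50 timepoints) significant. The
scoreable range is trimmed where the sliding window plus lag context (or
its mirror) would cross the epoch edge, leaving ~1230 ms of the nominal
1500.

The heavy lifting is batched: lagged cross-products are accumulated once
per (pair, permutation) and sliding-window sums give every timepoint's
normal equations simultaneously, so a 1000-permutation run on one pair
costs seconds, not hours. Trial-label permutations only alter the
between-channel product blocks, which is exploited.

**Cross-correlation.** Theta band-passed (3-8 Hz zero-phase Hamming FIR)
approach windows are concatenated per channel; the CCF over ±25 lags
(±250 ms at 100 Hz) is computed, and the best lag retained when the peak
|r| is in the top 5% of a null built by shuffling trial order while
keeping each slot's length (so concatenation discontinuities match in
every surrogate; unequal segments are cropped or wrap-padded to the slot).
`best_lag > 0` means the first channel leads — the same convention as a
positive net Granger score, which the consensus rule relies on.

**Consensus.** A region pair is directional only when hierarchical P+
exceeds 0.95 in the same direction for both methods (or falls below 0.05
for both, the reverse direction). A missing method leaves consensus
undefined rather than false.

## Hierarchical models

Every contrast family is a Gaussian linear mixed model with nested random
intercepts (patient, and electrode or electrode-pair within patient) and
the stated weakly informative priors: intercept Normal(0, 5), coefficients
Normal(0, 2), random-effect SDs Exponential(1). The residual SD also takes
Exponential(1) — a package choice, made for symmetry with the other scale
priors. Because the hierarchy is intercepts-only there are no
random-effect correlations, so no correlation prior enters the model.
Responses are standardized within the modelled subset per the analysis
registry (`scale`, `log_scale`, or `scale_no_center` for signed responses
like net Granger scores and lags, whose sign carries the direction);
approach times are log-transformed before scaling.

Sampling is a blocked Gibbs sampler: conjugate multivariate-normal updates
for the coefficients, conjugate per-level updates for each random block,
univariate slice steps on the log of each SD, plus an
ancillarity-sufficiency (ASIS) translation sweep that exchanges location
mass between the intercept and each random block each iteration — without
it the intercept and the random-intercept means random-walk together and
the intercept's effective sample size collapses. Defaults are 4 chains,
5000 iterations with 1000 warmup, escalating once to 10000/5000 if any
fixed effect shows Rhat > 1.01 or bulk ESS < 1000 (arviz diagnostics).
Tests and the acceptance script run reduced settings (2 chains, ~700
iterations) sized so the recovery and calibration checks complete in
seconds; the contract is the draws-plus-diagnostics interface, not a
specific sampler.

Summaries report the posterior mean, 95% credible interval, P+ (fraction
of draws > 0), Rhat and bulk ESS per coefficient. Contrasts fit on
logged responses can be exponentiated draw-wise into multiplicative
connectivity-strength ratios. Per-electrode significance uses the
conditional draws (coefficient plus that electrode's random intercept)
rather than per-electrode refits. Posterior predictive checks simulate
replicate datasets from posterior draws and report tail probabilities of
the observed mean and SD. Bayes factors are not computed: marginal
likelihoods (bridge sampling) are outside this package's inferential
surface, which is P+ and credible intervals.

## Numerical choices and degenerate inputs

- VAR normal equations get a 1e-10 ridge jitter; spectral GC arguments are
  clipped at the smallest positive float and scores floored at 0.
- The debiased wPLI² denominator can be zero (no imaginary cross-spectral
  mass); those cells return 0.
- Envelope correlations on constant envelopes are undefined; those trials
  are dropped and flagged.
- Granger of a channel on itself, singular mixing matrices, baselines with
  zero variance, single-level hierarchies, and counterbalancing-impossible
  configurations all raise informative errors rather than degrading.
- Sampler seeds derive deterministically from the user seed (chain c uses
  `seed + 1000c`); identical (data, seed) gives identical draws.

## Problem sizes

Fixtures use ≤10 channels, ≤60 trials of ≤4 s at 1000 Hz. Calibration
rates in the tests and acceptance script use 200 trial shuffles (the
full-scale analysis uses 1000), 112-224 pairs for coherence null rates and
28-56 pairs for Granger qualifying rates; recovery checks use 10-20 seeded
replicates. These sizes are the package's chosen desk-scale operating
point: large enough that binomial noise on a 5% rate stays within the
stated bounds, small enough to iterate on.

## Known limitations

- The generator produces stationary-within-epoch Gaussian processes;
  nonstationarity beyond the planted amplitude schedules, artifacts, and
  epileptiform events are out of scope.
- The behavioral agent is a threshold heuristic, not a learning model; it
  exists to produce realistic event statistics, not to model choice.
- Spectral Granger is parametric (VAR-based); pairwise only, by design.
- The sampler covers Gaussian responses with identity link — exactly what
  the analysis families here need, nothing more.
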