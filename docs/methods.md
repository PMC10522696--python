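# Methods

`lamsel` implements a laminar analysis of attentional capture during color
pop-out visual search: how early, in which cortical layers, and in how large a
neural population the search target ("oddball") is distinguished from
distractors, and how strongly the earliest (feedforward) population response
predicts behavioral reaction time. Because the real laminar recordings are not
bundled, every stage runs against a synthetic session generator with known
ground truth; this note describes the models, the numerical choices, and what
the synthetic data do and do not establish.

## The population reliability statistic

The core statistic assumes one neural population per search item (6 items by
default). A single simulated trial draws, with replacement, `pop_size`
trial-level multiunit response time courses per alternative — one oddball
alternative, five distractor alternatives, each drawn independently from the
corresponding empirical pool — sums them within alternative, and declares the
alternative with the largest summed response the winner at each millisecond.
Ties are broken uniformly at random (they matter only for degenerate inputs).
Over `n_sims = 1000` simulations the fraction of oddball wins gives the
selection frequency at each timepoint and population size; chance for 6 items
is 16.67%.

Design choices that the procedure leaves open:

- **Sampling with replacement.** Keeps the population size free of pool-size
  limits; pools larger than ~50 rows make the distinction negligible.
- **Whole time courses per simulation.** Each simulation draws its trials once
  and reuses them at every timepoint, preserving temporal continuity of the
  selection trace. The alternative (redrawing per millisecond) yields the same
  marginal frequencies but temporally whiter traces.
- **Chance window.** The 99% interval of selection frequencies computed during
  the 100 ms pre-stimulus baseline, pooled across timepoints and population
  sizes. This empirical window — not the nominal 16.67% — defines "reliable"
  selection, because with finite pools the statistic is conditionally biased:
  the empirical mean difference between two finite pools, multiplied by a
  250-unit sum, produces large conditional deviations from chance that the
  baseline window absorbs. For the same reason depth-resolved analyses pool
  trials across sessions before simulating.
- **Selection time.** The first post-stimulus crossing above the upper chance
  bound sustained for ≥ 5 consecutive ms. The sustain rule suppresses
  single-sample Monte-Carlo blips; 5 ms is short relative to the ~20 ms
  feedforward window.
- **Error trials.** Pools are built from incorrect trials, with the distractor
  pool restricted to the errantly fixated item; the signed metric reported is
  oddball frequency minus chance, so negative values mean the chosen
  distractor systematically wins. The per-alternative frequencies are retained
  (`freq_all`) so the alternative signed convention (oddball minus distractor
  frequency) can be derived.
- **Feature selectivity.** A two-alternative variant: 100 draws per color,
  1000 comparisons of the summed responses, exact ties counting half; 50%
  means unselective.

## Signal processing and laminar alignment

Multiunit envelopes follow the band-pass (0.5–5 kHz, 4th-order Butterworth) →
full-wave rectification → low-pass (0.25 kHz) chain, applied forward-backward
(zero phase) so envelope latencies are not distorted; the procedure is only
defined for broadband sampled above 10 kHz. Envelopes are baseline-corrected
per trial and channel by the mean of the 100 ms pre-stimulus window, and
z-scored by that window's SD; channel-trials with zero baseline SD are set to
NaN and excluded when pools are assembled.

Current source density is the second spatial difference of the laminar LFP,

    CSD(t, d) = -sigma * (x(t, d-z) + x(t, d+z) - 2 x(t, d)) / z^2,

with z = 0.1 mm electrode spacing and conductivity sigma = 0.4 S/m by default
(configurable; sinks are negative). Edge channels are undefined and marked
invalid rather than padded.

Laminar alignment finds the earliest post-stimulus granular input sink on the
trial-averaged CSD: contiguous channels staying below mean − k·SD of the
baseline for a sustained period. The channel at the bottom of that region is
the functional L4/5 boundary; the middle compartment is the 0.5 mm (5
channels) ending at the marker, upper the 0.5 mm above that, deep the 0.5 mm
below, and the 15 aligned depths span upper → middle → deep. Numerical
calibration of the detector:

- k = 4 baseline SDs sustained ≥ 10 ms. LFP noise is temporally
  autocorrelated, so 2-SD excursions lasting a few milliseconds occur by
  chance in nearly every session; a 4-SD/10 ms criterion rejects pure-noise
  sessions while real trial-averaged sinks (≳ 10 SDs) are detected with
  millisecond-scale onset accuracy.
- The baseline SD of the trial average is estimated from single-trial CSD
  baselines divided by √n_trials: trials are independent, so this gives far
  more effective samples than the (autocorrelated) averaged trace itself.
- Channels join the sink region if their own sustained crossing begins within
  15 ms of the earliest onset, which tolerates noise-induced onset jitter
  across the sink's channels while still rejecting later secondary sinks.
- Sessions with no suprathreshold sink raise an alignment error and are
  excluded, mirroring standard practice.

The per-trial granular sink magnitude is the mean CSD over the middle
compartment and the feedforward window, sign-flipped so larger = stronger
sink.

## Feedforward window and the power-law RT model

The feedforward window starts when the mean population spiking response first
reaches 50% of its post-stimulus maximum and lasts 20 ms. Reaction times are
rank-ordered within session, converted to percentiles, and cut into equal
percentile bins — 4 (quartiles) or 25, with the slowest of the 25 dropped as
outliers. (A 25-bin equal split makes the dropped bin 4% of trials; we
implement the equal split and drop bin 25.)

The regression table simulates 1000 trials per RT bin at population size 250:
the predictor SPK is the summed sampled responses averaged over the
feedforward window, and the response is the mean RT of the trials sampled into
that simulated population (the procedure needs an RT per simulated population;
the mean of its constituent trials is the natural choice).

The model is

    RT_i | alpha, beta, r, SPK_i ~ Normal(phi_i, sigma_e),
    phi_i = beta * SPK_i^r + alpha,

with priors alpha ~ LogNormal(0, 0.5), beta ~ LogNormal(1, 0.5),
r ~ Gamma(1, 3), sigma_e ~ Gamma(0.5, 5), Gamma in shape–rate form (the Stan
convention). Notes:

- **Sign of the exponent.** The Gamma prior restricts r to positive values,
  yet the empirically relevant relationship (faster RTs for stronger
  responses) has a negative exponent. Both conventions are shipped: the
  default positive-support model, and `exponent_sign = -1` which fits
  phi = beta * SPK^(−r) + alpha with the same positive prior on the magnitude.
  Reported exponents carry the sign of the fitted convention.
- **Standardization.** SPK is divided by its median and RT converted to
  seconds before sampling, so the LogNormal(0, 0.5) prior on alpha is
  sensible; coefficients are reported on that standardized scale (the exponent
  is invariant to the predictor rescaling).
- **Sampler.** An affine-invariant ensemble (emcee) with differential-
  evolution moves, initialized at the posterior mode (Nelder–Mead on the
  unconstrained log-parameters) and run with 16 walkers; the configured totals
  (default warmup 2000, total 5000, thin 2) apply per walker. Walkers serve as
  chains for split-R̂ and ESS (arviz); a fit is flagged unreliable when
  max R̂ > 1.01. There are no divergences in this sampler family; the ensemble
  acceptance fraction is reported instead.
- **Bayesian R².** var(phi) / (var(phi) + sigma_e²) per posterior draw,
  summarized by the median — the Gelman-style definition, chosen because the
  quantity is otherwise underspecified.
- **Window scans** refit the model across window widths and offsets. Windows
  without evoked activity (e.g. pre-stimulus offsets) can produce non-positive
  summed responses; the scan shifts the predictor onto positive support
  (logged) so the fit runs and its near-zero R² is interpretable.
- Degenerate designs (constant predictor) leave r unidentified; the posterior
  then stays prior-wide and the diagnostics flag the fit.

## Priming and error-trial analyses

Priming of pop-out is labeled from the position of a trial in its
target-color block: trial 1 after a color switch is `not_primed`, trials from
the 3rd repetition onward are `primed`, and the transitional trials are
excluded. The threshold of 3 is a package choice — behavioral priming builds
over the first few repetitions — and is configurable.

The baseline modulation analysis uses raw (not baseline-corrected)
pre-stimulus spiking of color-preferring columns: per column, the difference
mean(baseline | preferred color is target) − mean(baseline | non-preferred),
computed separately for primed and not-primed trials, compared by a paired
two-sided t test across columns (paired because each column contributes both
conditions). The not-primed model check refits the power model on not-primed
trials only, re-ranking RT percentiles within that subset so the procedure
reduces exactly to the full fit when every block has length one.

## Stimulus colorimetry

CIE xyY is converted to tristimulus values (X = xY/y, Z = (1−x−y)Y/y) and
mapped to L, M, S cone excitations with the Smith–Pokorny fundamentals on
Judd-modified tristimulus values; cone contrast is the Weber ratio against the
background, rounded to 2 decimals in reports. The bundled display calibration
reproduces the L and M excitations from chromaticity, but its S-cone values
follow a different (unidentified) normalization, so S excitations computed
from xyY are not comparable to the calibrated ones — contrasts, which are
ratios, are unaffected.

## The synthetic session generator

The generator emulates the statistical structure the analysis assumes, not the
biophysics:

- 32-channel probe, 0.1 mm spacing, 1 kHz envelope sampling, −100 to +400 ms
  around array onset; 6-item arrays with the receptive-field item at ring
  position 0; blocks of 5–15 trials with alternating target color; oddball
  position uniform; foreperiods 750–1250 ms from an exponential (scale 200 ms)
  right-censored at the maximum, giving a flat onset hazard on the interior.
- Each trial carries a latent oddball feedforward amplitude
  S ~ LogNormal(0, 0.3) and RT = alpha + beta·S^r + truncated Gaussian noise
  (floor 100 ms); defaults alpha = 120 ms, beta = 120, r = −0.7 give mean RTs
  near 240 ms. The evoked multiunit transient is a difference of gamma
  kernels rising at 58 ms (±2 ms per-trial jitter), peaking ~25 ms later.
  Distractor-trial amplitudes are independent of RT (gain 0.6).
- The LFP is spatially smoothed Ornstein–Uhlenbeck noise (SD 0.3, tau = 20 ms,
  Gaussian spatial kernel of 2 channels emulating volume conduction) plus an
  evoked component constructed by double spatial integration of a target CSD
  pattern: a flat sink across the configured granular channels with balancing
  flank sources, scaled per trial by the same amplitudes as the envelopes, so
  the forward CSD operator recovers the sink exactly and its magnitude is
  coupled to RT.
- Error trials (default 10%) fixate the receptive-field distractor whenever it
  holds one; on those trials the chosen distractor's population receives the
  oddball-like boost plus a small tonic bias (0.2 z) while the unattended
  oddball responds distractor-like — so errant selection precedes errant
  behavior by construction.
- Priming adds a tonic shift (configurable, z-units) to the column when its
  preferred color is the target and priming has built up (2nd block trial
  onward). A lightweight companion generator (`simulate_column_baselines`)
  produces multi-column baseline tables for the priming test at negligible
  cost.

What the generator deliberately omits: biophysical neuron and synapse models,
saccade kinematics, eye-position noise, display timing artifacts,
cross-channel correlated spiking noise, and session-to-session heterogeneity
beyond the configured parameters. Passing tests therefore establish that the
statistics are implemented correctly and behave as designed under realistic
noise levels — not that the scientific conclusions would replicate on real
recordings.

## Problem sizes

Default analyses are sized for a laptop-class run: sessions of a few hundred
to ~1200 trials, 1000 Monte-Carlo simulations per selection estimate, 250
simulated trials per RT bin in the regression table, and sampler runs of
800 warmup + 2200 kept steps × 16 walkers for the headline fits (the fuller
2000/5000 configuration remains the default of `MCMCConfig`). Parameter
recovery at these sizes completes in a few seconds per fit and covers the
generative parameters at the nominal CI rate.

## Known limitations

- The ensemble sampler's R̂ is computed across interacting walkers, a proxy
  for independent-chain R̂; short runs can exceed the 1.01 flag threshold even
  when medians are stable. The flag is conservative by design.
- The pseudo-population construction draws distractor alternatives from one
  shared pool (or geometry-conditioned pools); real simultaneous recordings of
  all six item locations would allow fully preserved correlation structure,
  approximated here only by the within-trial variant.
- At population size 250, chance windows computed from small single-session
  pools are near-vacuous (the conditional-bias effect above); depth-resolved
  conclusions require pooling across sessions.
- The envelope chain is exercised on synthetic broadband in demos and tests;
  the session container carries precomputed envelopes, which the pipeline
  consumes directly.
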