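# Methods

## The model

A single threshold-linear neuron receives 4N synaptic inputs across
N = 10 frequency channels: excitatory and inhibitory ON inputs driven by
sound onsets, and excitatory and inhibitory OFF inputs driven by sound
offsets.  The voltage is the weighted sum of all inputs,

    u = Σᵢ w_i^{ONᵉ} x_i^{ONᵉ} + w_i^{OFFᵉ} x_i^{OFFᵉ}
        + w_i^{ONⁱ} x_i^{ONⁱ} + w_i^{OFFⁱ} x_i^{OFFⁱ},

and the output rate is the rectified voltage, y = max(u − θ, 0) with
θ = 2.5.  All rates and inputs are dimensionless; one time step is read
as 1 ms wherever durations are quoted in milliseconds.

Inputs share a Gaussian tuning over channels, x = T s with
T_ij = exp(−d(i,j)² / (2σ)), σ = 1.5 and d the circular index distance
(channel 0 and channel N−1 are neighbours).  The denominator is kept in
the 2σ form; the textbook 2σ² variant is available via
`tuning_denominator="2sigma2"` and gives a slightly broader kernel.
Excitatory and inhibitory inputs are identical; only their weights
differ.

### Plasticity

* Excitatory Hebbian rule: Δwᵢ = αᵉ xᵢ y + ηᵢ wᵢ, with αᵉ = 10⁻⁴ and
  ηᵢ drawn uniformly from (−0.0025, 0.0025) independently per synapse
  per step (multiplicative synaptic noise/turnover; silent synapses do
  not drift).
* Inhibitory rate rule: Δwᵢ = αⁱ xᵢ (y − ρ) with αⁱ = 10⁻⁵ and target
  rate ρ = 0.01, applied to the weight *magnitudes* so that inhibition
  strengthens onto active inputs whenever the output exceeds its target.
  This is the orientation that produces excitatory/inhibitory
  co-tuning; applying the same increment to the signed (negative)
  weights would anti-co-tune, and is available as
  `inhib_rule="literal"`.
* Constraints, applied after every step: excitatory weights are clipped
  to [0, 1] and each class (ONᵉ, OFFᵉ) is rescaled multiplicatively to
  an L1 sum of 1 (joint L1 of 2 across both classes).  Inhibitory
  magnitudes are likewise rescaled to 1 per class, except that an
  all-zero class (the initial condition) is left untouched.  A joint
  normalisation across the ON/OFF pair is available for both weight
  types, but joint excitatory normalisation lets one class absorb
  nearly all weight during sound exposure, leaving cells with no OFF
  receptive field at all — inconsistent with the phenomenon being
  modelled — so per-class is the default.
* Homeostatic-scaling control: the excitatory Hebbian rule is replaced
  by a uniform multiplicative update — all excitatory weights × (1 −
  10⁻⁵) when y exceeds its running mean since simulation start, × (1 +
  10⁻⁵) when below.  The control freezes the inhibitory rule as well:
  it isolates the role of activity-dependent, input-specific learning,
  and any input-specific rule left running would reintroduce exactly
  the kind of receptive-field change the control is meant to exclude.
  Ratios between excitatory weights are preserved exactly.

### Development

Each cell runs two phases.

1. **Pre-hearing** (100,000 steps).  Stimulus channels carry spontaneous
   activity: uniform noise in (−0.5, 0.5) filtered with a first-order
   exponential filter (time constant 5 steps), minus θₓ = 0.1, rectified,
   and rescaled to a temporal mean of 1 per channel.  The same trace per
   channel drives ON and OFF (and excitatory and inhibitory) inputs —
   this shared drive is what makes ON and OFF tuning develop *matched*
   — while channels are mutually independent, which is what lets tuning
   develop at all.  Excitatory weights start uniform at 1/(2N) = 0.05,
   inhibitory at zero.
2. **Sound exposure** (100,000 steps).  A two-state switching process
   turns sound ON and OFF: when ON it switches OFF with probability
   1/50 per step, when silent it switches ON with probability 1/50
   (into a uniformly random channel; at most one channel is ON at a
   time).  In the overlapping condition every channel switches
   independently with switch-ON probability 1/500.  Each onset adds a
   unit pulse to the channel's ON trace and each offset to its OFF
   trace; pulses decay by exp(−1/τ) per step with τ = 10 (an EPSP-like
   time course).  Traces pass through the tuning matrix and are jointly
   rescaled so their global maximum is 40.

Weight snapshots are recorded at t = 0 (hearing onset), 500, 1000, 1500
("young"), 5000, 20000 and 100000 ("adult") of the sound phase.
Conditions: `single_channel` (default), `overlapping`,
`independent_on_off` (ON pulses from one switching sequence, OFF pulses
from an independent one, so onsets and offsets no longer alternate),
`excitation_only` (evoked inhibitory inputs and their rule removed; the
pre-hearing phase keeps full plasticity since it models spontaneous,
not evoked, activity) and `scaling_only` (the control above).

### Probing

Plasticity is frozen during all probing.

* **FRAs.**  Each channel is probed at eight intensities from 19.5 to
  65: an onset pulse of that size drives the ON inputs, and after a
  100-step tone duration an offset pulse drives the OFF inputs; the ON
  (OFF) response is the mean rate over a 30-step window (≈ 3τ) after
  the respective pulse.  The probe is tuning-weighted but not globally
  rescaled — the pulse size carries the level information.
* **CF.**  The characteristic frequency of a response surface is its
  response-weighted *circular* centre of mass over the channel ring
  (the vector mean of channel angles weighted by summed response).
  Channels form a ring, so a plain weighted mean index is meaningless
  for cells tuned across the wrap — and, usefully, the circular mean is
  exactly invariant to any uniform background response.  The plain mean
  remains available via `circular=False`.  Signed CF differences wrap
  to the shorter arc (a tie at exactly half the ring resolves
  positive) and convert to octaves at 0.5 oct per index (10 channels
  span 5 octaves).
* **FM sweeps.**  A stepwise sweep presents a tone in one band at a
  time, advancing one band (up or down, circularly) every 50 steps for
  3000 steps (60 presentations, six laps).  A band's offset event falls
  at the moment the sweep moves on, so the offset of the departing band
  coincides with the onset of the entered band; this coincidence — the
  sweep leaving the OFF-preferred band exactly while entering the
  ON-preferred band — is the mechanism that makes the response
  direction-dependent.  An isolated one-step-tone variant
  (`offset_timing="next_step"`) exists for comparison; it makes UP and
  DOWN responses identical to within exp(−5) residuals and therefore
  supports no direction selectivity.  Sweep inputs are generated exactly
  like sound-evoked inputs, including the rescale ceiling of 40: with
  θ = 2.5 and total net weights of order 1, a probe much weaker than
  the exposure scale cannot cross threshold at all (the voltage is
  bounded by the ceiling times the reachable net weight), so probing at
  a reduced ceiling simply yields silent cells.  The direction
  selectivity index is DSI = (r_up − r_down)/(r_up + r_down); when
  neither direction evokes output the index is reported as 0 with an
  `undefined` flag.  In the figure-level correlation the selectivity
  axis is oriented with DOWN-preference positive (the negated DSI), so
  the CF-difference correlation is negative; the per-cell tables carry
  the UP-positive DSI.

The magnitude of the sweep correlations is regime-dependent: with the
probe at the exposure scale, the full model's DSIs are sizeable and
tightly coupled to the CF difference (r between about −0.75 and −0.99
across 100-cell populations, depending on the master seed), whereas
excitation-only cells sit far above threshold, their DSIs shrink to
~10⁻³ and the correlation largely washes out (r of roughly −0.2 to
−0.35).  A probe near each model's own threshold (ceilings of
roughly 3–4 for excitation-only, 5–8 for the full model) would give
both models graded, strongly correlated selectivity, but no single
drive scale achieves that for both; the package keeps the single
exposure-scale convention rather than a per-condition probe level.

## Empirical spike-train analysis

The in-vivo-style routines operate on spike counts from a 25-frequency
(7–56 kHz, 0.125-octave spacing) × 8-level (10–80 dB, 10-dB steps) tone
grid, with ON and OFF counts in 0–100 ms windows after tone onset and
offset and a 100 ms pre-stimulus baseline window per presentation.

* Mean-count surfaces are smoothed with a 3×3 pyramidal kernel
  ([1,2,1; 2,4,2; 1,2,1]/16), renormalised over in-bounds taps at the
  grid edges (no invented padding).
* FRA edges: cells whose smoothed response is ≥ 130% of the baseline
  rate (inclusive).  A zero baseline falls back to 30% of the surface
  maximum.
* CF: at the lowest level with any defined cell, the response-weighted
  geometric-mean frequency of the defined cells.  BF: the argmax cell,
  ties resolved to the lowest level then lowest frequency.  Bandwidth:
  the octave span of the defined region exactly 30 dB above threshold;
  if that row is off the grid the bandwidth is flagged undefined rather
  than extrapolated.
* ON/OFF overlap: 100 × |intersection| / mean(|ON|, |OFF|) of the edge
  masks (identical masks → 100, disjoint → 0); a Jaccard-style
  alternative would order units identically.
* DSI per speed from mean counts; a unit is direction selective when
  the absolute *mean* of the DSIs at the two slowest speeds (2.2 and
  4.4 oct/s) is strictly above 0.05.
* DSI regression: ordinary least squares of the low-speed DSI on ten
  z-scored unit properties (onset/offset rate increases at CF and
  60 dB, their Fano factors, spontaneous rate and its Fano factor, ON
  and OFF bandwidths, overlap percentage, CF difference in octaves),
  with an intercept (the response is not centred; omitting the
  intercept would force the fit through a zero mean DSI).  The
  per-predictor proportional reduction of error drops that predictor's
  term *while keeping the full-model coefficients* —
  PRE = (SSE_truncated − SSE_full)/SSE_full — matching the definition
  of the truncated prediction; a refit variant is behind
  `refit_truncated=True`.  Adjusted R² uses the standard small-sample
  correction.  Exactly collinear predictors raise an error naming the
  offending columns.
* Pharmacology-style change metrics: mean element-wise post/baseline
  response ratio over stimuli inside the baseline FRA edges, excluding
  elements at or below a baseline floor (and units with fewer than one
  baseline spike on average); evoked LFP amplitude as the global
  minimum in the 0–300 ms post-onset window (deflections are
  negative-going); CF shifts as log₂(CF₂/CF₁).

## Synthetic recordings

The generator plants ground truth and emits the same tabular schemas the
analysis consumes, so every routine is testable by parameter recovery.
Each unit has ON and OFF V-shaped response fields: responsive where
level ≥ threshold + (60/bw)·|Δlog₂ f|, so the region is `bw` octaves
wide 30 dB above threshold, with the rate ramping linearly to its peak
30 dB above the local edge.  Counts are Poisson (the simplest count
model consistent with Fano-factor predictors near 1); sweep counts are
Poisson around peak_rate × (1 ± DSI), with the DSI magnitude constant up
to 17.5 oct/s, falling linearly to zero at 35 oct/s and zero above —
direction selectivity at slow speeds only.  The planted coupling is
DSI = clip(slope × (OFF − ON CF in octaves), −1, 1).

Population defaults model well-driven cortical units: 30 repeats per
stimulus, evoked peaks of 8–16 and spontaneous rates of 2–4 spikes per
100 ms window, thresholds of 10–30 dB, bandwidths of 0.8–1.6 octaves.
The spontaneous rate matters more than it looks: with a very low
baseline the 30%-above-baseline edge sits at the noisy tip of the V and
CF recovery degrades several-fold; at the chosen level the edge sits on
the steep flank and the CF-difference recovery error is ≈ 0.09 octaves.
Adult-like populations draw CF offsets of up to 0.5 octave (triangular,
mode 0.25, either sign) with coupling slope 1.2; young-like populations
draw near-zero offsets (up to 0.125 oct) with zero slope.

What the generator does *not* emulate: spike sorting and its failure
modes, over-dispersed or correlated spike counts (an over-dispersion
multiplier is the obvious extension), adaptation across repeats,
velocity-asymmetric tuning beyond the planted profile, and any
relationship among the nine nuisance properties.  Passing recovery
tests therefore show that the analysis chain is unbiased and
well-calibrated under clean Poisson assumptions, not that it is robust
to every pathology of real recordings.

## Numerics and reproducibility

The per-step update loop (voltage → rate → Hebbian and inhibitory
updates → clip + L1 normalisation) is JIT-compiled with numba; the
pure-Python rule functions define the reference semantics, and the test
suite pins the kernel to a hand-written scalar loop at 1e-12 over a
20-step schedule and to the composed public operations for single
steps.  All randomness flows from `numpy.random.SeedSequence` spawning:
master seed → per-cell streams → disjoint sub-streams for spontaneous
noise, switching sequences and synaptic noise, so populations are
reproducible bit-for-bit and independent of execution order.

Degenerate inputs are handled explicitly: an all-zero rectified
spontaneous trace triggers regeneration from a perturbed stream (and an
error once θₓ makes the rescale impossible); an empty event train
yields zero traces with a warning and no rescale; an all-zero FRA
surface raises an undefined-CF error and the cell is excluded from
population statistics with its count reported; a zero DSI denominator
reports 0 with a flag; an excitatory weight class collapsing to zero
sum (unreachable from the standard initial condition) aborts the run.

Default problem sizes follow the study conditions everywhere: 100-cell
populations, 10⁵ + 10⁵ steps.  The fast unit tests exercise the same
code paths at 2000-step phases; the acceptance tests and script run the
full scale (a 100-cell condition takes ~20 s on one core after JIT
compilation).

## Known limitations

* One feedforward neuron per cell; no recurrence, no spike timing, no
  conductances.
* The sweep probe level is a single global convention; the
  direction-selectivity *magnitudes* (and hence the strength of the
  CF-difference correlation) depend on where the probe sits relative to
  threshold, as discussed above.
* The circular centre of mass is the only CF estimator that behaves on
  the ring; comparisons with analyses that used a plain weighted mean
  on non-wrapping data will differ for boundary-tuned cells.
* The scaling control is exactly ratio-preserving, so its null result
  is structural rather than statistical.
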