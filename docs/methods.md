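# Methods

This note documents the models, estimators and numerical choices behind
`spikerel`, and what the synthetic-data experiments do and do not show.

## Stimulation protocol

The frozen-noise template is a sum of sinusoids at 1–100 Hz (1 Hz steps)
with i.i.d. uniform phases and amplitudes proportional to 1/√f, giving a
power spectrum proportional to 1/f ("equal energy per octave"). The time
average is removed and the residual is rescaled so that, after adding a
unit DC offset, the coefficient of variation is exactly 0.2. The 1/√f
amplitudes fix only the relative spectral weights, so enforcing the CV by
a single scale factor is the natural closure; the log-log spectral slope of
the result is −1 to machine precision because each component occupies its
own FFT bin on an integer-second template.

The 1 s template is concatenated three times into a 3 s stimulus template
(the concatenation puts a local autocorrelation maximum at a 1 s lag);
copies scaled to 75/100/150 % of the neuron's rheobase are ordered
ascending and separated by 5 s of zero-current recovery. Recovery windows
are placed only between segments; leading/trailing padding is exposed as
configuration. The stimulus sampling rate is not a protocol constant; the
default is 25 kHz and every invariant holds at any rate ≥ 2·f_max (tests
run at 5 kHz to keep arrays small). Autocorrelation of a constant trace is
an error (zero variance), never NaN output.

## Spiking reliability

For an ordered pair of sweeps (A, B) of the same noise and intensity, the
matching fraction is the proportion of spikes of A with at least one spike
of B within a coincidence window (default 1 ms, boundary inclusive). A
neuron's raw reliability is the mean over all ordered pairs of usable
sweeps; ordered-pair averaging preserves the per-spike interpretation when
trains differ in length and equals the mean of the two directed fractions
per unordered pair. Sweeps with zero spikes are excluded from pair
formation (a 0/0 fraction is undefined); their count is logged.

The firing-rate correction subtracts the mean reliability of 100 surrogate
sweep sets in which each sweep keeps its spike count but its spike times
are redrawn uniformly within the stimulus window ("random relocation
preserving count"; no refractory constraint). The surrogate generator is
seeded, so results are reproducible. The corrected value is ≈ 0 for
Poisson-like trains of any rate and can be slightly negative by sampling
noise.

The estimator is a per-pair average, so its expectation does not depend on
the number of trials; only its variance does. Note that this unbiasedness
is a statement about i.i.d. sweeps — literally duplicating a sweep
introduces identical-pair comparisons with matching fraction 1 and shifts
the average, which is the correct behavior of the definition, not a bias.

Reliability is computed per (noise, intensity) sweep set and averaged over
the two noises per neuron; latency pools for cumulative distributions pool
both directions of every pair and both noises. The default analysis
intensity is 100 % rheobase with a confirmation run at 150 %.

Nearest-spike latency CDFs offer an empirical estimator and a
Gaussian-kernel estimator (Silverman plug-in bandwidth); both are
non-decreasing and bounded by [0, 1].

Subthreshold reliability is the mean pairwise Spearman correlation of the
voltage traces recorded at the sub-rheobase (75 %) intensity; constant
traces are excluded from pairing with a warning.

## Cell typing

The average spike is the elementwise mean of peak-aligned waveforms. Width
is measured at half of the peak-to-baseline amplitude, between the first
upward and last downward crossing, with linear interpolation between
samples; a Gaussian-shaped spike of SD s therefore measures 2·s·√(2 ln 2).
Baseline defaults to the median over the 2 ms preceding the peak and is
configurable. Cells are *fast* spiking iff the width is strictly below
400 µs (exactly 400 µs is regular). The transcriptomic line → group table
(PV / non-PV inhibitory / mixed / excitatory) is a versioned CSV, matched
by Cre-driver prefix; unknown lines raise rather than defaulting, because a
silent mis-grouping would contaminate every downstream comparison.

## Synthetic populations

The generator emulates the sweep structure of frozen-noise experiments:
two noises × three intensities × 2–8 repetitions per neuron, all sweeps of
a condition sharing one stimulus. Ground truth is an inhomogeneous Poisson
template train whose intensity follows the positive part of the stimulus
current, normalized to a class mean rate; each sweep corrupts the template
by independent spike deletion, Gaussian spike-time jitter (reflected at
the window edges so counts are preserved) and homogeneous extra spikes.
Keeping these three knobs as the only sources of across-sweep variability
makes parameter recovery interpretable: corrected reliability must be
monotone in the jitter SD. A Poisson backbone was chosen over a
biophysical generator precisely for this interpretability; an
Izhikevich-driven backend can be substituted for integration experiments.

The two reference classes place jitter at 0.2 ms (PV-like) and 5 ms
(excitatory-like), bracketing the 1 ms coincidence window; mean rates
(15 vs 8 Hz), deletion (5 vs 10 %) and membrane/rheobase values are typical
cortical fast-spiking vs regular-spiking magnitudes. Intrinsic features
are drawn around class means tied monotonically to the jitter SD, with
15 % lognormal noise, so the sign of each feature–reliability correlation
is known by construction.

Voltage synthesis (for subthreshold and spike-width tests) is a membrane-
tau RC filter of the stimulus (~10 mV modulation) plus Gaussian noise split
into a shared and a private component (shared fraction configurable) plus
stereotyped Gaussian spike waveforms of class-dependent width. It emulates
the *correlation structure* of repeated sub-threshold responses, not
conductance dynamics, spike afterpotentials or electrode artifacts — tests
passing on it certify the estimators, not biological realism.

A single master seed derives per-neuron seeds through `SeedSequence`, so
populations are bit-reproducible and iterations are independent.

## Downstream-neuron model

One Izhikevich neuron (dv/dt = 0.04v² + 5v + 140 − u + I, du/dt =
a(bv − u)) receives N single-spike inputs whose times are drawn from
Normal(t0, σ); polarity signs the current. Coefficients default to the
canonical regular-spiking set (a = 0.02, b = 0.2, c = −65, d = 8), voltage
capped at 30 mV; all are configurable. Integration uses the original
modified Euler scheme — v advances in two half-steps of dt/2 per u step —
with dt = 0.5 ms by default and a refinement check at 0.25 ms.

"Instantaneous" inputs are treated as true delta currents: each input
shifts v by exactly `amplitude` mV at its (grid-binned) time, and the ODE
is integrated between impulses. Realizing the impulse instead as a finite
current over one step would make the delivered effect depend on dt and
defeat any step-refinement comparison. The minimum voltage used for the
inhibition depth is tracked immediately after each jump, since the true
trajectory minimum of a delta response occurs at the jump instant, before
any within-step recovery.

Amplitude defaults are polarity-specific, chosen once from the model's
dynamics: 12 mV-equivalent for excitatory inputs — a lone input is clearly
subthreshold (threshold is ≈ 15 mV above rest for the RS set), a
synchronous volley of 10–50 inputs fires exactly one spike, and a few
near-coincident inputs can re-trigger the neuron after a reset, which is
what lets intermediate jitter (σ = 10 ms) produce more spikes than either
synchrony or heavy jitter — and 2 mV-equivalent for inhibitory inputs,
giving a 40 mV hyperpolarization for a synchronous volley of 20 while
keeping the quadratic voltage dynamics far from their unstable
large-|v| regime. A single shared amplitude cannot satisfy both roles:
values large enough for excitatory re-triggering drive synchronous
inhibitory volleys into the quadratic blow-up region.

Inhibition depth is baseline minus minimum voltage, with baseline the mean
voltage over the 50 ms before the earliest input (robust to initialization
transients, unlike the global resting value). Depth is computed per
iteration and then averaged; the alternative (minimum of the mean trace)
can be assembled from the returned traces. Sweeps run 500 iterations per
grid point by default with per-iteration seeds spawned from one sequence.
Non-finite states raise immediately, reporting the step.

Robustness: the inhibitory depth ordering (σ = 0 > 10 > 50 ms) holds under
alternative Izhikevich parameter sets; the excitatory σ-curve's shape is
parameter-sensitive and only its default-parameter behavior is asserted.

## Group statistics

Groups are compared with a Kruskal-Wallis omnibus test plus all pairwise
two-sample Kolmogorov-Smirnov tests on corrected reliability; because no
multiple-testing correction is canonical here, raw and Holm-adjusted
p-values are both reported. Feature correlations are Spearman.
Species × type comparisons use a two-way ANOVA (type-II, via OLS); under a
fully null population its p-values are uniform, which the test suite
verifies by a KS test over 500 seeded replicates.

## Problem sizes and tolerances

Tests and the acceptance script use a 5 kHz stimulus sampling rate, 30
neurons per class over 20 seeds for parameter recovery, 200 neurons for
the null-consistency check, 1000 random pairs for oracle equivalence, and
500 iterations per grid point for the model sweeps — sizes at which every
Monte Carlo assertion has comfortable margin while the full suite runs in
a few minutes. Exact assertions (CV, spectral slope, segment durations,
protocol round-trips) use machine-precision or printed-precision
tolerances; Monte Carlo assertions use 3-SE bounds or the explicit margins
stated in the tests.

## Known limitations

* The synthetic generator does not match any empirical feature
  distribution; it provides controllable ground truth, not realism.
* The permutation surrogate ignores refractoriness; for very high rates it
  slightly overestimates chance coincidence.
* NWB ingestion of real recordings is a thin adapter surface
  (`NeuronRecord` construction) and is not exercised by the test suite.
* The downstream model is deliberately unphysiological (single neuron, no
  background input, single-spike inputs); it isolates the effect of input
  timing variability and nothing else.
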