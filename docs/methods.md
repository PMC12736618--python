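# Methods

## Measurement-chain model

The front end is solved by nodal analysis of a two-node linear network.
With source voltage V, series conductance `ys = 1/r_series`, tank
admittance `yt = 1/(jωL) + jωC + 1/r_damp`, coupling admittance
`yc = jω·c_couple` and plant admittance `yp = 1/Z_plant`:

```
[ ys + yt + yc   −yc ] [vA]   [ ys·V ]
[     −yc      yc+yp ] [vB] = [  0   ]
```

The measured node is B, the voltage across the plant ("the response
attached to the object"); node A is available as an option. At DC the
inductor shorts node A and the coupling capacitor isolates node B, so both
gains are exactly zero. An open-circuit sentinel removes the plant branch,
in which case node B floats at the node-A divider potential. The solver is
the closed-form 2×2 solution; the test suite checks it against an
independent dense `numpy.linalg.solve` of the same admittance matrix to
1e-9 relative error over randomized components, loads and frequencies.

**Excitation and envelope.** The source is a unit square wave. Odd
harmonic k carries amplitude 4/(πk); harmonics are kept while
k·f ≤ 1 MHz (configurable), and the ideal peak detector is modeled as the
sum of per-harmonic steady-state response magnitudes minus the (default
zero) diode drop, clipped at zero. This peak-sum is an upper envelope — it
ignores relative harmonic phase — chosen because the detector's 1.6 kHz
cutoff is far below the sweep rate, making a steady-state approximation
valid, and because it keeps a sweep at O(n_points · n_harmonics). A
consequence worth knowing: with square-wave excitation the harmonic
pile-up at low fundamentals places the sweep maximum at the 20 kHz edge of
the grid (the curve is still unimodal — it only decays); with
fundamental-only excitation the loaded tank resonance (≈ 29 kHz with
default components) appears as an interior peak. Amplitudes are in
arbitrary units throughout; the default ADC full scale is 2.0 units
mapped linearly onto uint16.

**Plant load.** A single-dispersion Cole model
`Z(ω) = R∞ + (R0 − R∞)/(1 + (jωτ)^α)` — the minimal standard tissue
parameterization, capacitive (Im Z ≤ 0) for α ≤ 1. Default dark-state
values R0 = 50 kΩ, R∞ = 2 kΩ, τ = 2 µs, α = 0.8 place |Z| in the same
decade as the 10 kΩ series resistor and the 4.7 kΩ tank, so the divider
converts a double-digit-percent load change into a percent-level amplitude
change: large enough to detect above the noise floor after averaging a
burst, small enough that the classification problem is not trivial. The
unloaded tank resonates near 29 kHz; the loaded network's empirical center
frequency is not a target of the simulator.

## Synthetic grow-box experiment

The generator emulates: per-minute bursts (default 100 sweeps, 20 in the
desk-scale studies), light/dark phases drawn uniformly from 1–3 h
(configurable; 1–4 h is also plausible for this kind of protocol),
first-order relaxation of every Cole parameter toward the active state's
target with time constant `tau_resp` = 5 min (the "delay of several
minutes" a plant needs to respond to a light change), illumination
encoded as a 30 % reduction of R0 and a 20 % reduction of τ, a geometric
random walk (one shared log-normal factor per step, SD 0.002/√min) on R0
and R∞ representing slow hydration/electrode baseline drift (≈ ±10 %
accumulated SD over 48 h — clearly visible in the trend plots), and
additive Gaussian amplitude noise with SD 2 % of full scale. Temperature
and humidity are treated as held constant and are not simulated.

Relaxation uses explicit Euler with the per-step gain clipped at 1, so
`dt ≫ tau_resp` degenerates gracefully to target-tracking. Bursts inherit
the plant state of their minute (a burst lasts ~23 s ≪ tau_resp) and
differ across sweeps only through measurement noise.

What the generator does **not** emulate: mechanistic photosynthesis or
ion-transport dynamics, circadian anticipation, stimulus-specific
transients at the switch itself, electrode–tissue contact physics,
temperature/humidity covariates, or non-stationary noise. Passing tests
therefore demonstrate that the pipeline recovers a lagged, drifting,
noisy spectral state change — not that any specific plant species is
classifiable at these accuracies.

The "second plant" multiplies each Cole target parameter by one
independent log-normal factor exp(N(0, shift)), the same factor for the
dark and light targets of that parameter, so the plant's baseline moves
while the direction of the light effect is preserved — mimicking
specimen-to-specimen variability.

## Pipeline

Order of operations: (1) drop samples in the half-open 10-min window
[t_switch, t_switch + 10) after every light transition; (2) split the
remainder chronologically 60/20/20 (sizes floored, remainder to test);
(3) standardize per frequency bin — mean/SD pooled over all sweeps of all
training samples — fit on the training block only and applied frozen to
validation and test. Fitting the scaler before splitting would leak
evaluation statistics into training; the leakage-free order is used.
Constant features map to zero. Class balance is reported (flag when the
minority class is below 35 %) but never corrected.

**Zero-shot protocol.** When the trained pipeline is applied to a new
plant without retraining, the new data is standardized with the *first*
plant's frozen statistics — a never-retrained deployment has nothing
else. The new plant's own train-fit statistics come into existence only
at fine-tuning time, together with its chronological split. This detail
is what produces the characteristic cross-plant accuracy collapse: the
variant's light/dark *signature* is nearly identical in shape, but its
*baseline* lands far from where the frozen scaler expects it.

## Classifier

LSTM (16 units, sequences returned, forget-gate bias initialized to 1,
Glorot input / orthogonal recurrent initialization) over the burst's
sweeps as timesteps; additive attention
`e_t = vᵀ tanh(W h_t + b)`, `α = softmax(e)`, context `c = Σ α_t h_t`;
Dense(16, ReLU) with L2 1e-3 on its kernel; dropout 0.5 after the LSTM
sequence output and after the dense hidden layer; sigmoid output with
light = 1 and decision threshold ≥ 0.5.

Training: Adam (1e-3, β = 0.9/0.999, ε = 1e-7), binary cross-entropy,
batch 32, ≤ 100 epochs. Early stopping monitors validation loss with
patience 10 and restores the best weights; with a constant monitored loss
training halts after patience + 1 epochs (the first epoch sets the
incumbent). ReduceLROnPlateau halves the rate after 5 stale epochs, floor
1e-5. Fine-tuning restarts Adam at 5e-4 with plateau patience 3, keeps
every layer trainable, and seeds the early-stopping incumbent with the
incoming weights' validation loss, so restoration can never end below the
starting point on the monitored metric; `max_epochs=0` is an exact no-op.

The network is implemented directly in NumPy (float64) with hand-derived
backpropagation through time. This keeps the package dependency-light,
makes every run bit-for-bit reproducible from a single integer seed on
one thread, and exposes exact input gradients for attribution. The
backward pass is verified against central finite differences for every
parameter tensor and for the input gradient; an overfit check on a
linearly separable toy set and a dead-branch (nonzero-gradient) check
guard the training loop.

## Attribution

Integrated gradients with a right-Riemann approximation (`m` = 50 by
default) of the path integral from an all-zeros baseline — the dataset
mean in standardized space, i.e. the least-informative reference — to the
input, computed on the output probability with dropout off. Completeness
(Σ IG ≈ F(x) − F(baseline) within 2 % at m = 200) and exactness on linear
models are tested; per-frequency reduction sums over time (conserving the
total), ranking uses |importance| with ties broken toward the lower bin,
and band summaries aggregate |importance| over [low, high) Hz. The
nominal 0–30 kHz report band reduces to its [20, 30) kHz overlap with the
sweep grid.

## Evaluation

Per-cycle accuracy assigns every evaluated sample to exactly one schedule
phase (half-open phase intervals; the final boundary belongs to the last
phase). Detection delay is the time from a switch to the first of 3
consecutive correct predictions before the next switch (−1 when none);
the 3-sample run guards against single-burst flicker. Delay is measured
on unfiltered predictions, because delays shorter than the 10-min
transition filter would otherwise be unobservable; cycle accuracy uses
the filtered evaluation split.

## Problem sizes and defaults

The reference study simulates 48 h per plant at one burst per minute with
20 sweeps per burst (the wire format's 100 sweeps are retained as the
acquisition default; 20 keeps a full three-replicate study around a
minute of CPU while leaving the per-burst noise averaging qualitatively
intact). Three replicate seeds are run and medians reported.
Desk-scale accuracies: median best validation accuracy on the primary
plant ≈ 97–99 %, zero-shot on the shift-0.3 variant ≈ 33–98 % (strongly
dependent on where the variant's drift trajectory wanders relative to the
frozen scaler), post-fine-tune test accuracy ≈ 79–99 % with medians above
98 %. These numbers are recomputed, not stored, by
`scripts/acceptance.py` and the acceptance test module.

## Known limitations

- The peak-sum envelope ignores harmonic phase; a time-domain rectifier
  simulation would sit slightly lower and is out of scope.
- Amplitudes are in arbitrary units; absolute voltages and the ADC
  reference are not modeled.
- The variant-plant generator preserves the shape of the light/dark
  difference spectrum almost exactly; cross-plant difficulty comes from
  baseline displacement and drift, not from a qualitatively different
  physiological response.
- Pure-NumPy training is single-threaded; it is sized for desk-scale
  studies (thousands of bursts), not for multi-week corpora.
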