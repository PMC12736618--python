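# phytosense

Swept-frequency plant bioimpedance simulation and light/dark state
classification.

A living plant wired into an RLC measurement network acts as a complex,
frequency-dependent load: its ionic content, membranes and hydration set a
bioimpedance spectrum that changes with physiological state. `phytosense`
models the complete sensing-and-inference chain for a grow-box experiment
in which a plant's exposure to light is read back out of nothing but its
electrical response:

1. **Analog front end** — a square-wave source drives a 10 kΩ series
   resistor into a parallel resonant tank (L = 30 mH, C = 1 nF,
   R = 4.7 kΩ), coupled to the plant through 10 nF; the plant-node voltage
   passes an ideal envelope detector (R = 1 MΩ, C = 100 pF, cutoff
   1/(2πRC) ≈ 1.6 kHz). Sweeping 20–249 kHz in 1 kHz steps (230 points,
   1 ms dwell) yields one band-pass-shaped amplitude spectrum per sweep.
2. **Plant load** — a single-dispersion Cole impedance
   `Z(ω) = R∞ + (R0 − R∞)/(1 + (jωτ)^α)`, whose parameters relax toward
   light- or dark-specific targets with a lag of a few minutes and drift
   slowly over hours.
3. **Acquisition** — one burst per minute of 100 consecutive sweeps
   (≈ 23 s), each point quantized to 2 bytes (460 B per sweep on the
   wire), stored as labeled `(sweeps × 230)` samples in a self-describing
   HDF5 container.
4. **Classifier** — per-frequency standardization (train-fit only), a
   strict chronological 60/20/20 split, and an LSTM(16) →
   additive-attention → Dense(16, ReLU, L2 1e-3) → sigmoid network trained
   with Adam (1e-3, batch 32, ≤ 100 epochs, early stopping patience 10,
   LR-on-plateau), implemented in NumPy with hand-derived backpropagation
   so runs are bit-reproducible from a seed.
5. **Cross-plant transfer** — a parameter-shifted "second plant" is
   classified zero-shot with the first plant's frozen pipeline (accuracy
   collapses), then recovered by fine-tuning on the second plant's own
   training split at a reduced rate of 5e-4.
6. **Attribution** — integrated gradients
   `IG_i = (x_i − x′_i)·(1/m)Σ_k ∂F(x′ + (k/m)(x − x′))/∂x_i`
   per burst, reduced to per-frequency importances, top-10 feature trends
   and frequency-band summaries.

The package is aimed at researchers prototyping plant-as-sensor pipelines
who need a controllable, fully synthetic test bed before committing to
hardware.

## Worked example

```python
from phytosense.evaluation import ExperimentConfig, run_experiment

cfg = ExperimentConfig(duration_min=720.0, seed=7)   # 12 h study
res = run_experiment(cfg)
print("acc_A_val       ", round(res["acc_A_val"], 4))
print("acc_A_test      ", round(res["acc_A_test"], 4))
print("acc_B_zero_shot ", round(res["acc_B_zero_shot"], 4))
print("acc_B_finetuned ", round(res["acc_B_finetuned"], 4))
print(list(res["delay_report"].transitions["delay_min"]))
```

prints

```
acc_A_val        0.9925
acc_A_test       0.9925
acc_B_zero_shot  0.3358
acc_B_finetuned  0.9701
[5.13, 0.41, 4.07, 2.34, 5.74]
```

The classifier reads the first plant's light state almost perfectly
(99.3 % validation and test accuracy). Applied unchanged to the shifted
second plant it collapses to 33.6 % — the two plants' baselines differ, so
the frozen standardization maps plant B far from the decision surface —
and fine-tuning on plant B's own training split restores 97.0 %. The
detection delays (minutes from each light switch until three consecutive
correct predictions) land between 0.4 and 5.7 min, consistent with the
simulated physiological response lag of 5 min.

The same pipeline is available from the shell:

```sh
phytosense run-all --seed 7 --out out/       # full study + plots/reports
phytosense simulate --config exp.yaml --out data/
```

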