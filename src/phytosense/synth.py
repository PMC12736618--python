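"""Synthetic grow-box experiment: schedules, plant dynamics, burst datasets.

The generator emulates the in-vivo experiment the pipeline is meant for:
a plant in a grow box whose lights alternate at irregular intervals of one
to three hours, sampled once per minute with a burst of frequency sweeps.
The plant's electrical state is a Cole parameter set that relaxes
exponentially toward a light- or dark-specific target with a lag of a few
minutes (the plant's physiological response time), on top of a slow
multiplicative random-walk drift of its resistances (electrode/hydration
baseline drift).  Rendered through the circuit model plus measurement
noise, this yields labeled 100×230-style burst datasets with the same
structure as the real acquisition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .circuit import (CircuitComponents, ColeLoadParameters, SweepConfig,
                      sweep_response)
from .dataio import (AcquisitionConfig, DatasetContainer, LabeledSample,
                     burst_duration, quantize, DEFAULT_FULL_SCALE)

__all__ = [
    "LightSchedule",
    "PlantProfile",
    "default_profile",
    "generate_schedule",
    "simulate_plant_state",
    "generate_dataset",
    "make_variant_profile",
]

_COLE_FIELDS = ("r0", "r_inf", "tau", "alpha")


@dataclass(frozen=True)
class LightSchedule:
    """Alternating dark/light phases with durations in minutes."""

    phases: tuple  # of (state, duration_minutes)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        states = [s for s, _ in self.phases]
        if any(s not in ("dark", "light") for s in states):
            raise ValueError("states must be 'dark' or 'light'")
        if any(a == b for a, b in zip(states, states[1:])):
            raise ValueError("states must strictly alternate")
        if any(d <= 0 for _, d in self.phases):
            raise ValueError("phase durations must be positive")
        object.__setattr__(self, "phases", tuple(
            (s, float(d)) for s, d in self.phases))

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.phases)

    @property
    def end_time(self) -> float:
        return self.start_time + self.total_duration

    @property
    def switch_times(self) -> np.ndarray:
        """Times of the internal light↔dark transitions (minutes)."""
        edges = self.start_time + np.cumsum([d for _, d in self.phases])
        return edges[:-1]

    def boundaries(self) -> Iterator[tuple[str, float, float]]:
        """Yield (state, start, end) per phase."""
        t = self.start_time
        for state, dur in self.phases:
            yield state, t, t + dur
            t += dur

    def state_at(self, t: float) -> str:
        """Scheduled state at time t (end boundary belongs to the last phase)."""
        if not (self.start_time <= t <= self.end_time):
            raise ValueError(f"t={t} outside schedule span")
        for state, lo, hi in self.boundaries():
            if lo <= t < hi:
                return state
        return self.phases[-1][0]

    def digest(self) -> str:
        raw = repr((self.start_time, self.phases)).encode()
        return hashlib.sha256(raw).hexdigest()[:16]


@dataclass(frozen=True)
class PlantProfile:
    """Per-plant ground truth: state targets, lag, drift and noise levels.

    tau_resp is the exponential relaxation time constant of the Cole
    parameters toward the active state's target (minutes); drift_sd the
    per-√minute SD of a geometric random walk applied to r0 and r_inf;
    noise_sd the additive amplitude-noise SD of the measurement in
    simulator units (default 2% of the ADC full scale).
    """

    dark_target: ColeLoadParameters
    light_target: ColeLoadParameters
    tau_resp: float = 5.0
    drift_sd: float = 0.002
    noise_sd: float = 0.02 * DEFAULT_FULL_SCALE
    profile_id: str = "plant-A"

    def __post_init__(self) -> None:
        if self.tau_resp <= 0:
            raise ValueError("tau_resp must be positive")
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError("drift_sd and noise_sd must be non-negative")

    def target(self, state: str) -> ColeLoadParameters:
        return self.dark_target if state == "dark" else self.light_target


def default_profile(**overrides) -> PlantProfile:
    """Reference plant: illumination lowers r0 by 30% and tau by 20%.

    The dark-state Cole values (50 kΩ / 2 kΩ, τ = 2 µs, α = 0.8) put the
    plant's impedance magnitude in the same decade as the series resistor
    and tank, so the divider transfers a double-digit-percent load change
    into a percent-level amplitude change — detectable above the default
    noise floor without being trivial.
    """
    dark = ColeLoadParameters(r0=50e3, r_inf=2e3, tau=2e-6, alpha=0.8)
    light = dark.scaled(r0=0.7, tau=0.8)
    params = dict(dark_target=dark, light_target=light)
    params.update(overrides)
    return PlantProfile(**params)


def generate_schedule(total: float, min_phase: float = 60.0,
                      max_phase: float = 180.0, initial_state: str = "dark",
                      seed: int | np.random.Generator = 0) -> LightSchedule:
    """Draw an alternating schedule with uniform phase lengths.

    Phase durations are i.i.d. uniform on [min_phase, max_phase] minutes;
    the last phase is truncated so the schedule spans exactly `total`
    minutes.  Deterministic for a fixed seed.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 < min_phase <= max_phase):
        raise ValueError("require 0 < min_phase <= max_phase")
    if initial_state not in ("dark", "light"):
        raise ValueError("initial_state must be 'dark' or 'light'")
    rng = np.random.default_rng(seed)
    phases: list[tuple[str, float]] = []
    state, remaining = initial_state, float(total)
    while remaining > 0:
        dur = min(float(rng.uniform(min_phase, max_phase)), remaining)
        phases.append((state, dur))
        remaining -= dur
        state = "light" if state == "dark" else "dark"
    return LightSchedule(tuple(phases))


def simulate_plant_state(schedule: LightSchedule, profile: PlantProfile,
                         dt: float = 1.0,
                         seed: int | np.random.Generator = 0
                         ) -> tuple[np.ndarray, list[ColeLoadParameters]]:
    """Lagged Cole-parameter trajectory over the schedule span.

    Each parameter relaxes toward the active state's target with first-order
    kinetics (time constant tau_resp); r0 and r_inf then pick up a
    multiplicative log-normal drift increment exp(N(0, drift_sd·√dt)).
    Returns (times in minutes, parameter list), one entry per step starting
    at the schedule start (initialized at the initial state's target).
    alpha is clipped to (0, 1] so every entry is a valid parameter set.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    times = schedule.start_time + dt * np.arange(
        int(np.floor(schedule.total_duration / dt)) + 1)
    times = times[times <= schedule.end_time]
    state0 = schedule.state_at(times[0])
    current = {f: getattr(profile.target(state0), f) for f in _COLE_FIELDS}
    drift = {"r0": 1.0, "r_inf": 1.0}
    # relaxation gain per step; alpha=1 step reaches the target exactly
    # (explicit Euler is clipped at 1 so dt >> tau_resp stays stable)
    gain = min(dt / profile.tau_resp, 1.0)
    out: list[ColeLoadParameters] = []

    def emit() -> None:
        r0 = current["r0"] * drift["r0"]
        r_inf = current["r_inf"] * drift["r_inf"]
        r_inf = min(r_inf, 0.999 * r0)  # keep r0 > r_inf under drift
        out.append(ColeLoadParameters(
            r0=r0, r_inf=r_inf, tau=current["tau"],
            alpha=float(np.clip(current["alpha"], 1e-6, 1.0))))

    emit()
    for t in times[1:]:
        target = profile.target(schedule.state_at(min(t, schedule.end_time)))
        for f in _COLE_FIELDS:
            current[f] += gain * (getattr(target, f) - current[f])
        if profile.drift_sd > 0:
            # one shared baseline factor: hydration/contact drift scales the
            # whole resistive path, not r0 and r_inf separately
            step = float(np.exp(rng.normal(0.0, profile.drift_sd * np.sqrt(dt))))
            for f in drift:
                drift[f] *= step
        emit()
    return times, out


def generate_dataset(schedule: LightSchedule, profile: PlantProfile,
                     acq: AcquisitionConfig | None = None,
                     comps: CircuitComponents | None = None,
                     seed: int = 0,
                     full_scale: float = DEFAULT_FULL_SCALE
                     ) -> DatasetContainer:
    """Render a schedule + plant into a labeled burst dataset.

    One sample per acquisition interval; each burst shares the plant state
    of its minute (a burst lasts ~23 s, short against tau_resp) and differs
    across sweeps only through measurement noise.  Amplitudes are quantized
    to uint16 against `full_scale`.  Fully reproducible for a fixed seed.
    """
    acq = acq or AcquisitionConfig()
    comps = comps or CircuitComponents()
    rng = np.random.default_rng(seed)
    state_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))
    times, states = simulate_plant_state(
        schedule, profile, dt=acq.interval, seed=state_rng)
    samples: list[LabeledSample] = []
    n_points = acq.sweep.n_points
    for t, load in zip(times, states):
        # an end-of-span sample belongs to no burst (tolerance absorbs the
        # float error of summed phase durations)
        if t >= schedule.end_time - 1e-9:
            break
        clean = sweep_response(acq.sweep, comps, load, noise_sd=0.0)
        burst = np.broadcast_to(clean, (acq.sweeps_per_burst, n_points)).copy()
        if profile.noise_sd > 0:
            burst += noise_rng.normal(0.0, profile.noise_sd, size=burst.shape)
        burst = np.maximum(burst, 0.0)
        samples.append(LabeledSample(
            timestamp=float(t),
            data=quantize(burst, full_scale),
            label=schedule.state_at(t)))
    manifest = {
        "full_scale": full_scale,
        "sweeps_per_burst": acq.sweeps_per_burst,
        "n_points": n_points,
        "interval_min": acq.interval,
        "f_start": acq.sweep.f_start,
        "f_stop": acq.sweep.f_stop,
        "f_step": acq.sweep.f_step,
        "dwell": acq.sweep.dwell,
        "schedule_digest": schedule.digest(),
        "seed": int(seed),
        "profile_id": profile.profile_id,
    }
    return DatasetContainer(samples, manifest)


def make_variant_profile(base: PlantProfile, shift: float = 0.3,
                         seed: int = 0) -> PlantProfile:
    """Synthesize a "second plant" by jittering the base profile.

    Each Cole target parameter is multiplied by an independent log-normal
    factor exp(N(0, shift)); the same factor is applied to the dark and
    light targets of a parameter, so the direction of the light effect is
    preserved while the plant's baseline moves.  shift=0 returns the
    profile unchanged (modulo the new id).
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    rng = np.random.default_rng(seed)
    factors = {f: float(np.exp(rng.normal(0.0, shift))) for f in _COLE_FIELDS}

    def shifted(target: ColeLoadParameters) -> ColeLoadParameters:
        vals = {f: getattr(target, f) * factors[f] for f in _COLE_FIELDS}
        vals["alpha"] = min(vals["alpha"], 1.0)
        return ColeLoadParameters(**vals)

    return replace(base,
                   dark_target=shifted(base.dark_target),
                   light_target=shifted(base.light_target),
                   profile_id=f"{base.profile_id}-variant")
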