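"""Analog front-end model for swept-frequency plant bioimpedance sensing.

The measurement chain is: a square-wave excitation source, a 10 kΩ series
resistor, a parallel resonant tank (30 mH ∥ 1 nF ∥ 4.7 kΩ) at node A, a
10 nF coupling capacitor to node B, and the plant itself from node B to
ground.  The plant is represented as a single-dispersion Cole impedance

    Z(ω) = R∞ + (R0 − R∞) / (1 + (jωτ)^α),

the standard minimal parameterization of tissue bioimpedance.  The measured
quantity per frequency point is the envelope-detected amplitude at node B
(across the plant), so a full sweep traces out a band-pass-like amplitude
vs. frequency curve that shifts as the plant's electrical state changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CircuitComponents",
    "ColeLoadParameters",
    "SweepConfig",
    "OPEN_CIRCUIT",
    "plant_impedance",
    "network_response",
    "envelope_cutoff",
    "sweep_response",
    "square_wave_harmonics",
]

#: Sentinel load meaning "nothing attached": the coupling branch is left open
#: and the response reduces to the node-A resistive/tank divider.
OPEN_CIRCUIT = "open"


@dataclass(frozen=True)
class CircuitComponents:
    """Component values of the analog front end (SI units)."""

    r_series: float = 10e3
    l_tank: float = 30e-3
    c_tank: float = 1e-9
    r_damp: float = 4.7e3
    c_couple: float = 10e-9
    r_env: float = 1e6
    c_env: float = 100e-12
    v_diode: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_series", "l_tank", "c_tank", "r_damp", "c_couple",
                     "r_env", "c_env"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.v_diode < 0:
            raise ValueError("v_diode must be non-negative")

    @property
    def tank_resonance_hz(self) -> float:
        """Unloaded LC tank resonance 1/(2π√(LC))."""
        return 1.0 / (2 * math.pi * math.sqrt(self.l_tank * self.c_tank))


@dataclass(frozen=True)
class ColeLoadParameters:
    """Single-dispersion Cole model of the plant load.

    r0 and r_inf are the low/high-frequency resistances (Ω), tau the
    dispersion time constant (s) and alpha ∈ (0, 1] the dispersion
    broadness (alpha = 1 recovers a single-pole Debye relaxation).
    """

    r0: float
    r_inf: float
    tau: float
    alpha: float = 0.8

    def __post_init__(self) -> None:
        if not (self.r0 > self.r_inf > 0):
            raise ValueError("require r0 > r_inf > 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    def scaled(self, **factors: float) -> "ColeLoadParameters":
        """Return a copy with named fields multiplied by given factors."""
        return replace(self, **{k: getattr(self, k) * v
                                for k, v in factors.items()})


@dataclass(frozen=True)
class SweepConfig:
    """Frequency-sweep grid: 20–249 kHz in 1 kHz steps, 1 ms dwell.

    The grid is inclusive of both ends, so the defaults give exactly 230
    points per sweep.
    """

    f_start: float = 20e3
    f_stop: float = 249e3
    f_step: float = 1e3
    dwell: float = 1e-3

    def __post_init__(self) -> None:
        if self.f_start >= self.f_stop:
            raise ValueError("f_start must be below f_stop")
        if self.f_step <= 0 or self.dwell <= 0:
            raise ValueError("f_step and dwell must be positive")

    @property
    def n_points(self) -> int:
        return int(math.floor((self.f_stop - self.f_start) / self.f_step)) + 1

    @property
    def frequencies(self) -> np.ndarray:
        return self.f_start + self.f_step * np.arange(self.n_points)


def plant_impedance(params: ColeLoadParameters,
                    freq: float | np.ndarray) -> complex | np.ndarray:
    """Complex Cole impedance Z(ω) = R∞ + (R0 − R∞)/(1 + (jωτ)^α).

    Accepts a scalar frequency in Hz or an array; frequencies must be
    non-negative.  At DC the dispersion term vanishes and Z = R0 exactly.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    jwt = 1j * 2 * np.pi * f * params.tau
    # 0**alpha is 0 for alpha > 0, numpy handles the complex power branch
    z = params.r_inf + (params.r0 - params.r_inf) / (1 + jwt ** params.alpha)
    if np.isscalar(freq) or np.ndim(freq) == 0:
        return complex(z)
    return z


def _branch_admittances(freq, comps: CircuitComponents, z_plant):
    w = 2 * np.pi * np.asarray(freq, dtype=float)
    y_series = 1.0 / comps.r_series
    with np.errstate(divide="ignore"):
        y_tank = np.where(
            w > 0,
            1.0 / (1j * np.where(w > 0, w, 1.0) * comps.l_tank)
            + 1j * w * comps.c_tank + 1.0 / comps.r_damp,
            np.inf + 0j,
        )
    y_couple = 1j * w * comps.c_couple
    if isinstance(z_plant, str):
        if z_plant != OPEN_CIRCUIT:
            raise ValueError(f"unknown load sentinel {z_plant!r}")
        y_plant = np.zeros_like(y_couple)
    else:
        zp = np.asarray(z_plant, dtype=complex)
        if not np.all(np.isfinite(zp)):
            raise ValueError("z_plant must be finite (or the open sentinel)")
        y_plant = 1.0 / zp
    return y_series, y_tank, y_couple, y_plant


def network_response(freq, comps: CircuitComponents, z_plant,
                     node: str = "B"):
    """Complex voltage gain of the coupled network at `freq` Hz.

    Nodal analysis of the two-node network (source → r_series → node A with
    the tank to ground; node A → c_couple → node B with the plant to
    ground).  ``node="B"`` (default) returns the gain across the plant;
    ``node="A"`` the gain at the tank node.  The open-circuit sentinel for
    ``z_plant`` removes the plant branch, in which case node B floats at the
    node-A potential.
    """
    if node not in ("A", "B"):
        raise ValueError("node must be 'A' or 'B'")
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    ys, yt, yc, yp = _branch_admittances(f, comps, z_plant)

    # Solve [[ys+yt+yc, -yc], [-yc, yc+yp]] @ [vA, vB] = [ys, 0] in closed
    # form.  At DC the inductor shorts node A and the coupling capacitor
    # blocks node B, so both gains are exactly zero.
    dc = f == 0
    ytank = np.where(dc, 0.0 + 0j, yt)  # placeholder; dc handled below
    det = (ys + ytank + yc) * (yc + yp) - yc * yc
    with np.errstate(invalid="ignore", divide="ignore"):
        va = ys * (yc + yp) / det
        vb = ys * yc / det
        # open plant branch: no current through c_couple, vB tracks vA
        open_branch = np.abs(yc + yp) == 0
        va = np.where(open_branch, ys / (ys + ytank), va)
        vb = np.where(open_branch, va, vb)
    gain = va if node == "A" else vb
    gain = np.where(dc, 0.0 + 0j, gain)
    if np.ndim(freq) == 0:
        return complex(gain)
    return gain


def envelope_cutoff(r_env: float, c_env: float) -> float:
    """−3 dB cutoff 1/(2πRC) of the envelope detector's RC low-pass, Hz."""
    if r_env <= 0 or c_env <= 0:
        raise ValueError("r_env and c_env must be positive")
    return 1.0 / (2 * math.pi * r_env * c_env)


def square_wave_harmonics(fundamental: float, f_limit: float) -> np.ndarray:
    """Odd harmonic orders k of a square wave with k·f ≤ f_limit (k ≥ 1)."""
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    k_max = int(f_limit // fundamental)
    if k_max < 1:
        return np.array([1])  # always keep the fundamental
    return np.arange(1, k_max + 1, 2)


def sweep_response(cfg: SweepConfig, comps: CircuitComponents,
                   load: ColeLoadParameters, *,
                   excitation: str = "square",
                   harmonic_limit: float = 1e6,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None,
                   node: str = "B") -> np.ndarray:
    """One amplitude-vs-frequency sweep for a given plant state.

    For each grid frequency f the excitation is either a unit square wave
    (``"square"``: odd harmonics k with amplitude 4/(πk), kept while
    k·f ≤ harmonic_limit) or its pure fundamental (``"fundamental"``,
    amplitude 4/π).  The ideal peak-detector output is the sum of the
    per-harmonic steady-state response magnitudes minus the diode drop,
    clipped at zero; Gaussian noise of SD ``noise_sd`` is then added and the
    result clipped at zero again.  With ``noise_sd=0`` the sweep is fully
    deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if excitation not in ("square", "fundamental"):
        raise ValueError("excitation must be 'square' or 'fundamental'")
    freqs = cfg.frequencies
    if excitation == "fundamental":
        orders = np.array([1])
    else:
        orders = square_wave_harmonics(cfg.f_start, harmonic_limit)
    # (n_harmonics, n_points) grid of harmonic frequencies
    hf = orders[:, None] * freqs[None, :]
    keep = hf <= harmonic_limit
    keep[0, :] = True  # fundamental always excites
    zp = plant_impedance(load, hf.ravel()).reshape(hf.shape)
    gains = network_response(hf.ravel(), comps, zp.ravel(), node=node)
    gains = np.abs(gains.reshape(hf.shape))
    amps = (4.0 / (np.pi * orders))[:, None] * gains * keep
    envelope = np.maximum(amps.sum(axis=0) - comps.v_diode, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        envelope = envelope + rng.normal(0.0, noise_sd, size=envelope.shape)
    return np.maximum(envelope, 0.0)
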