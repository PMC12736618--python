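"""Sweep payload encoding and the on-disk burst dataset container.

Each per-minute acquisition ("burst") is 100 consecutive sweeps of 230
frequency points, every point quantized to an unsigned 16-bit integer
(2 bytes/point → 460 bytes/sweep on the wire).  A dataset is an ordered
sequence of labeled bursts with a manifest describing how it was acquired;
it is stored as an HDF5 file holding the uint16 amplitude cube, timestamps,
labels, and the manifest as a JSON attribute, so a file is fully
self-describing.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .circuit import SweepConfig

__all__ = [
    "LABELS",
    "SweepRecord",
    "LabeledSample",
    "DatasetContainer",
    "AcquisitionConfig",
    "encode_sweep",
    "decode_sweep",
    "quantize",
    "dequantize",
    "burst_duration",
    "write_dataset",
    "read_dataset",
    "export_csv",
    "IntegrityError",
]

#: Fixed label vocabulary for the light/dark experiment.
LABELS = ("dark", "light")

#: Default ADC full-scale amplitude (simulator units mapped onto 65535).
DEFAULT_FULL_SCALE = 2.0


class IntegrityError(ValueError):
    """Raised when a container's manifest and payload disagree."""


@dataclass(frozen=True)
class SweepRecord:
    """One quantized sweep: n_points uint16 envelope samples."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes)
        if a.ndim != 1:
            raise ValueError("amplitudes must be a 1-D vector")
        if np.any(a < 0) or np.any(a > 0xFFFF):
            raise ValueError("amplitude outside the 16-bit range [0, 65535]")
        object.__setattr__(self, "amplitudes", a.astype(np.uint16))

    def __eq__(self, other) -> bool:
        return (isinstance(other, SweepRecord)
                and np.array_equal(self.amplitudes, other.amplitudes))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Burst acquisition protocol: one burst of sweeps every `interval` min."""

    interval: float = 1.0
    sweeps_per_burst: int = 100
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.sweeps_per_burst < 1:
            raise ValueError("sweeps_per_burst must be at least 1")
        if burst_duration(self) >= self.interval * 60.0:
            raise ValueError("burst duration must fit inside the interval")


def burst_duration(acq: AcquisitionConfig) -> float:
    """Duration of one burst in seconds (sweeps × points × dwell)."""
    return acq.sweeps_per_burst * acq.sweep.n_points * acq.sweep.dwell


@dataclass
class LabeledSample:
    """One burst: (sweeps × n_points) uint16 matrix with label + timestamp."""

    timestamp: float  # minutes since run start
    data: np.ndarray  # (sweeps_per_burst, n_points) uint16
    label: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError("data must be (sweeps, n_points)")
        if np.any(d < 0) or np.any(d > 0xFFFF):
            raise ValueError("amplitude outside the 16-bit range")
        self.data = d.astype(np.uint16)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")

    @property
    def times(self) -> int:
        """Measurements per frequency in this sample (= sweeps per burst)."""
        return self.data.shape[0]


@dataclass
class DatasetContainer:
    """Ordered labeled bursts plus an acquisition manifest.

    The manifest is a plain JSON-serializable dict recording the sweep grid,
    burst protocol, amplitude full scale, the generating seed/schedule
    digest and the plant profile id, so a stored file needs no side
    information to be interpreted.
    """

    samples: list[LabeledSample]
    manifest: dict

    def __post_init__(self) -> None:
        ts = [s.timestamp for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("samples must be strictly increasing in time")
        self.manifest = dict(self.manifest)
        self.manifest.setdefault("n_samples", len(self.samples))
        if self.samples:
            sweeps, n_points = self.samples[0].data.shape
            self.manifest.setdefault("sweeps_per_burst", sweeps)
            self.manifest.setdefault("n_points", n_points)
            for s in self.samples:
                if s.data.shape != (self.manifest["sweeps_per_burst"],
                                    self.manifest["n_points"]):
                    raise IntegrityError("sample shape disagrees with manifest")
        self.manifest.setdefault("full_scale", DEFAULT_FULL_SCALE)

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DatasetContainer):
            return NotImplemented
        if self.manifest != other.manifest or len(self) != len(other):
            return False
        return all(a.timestamp == b.timestamp and a.label == b.label
                   and np.array_equal(a.data, b.data)
                   for a, b in zip(self.samples, other.samples))

    # -- columnar views ----------------------------------------------------
    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.samples], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def data_cube(self, dtype=np.float64) -> np.ndarray:
        """(n_samples, sweeps, n_points) array of dequantized amplitudes."""
        cube = np.stack([s.data for s in self.samples])
        if np.issubdtype(np.dtype(dtype), np.floating):
            return dequantize(cube, self.manifest["full_scale"]).astype(dtype)
        return cube.astype(dtype)

    def subset(self, indices: Sequence[int]) -> "DatasetContainer":
        manifest = {k: v for k, v in self.manifest.items() if k != "n_samples"}
        return DatasetContainer([self.samples[i] for i in indices], manifest)


def quantize(amplitudes: np.ndarray, full_scale: float = DEFAULT_FULL_SCALE
             ) -> np.ndarray:
    """Map float amplitudes [0, full_scale] → uint16 [0, 65535].

    Round-half-to-even, clipped at both rails (the ADC saturates rather
    than wraps).
    """
    if full_scale <= 0:
        raise ValueError("full_scale must be positive")
    scaled = np.asarray(amplitudes, dtype=float) * (0xFFFF / full_scale)
    return np.clip(np.rint(scaled), 0, 0xFFFF).astype(np.uint16)


def dequantize(codes: np.ndarray, full_scale: float = DEFAULT_FULL_SCALE
               ) -> np.ndarray:
    """Inverse of :func:`quantize` up to quantization error."""
    return np.asarray(codes, dtype=float) * (full_scale / 0xFFFF)


def encode_sweep(rec: SweepRecord) -> bytes:
    """Encode one sweep as little-endian uint16, 2 bytes per point."""
    return rec.amplitudes.astype("<u2").tobytes()


def decode_sweep(payload: bytes, n_points: int) -> SweepRecord:
    """Exact inverse of :func:`encode_sweep`."""
    if len(payload) != 2 * n_points:
        raise ValueError(
            f"payload is {len(payload)} bytes, expected {2 * n_points}")
    return SweepRecord(np.frombuffer(payload, dtype="<u2").copy())


def write_dataset(ds: DatasetContainer, path) -> None:
    """Write a container to an HDF5 file (uint16 cube + manifest JSON)."""
    with h5py.File(path, "w") as f:
        if ds.samples:
            cube = np.stack([s.data for s in ds.samples])
        else:
            cube = np.zeros((0, 0, 0), dtype=np.uint16)
        f.create_dataset("amplitudes", data=cube, dtype=np.uint16)
        f.create_dataset("timestamps", data=ds.timestamps)
        f.create_dataset(
            "labels", data=np.array([s.label for s in ds.samples], dtype="S8"))
        f.attrs["manifest"] = json.dumps(ds.manifest, sort_keys=True)


def read_dataset(path) -> DatasetContainer:
    """Read a container back; validates payload against its manifest."""
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        cube = f["amplitudes"][...]
        timestamps = f["timestamps"][...]
        labels = [x.decode() for x in f["labels"][...]]
    if cube.shape[0] != manifest.get("n_samples", cube.shape[0]):
        raise IntegrityError("stored sample count disagrees with manifest")
    if cube.shape[0] and (
            cube.shape[1] != manifest.get("sweeps_per_burst", cube.shape[1])
            or cube.shape[2] != manifest.get("n_points", cube.shape[2])):
        raise IntegrityError("stored sample shape disagrees with manifest")
    samples = [LabeledSample(float(t), d, lab)
               for t, d, lab in zip(timestamps, cube, labels)]
    return DatasetContainer(samples, manifest)


def export_csv(ds: DatasetContainer, path) -> pd.DataFrame:
    """One-row-per-sample CSV for quick inspection (mean sweep per burst)."""
    frame = pd.DataFrame({
        "timestamp_min": ds.timestamps,
        "label": ds.labels,
        "times": [s.times for s in ds.samples],
        "mean_amplitude": [float(dequantize(s.data,
                                            ds.manifest["full_scale"]).mean())
                           for s in ds.samples],
    })
    frame.to_csv(path, index=False)
    return frame
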