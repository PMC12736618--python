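"""Data conditioning: transition filtering, chronological split, scaling.

The order of operations matters for a time series: samples inside the
post-transition settling window are dropped first, the remainder is split
into contiguous chronological train/validation/test blocks, and the
standardizer is fit on the training block only so no statistic of the
evaluation data leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataio import DatasetContainer, LABELS
from .synth import LightSchedule

__all__ = [
    "SplitSpec",
    "filter_transitions",
    "chronological_split",
    "BurstStandardizer",
    "standardize",
    "class_balance_report",
    "labels_to_binary",
]

#: Class encoding used throughout: light = 1, dark = 0.
POSITIVE_LABEL = "light"


def labels_to_binary(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(np.int64)


@dataclass(frozen=True)
class SplitSpec:
    """Chronological split fractions; defaults 60/20/20."""

    train_frac: float = 0.60
    val_frac: float = 0.20
    test_frac: float = 0.20

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not (0 < f < 1) for f in fracs):
            raise ValueError("fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def filter_transitions(ds: DatasetContainer, schedule: LightSchedule,
                       window: float = 10.0) -> DatasetContainer:
    """Drop samples inside the settling window after each light transition.

    A sample at time t is removed when t_switch ≤ t < t_switch + window for
    any switch time (half-open, so the switch minute itself goes and the
    sample exactly `window` minutes later stays).  window=0 is the identity.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    ts = ds.timestamps
    if len(ts) and not (schedule.start_time <= ts[0]
                        and ts[-1] <= schedule.end_time):
        raise ValueError("schedule does not cover the dataset span")
    keep = np.ones(len(ts), dtype=bool)
    for sw in schedule.switch_times:
        keep &= ~((ts >= sw) & (ts < sw + window))
    return ds.subset(np.flatnonzero(keep))


def chronological_split(ds: DatasetContainer, spec: SplitSpec | None = None
                        ) -> tuple[DatasetContainer, DatasetContainer,
                                   DatasetContainer]:
    """Contiguous prefix/middle/suffix split in time order.

    Sizes are floor(N·train_frac) and floor(N·val_frac); the remainder goes
    to test, so with the default fractions N=100 gives 60/20/20.
    """
    spec = spec or SplitSpec()
    n = len(ds)
    n_train = int(np.floor(n * spec.train_frac))
    n_val = int(np.floor(n * spec.val_frac))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"{n} samples are too few for three partitions")
    idx = np.arange(n)
    return (ds.subset(idx[:n_train]),
            ds.subset(idx[n_train:n_train + n_val]),
            ds.subset(idx[n_train + n_val:]))


class BurstStandardizer(BaseEstimator, TransformerMixin):
    """Per-frequency standardization of burst cubes, fit on training data.

    Input is an (n_samples, sweeps, n_points) amplitude cube.  With
    ``mode="frequency"`` (default) a mean/SD pair is estimated per frequency
    bin, pooling all sweeps of all training samples — the plant state is
    constant within a burst, so sweeps are repeated draws of the same
    spectrum.  ``mode="cell"`` estimates a pair per (sweep, frequency) cell
    instead.  Constant features transform to exactly 0.

    Fitted attributes: ``mean_``, ``scale_`` (per feature), ``mode_``.
    """

    def __init__(self, mode: str = "frequency"):
        self.mode = mode

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a standardizer on an empty partition")
        if self.mode == "frequency":
            flat = X.reshape(-1, X.shape[2])
        else:  # cell
            flat = X.reshape(X.shape[0], -1)
        self.mean_ = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.mode_ = self.mode
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X):
        X = self._validate(X)
        if not hasattr(self, "mean_"):
            raise ValueError("standardizer is not fitted")
        if self.mode_ == "frequency":
            return (X - self.mean_[None, None, :]) / self.scale_[None, None, :]
        shape = X.shape
        flat = X.reshape(shape[0], -1)
        return ((flat - self.mean_) / self.scale_).reshape(shape)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected an (n_samples, sweeps, n_points) cube")
        return X

    def _more_tags(self):  # non-tabular input; skip sklearn's 2-D checks
        return {"X_types": ["3darray"]}


@dataclass(frozen=True)
class StandardizationStats:
    """Frozen per-feature mean/SD as fitted on a training partition."""

    mean: np.ndarray
    sd: np.ndarray
    mode: str


def standardize(train: DatasetContainer, *others: DatasetContainer,
                mode: str = "frequency"
                ) -> tuple[list[np.ndarray], StandardizationStats]:
    """Standardize container partitions with train-fit statistics.

    Returns ([train_cube, *other_cubes], stats); every cube is transformed
    with the statistics of `train` only.
    """
    scaler = BurstStandardizer(mode=mode).fit(train.data_cube())
    cubes = [scaler.transform(p.data_cube()) for p in (train, *others)]
    return cubes, StandardizationStats(scaler.mean_.copy(),
                                       scaler.scale_.copy(), scaler.mode_)


def class_balance_report(threshold: float = 0.35,
                         **partitions: DatasetContainer) -> dict:
    """Label counts, minority fraction and an imbalance flag per partition."""
    report = {}
    for name, part in partitions.items():
        labels = part.labels if isinstance(part, DatasetContainer) \
            else np.asarray(part)
        counts = {lab: int(np.sum(labels == lab)) for lab in LABELS}
        total = sum(counts.values())
        minority = min(counts.values()) / total if total else 0.0
        report[name] = {
            "counts": counts,
            "total": total,
            "minority_fraction": minority,
            "imbalanced": total == 0 or minority < threshold,
        }
    return report
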