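"""Raw-cycle filtering, feature extraction and z-score standardization.

An e-nose measurement is one *response cycle*: every gas sensor in the array
is sampled through a baseline phase (clean carrier gas), a sample phase
(headspace of the specimen) and a purge phase (system cleaning).  The
per-sample feature is the maximum of each sensor's (smoothed) response over
the cycle, giving one feature vector per specimen; feature matrices are then
column-wise z-scored within each domain before any subspace computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DataError,
    DegenerateFeatureError,
    InvalidParameterError,
    ShapeMismatchError,
)

#: (baseline, sample, purge) index ranges for the standard 14-minute cycle
#: sampled at 1 Hz: 3 min baseline, 3 min sample, 8 min purge = 840 points.
DEFAULT_PHASE_BOUNDS = ((0, 180), (180, 360), (360, 840))

PHASE_NAMES = ("baseline", "sample", "purge")


@dataclass
class ResponseCycle:
    """One specimen's raw multichannel sensor time series.

    Parameters
    ----------
    values : ndarray, shape (d, T)
        Sensor readings, one row per sensor, in raw response units.
    sampling_rate_hz : float
        Sampling frequency; the standard protocol samples at 1 Hz.
    phase_bounds : tuple of three (start, stop) pairs
        Contiguous, ordered index ranges of the baseline, sample and purge
        phases along the time axis; together they must tile ``[0, T)``.
    sensor_names : list of str, optional
        One identifier per sensor row.
    """

    values: np.ndarray
    sampling_rate_hz: float = 1.0
    phase_bounds: tuple = DEFAULT_PHASE_BOUNDS
    sensor_names: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeMismatchError("cycle values must be a (sensors, time) matrix")
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling_rate_hz must be positive")
        bounds = tuple((int(a), int(b)) for a, b in self.phase_bounds)
        if len(bounds) != 3:
            raise InvalidParameterError("phase_bounds needs baseline, sample and purge ranges")
        if bounds[0][0] != 0 or bounds[2][1] != self.values.shape[1]:
            raise InvalidParameterError("phases must tile the full cycle")
        for (a0, a1), (b0, b1) in zip(bounds[:-1], bounds[1:]):
            if a1 != b0:
                raise InvalidParameterError("phases must be contiguous and ordered")
        if any(b <= a for a, b in bounds):
            raise InvalidParameterError("every phase must be non-empty")
        self.phase_bounds = bounds
        if self.sensor_names is not None:
            if len(self.sensor_names) != self.values.shape[0]:
                raise ShapeMismatchError("one sensor name per sensor row required")
            self.sensor_names = list(self.sensor_names)

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def phase_slice(self, phase: str) -> slice:
        """Index slice of ``phase`` ('baseline', 'sample' or 'purge')."""
        a, b = self.phase_bounds[PHASE_NAMES.index(phase)]
        return slice(a, b)


@dataclass
class DomainDataset:
    """A feature matrix with optional labels and a domain tag.

    ``features`` is samples-in-rows (N, d).  ``labels`` are integer class ids;
    the target domain is typically unlabeled (or labeled for evaluation only).
    ``standardized`` asserts that every column is mean-0 / sd-1, which is
    checked at construction.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    domain_tag: str = "source"
    standardized: bool = False
    sensor_names: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ShapeMismatchError("features must be a (samples, sensors) matrix")
        if not np.all(np.isfinite(self.features)):
            raise DataError("features contain non-finite values")
        if self.domain_tag not in ("source", "target"):
            raise InvalidParameterError("domain_tag must be 'source' or 'target'")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.features.shape[0],):
                raise ShapeMismatchError("labels must have one entry per sample")
        if self.sensor_names is not None and len(self.sensor_names) != self.features.shape[1]:
            raise ShapeMismatchError("one sensor name per feature column required")
        if self.standardized:
            mu = self.features.mean(axis=0)
            sd = self.features.std(axis=0, ddof=1)
            if np.abs(mu).max() > 1e-9 or np.abs(sd - 1).max() > 1e-9:
                raise DataError("standardized flag set but columns are not mean-0/sd-1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def lowpass_filter(cycle: ResponseCycle, cutoff_hz: float = 0.1, order: int = 2) -> ResponseCycle:
    """Zero-phase Butterworth low-pass smoothing of a response cycle.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    response peaks, which carry the feature, are not delayed; the DC level is
    preserved.  The effective magnitude response is the square of the one-pass
    Butterworth response.

    Parameters
    ----------
    cutoff_hz : float
        Cut-off frequency; must lie strictly below the Nyquist frequency.
        The default 0.1 Hz suits the 1 Hz sampling of the standard protocol.
    order : int
        One-pass filter order (doubled by the forward-backward application).
    """
    nyquist = cycle.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise InvalidParameterError(
            f"cutoff_hz must be in (0, {nyquist}); got {cutoff_hz}"
        )
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not np.all(np.isfinite(cycle.values)):
        raise DataError("cycle contains non-finite values")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=cycle.sampling_rate_hz, output="sos")
    smoothed = signal.sosfiltfilt(sos, cycle.values, axis=1)
    return replace(cycle, values=smoothed)


def extract_features(cycle: ResponseCycle, baseline_correct: bool = False) -> np.ndarray:
    """Per-sensor maximum response over the full cycle.

    With ``baseline_correct`` the mean of the baseline phase is subtracted
    per sensor first, so the feature is the response *rise* rather than the
    absolute level.  Default is the plain maximum.
    """
    values = cycle.values
    if baseline_correct:
        base = values[:, cycle.phase_slice("baseline")].mean(axis=1, keepdims=True)
        values = values - base
    return values.max(axis=1)


def zscore_standardize(
    dataset: DomainDataset, ddof: int = 1, per_sample: bool = False
) -> tuple[DomainDataset, np.ndarray, np.ndarray]:
    """Z-score a feature matrix; returns the dataset plus fitted statistics.

    Default is column-wise (per sensor across the dataset): each column is
    transformed to mean 0, standard deviation 1 using the ``ddof`` (sample,
    n−1 by default) convention.  ``per_sample=True`` instead normalizes each
    row — a variant occasionally used in subspace methods; note the
    ``standardized`` flag refers to the column-wise property and stays False
    in that mode.

    Returns
    -------
    (standardized dataset, means, stds) — means/stds are per column
    (or per row in ``per_sample`` mode) for reuse on new data.
    """
    X = dataset.features
    axis = 1 if per_sample else 0
    if X.shape[axis] < 2:
        raise InvalidParameterError("need at least 2 observations per statistic")
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, ddof=ddof, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        names = dataset.sensor_names
        ident = names[zero[0]] if (names and not per_sample) else int(zero[0])
        what = "sample row" if per_sample else "feature column"
        raise DegenerateFeatureError(f"zero-variance {what}: {ident}")
    Z = (X - mu) / sd
    out = DomainDataset(
        features=Z,
        labels=dataset.labels,
        domain_tag=dataset.domain_tag,
        standardized=not per_sample,
        sensor_names=dataset.sensor_names,
    )
    return out, mu.ravel(), sd.ravel()


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_cycle_csv(cycle: ResponseCycle, path) -> None:
    """One row per time point, one column per sensor (header = names)."""
    names = cycle.sensor_names or [f"S{i:02d}" for i in range(cycle.n_sensors)]
    pd.DataFrame(cycle.values.T, columns=names).to_csv(path, index=False)


def read_cycle_csv(path, sampling_rate_hz: float = 1.0, phase_bounds=DEFAULT_PHASE_BOUNDS) -> ResponseCycle:
    df = pd.read_csv(path)
    return ResponseCycle(
        values=df.to_numpy().T,
        sampling_rate_hz=sampling_rate_hz,
        phase_bounds=phase_bounds,
        sensor_names=list(df.columns),
    )


def write_features_csv(dataset: DomainDataset, path) -> None:
    """Header = sensor names (plus a final 'label' column when labeled)."""
    names = dataset.sensor_names or [f"S{i:02d}" for i in range(dataset.n_features)]
    df = pd.DataFrame(dataset.features, columns=names)
    if dataset.labels is not None:
        df["label"] = dataset.labels
    df.to_csv(path, index=False)


def read_features_csv(path, domain_tag: str = "source") -> DomainDataset:
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return DomainDataset(
        features=df.to_numpy(),
        labels=labels,
        domain_tag=domain_tag,
        sensor_names=list(df.columns),
    )
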