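"""Intra-subject harmonization of grey-matter maps and ROI time series.

Multi-site MRI brings scanner- and protocol-dependent intensity scales.  The
second harmonization step applied here rescales each subject's grey-matter
(GM) segmentation to the [0, 1] range with per-subject min-max scaling, and
normalises resting-state ROI time series with a band-pass filter
(0.01-0.1 Hz), truncation to a common length of 120 volumes, and per-ROI
z-scoring.  Upstream steps (segmentation, spatial normalisation, confound
regression) are assumed done and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GMImageSet",
    "ROITimeSeries",
    "SubjectMinMaxScaler",
    "TimeSeriesPreprocessor",
    "minmax_scale_subject",
    "whole_brain_mean_volume",
    "bandpass_filter",
    "preprocess_timeseries",
]

N_VOLUMES_DEFAULT = 120
BAND_DEFAULT = (0.01, 0.1)


@dataclass
class GMImageSet:
    """Masked per-subject grey-matter volume arrays on a common grid.

    ``data`` is subjects x voxels (masked, flattened in C order over the
    voxels where ``mask`` is True); ``tiv`` is total intracranial volume in
    mm^3, carried as a covariate rather than divided out.
    """

    data: np.ndarray
    mask: np.ndarray
    tiv: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.tiv = np.asarray(self.tiv, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("GM data must be subjects x voxels")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("mask voxel count does not match data columns")
        if self.tiv.shape[0] != self.data.shape[0]:
            raise ValueError("tiv length does not match subject count")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class ROITimeSeries:
    """One subject's ROI x T array after preprocessing."""

    data: np.ndarray
    sampling_interval: float
    condition: int = 0  # 0 = eyes closed, 1 = eyes open


class SubjectMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-subject min-max scaling of masked GM values to [0, 1].

    Stateless transformer (fit is a no-op): each row (subject) is mapped by
    ``(x - min) / (max - min)`` over its masked voxels, so min 0 and max 1
    are attained for every subject.  A constant map cannot be scaled and is
    rejected as a degenerate segmentation.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim not in (1, 2):
            raise ValueError("expected subjects x voxels array (or one subject)")
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[None, :]
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        if np.any(span <= 0):
            bad = np.nonzero(span.ravel() <= 0)[0].tolist()
            raise ValueError(f"degenerate segmentation (constant map) for subjects {bad}")
        out = (X - lo) / span
        return out[0] if one_d else out


def minmax_scale_subject(gm_values: np.ndarray) -> np.ndarray:
    """Min-max scale one subject's masked GM values (or a stack of them)."""
    return SubjectMinMaxScaler().fit_transform(np.asarray(gm_values, dtype=float))


def whole_brain_mean_volume(gm: GMImageSet | np.ndarray) -> np.ndarray:
    """Arithmetic mean of GM volume over masked voxels, one scalar per subject."""
    data = gm.data if isinstance(gm, GMImageSet) else np.asarray(gm, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] == 0:
        raise ValueError("empty mask: no voxels to average")
    return data.mean(axis=1)


def bandpass_filter(
    ts: np.ndarray,
    sampling_interval: float,
    band: tuple[float, float] = BAND_DEFAULT,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (last axis).

    A second-order Butterworth applied forward-backward (sosfiltfilt) keeps
    the filter zero-phase so no lag structure is induced into functional
    connectivity.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling interval must be positive")
    fs = 1.0 / sampling_interval
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid for sampling rate {fs} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


class TimeSeriesPreprocessor(BaseEstimator, TransformerMixin):
    """Band-pass, truncate to 120 volumes, z-score each ROI row.

    Parameters
    ----------
    sampling_interval : float
        TR in seconds.
    band : (float, float)
        Pass band in Hz, default 0.01-0.1.
    n_volumes : int
        Common length after truncation; the first ``n_volumes`` post-filter
        volumes are kept.  Subjects with fewer volumes are rejected rather
        than padded.
    """

    def __init__(
        self,
        sampling_interval: float = 2.0,
        band: tuple[float, float] = BAND_DEFAULT,
        n_volumes: int = N_VOLUMES_DEFAULT,
        filter_order: int = 2,
    ):
        self.sampling_interval = sampling_interval
        self.band = band
        self.n_volumes = n_volumes
        self.filter_order = filter_order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        ts = np.asarray(X, dtype=float)
        if ts.ndim != 2:
            raise ValueError("expected ROI x T array")
        n_roi, t = ts.shape
        if t < self.n_volumes:
            raise ValueError(
                f"insufficient volumes: {t} < required {self.n_volumes}"
            )
        raw_sd = ts.std(axis=1, ddof=0)
        if np.any(raw_sd == 0):
            bad = np.nonzero(raw_sd == 0)[0].tolist()
            raise ValueError(f"constant ROI rows: {bad}")
        filt = bandpass_filter(
            ts, self.sampling_interval, self.band, order=self.filter_order
        )
        filt = filt[:, : self.n_volumes]
        sd = filt.std(axis=1, ddof=0)
        if np.any(sd <= 1e-300):
            bad = np.nonzero(sd <= 1e-300)[0].tolist()
            raise ValueError(f"constant ROI rows after filtering: {bad}")
        return (filt - filt.mean(axis=1, keepdims=True)) / sd[:, None]


def preprocess_timeseries(
    raw: np.ndarray,
    sampling_interval: float,
    condition: int = 0,
    band: tuple[float, float] = BAND_DEFAULT,
    n_volumes: int = N_VOLUMES_DEFAULT,
) -> ROITimeSeries:
    """Run the full time-series normalisation chain for one subject."""
    pre = TimeSeriesPreprocessor(
        sampling_interval=sampling_interval, band=band, n_volumes=n_volumes
    )
    return ROITimeSeries(
        data=pre.fit_transform(raw),
        sampling_interval=sampling_interval,
        condition=condition,
    )
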