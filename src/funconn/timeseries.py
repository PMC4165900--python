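"""Core data containers: ROI time series and rigid-body motion parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's region-averaged signal matrix.

    Parameters
    ----------
    values : (T, N) ndarray
        T timepoints by N regions; no missing values.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    region_names : tuple of str
        Unique labels, one per column.
    subject_id : str
        Subject identifier carried through the pipeline.
    """

    values: np.ndarray
    tr_seconds: float
    region_names: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(v).all():
            raise ValueError("values contain non-finite entries")
        names = tuple(self.region_names)
        if len(names) != v.shape[1]:
            raise ValueError("region_names length must match column count")
        if len(set(names)) != len(names):
            raise ValueError("region_names must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_names", names)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "RoiTimeSeries":
        """New series with the same metadata and different values."""
        return RoiTimeSeries(
            values=values,
            tr_seconds=self.tr_seconds,
            region_names=self.region_names,
            subject_id=self.subject_id,
        )


@dataclass(frozen=True)
class MotionParams:
    """T x 6 rigid-body realignment parameters.

    Columns 0-2 are translations in millimetres, columns 3-5 rotations in
    radians, matching the ordering written by standard realignment tools.
    """

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError("motion parameters must be a T x 6 matrix")
        if not np.isfinite(v).all():
            raise ValueError("motion parameters contain non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FdSeries:
    """Per-frame framewise displacement in mm; the first frame is defined 0."""

    values: np.ndarray
    threshold_mm: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("FD must be one-dimensional")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("FD values must be finite and nonnegative")
        if v[0] != 0:
            raise ValueError("FD of the first frame is defined to be 0")
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")
        object.__setattr__(self, "values", v)
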