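"""ROI-level signal cleaning: motion censoring, confound regression, filtering.

The cleaning pipeline mirrors common resting-state practice at the
region-averaged level: frames with excessive head motion are censored
(framewise displacement above a threshold), nuisance variance is removed by
least-squares regression (including the 24-parameter motion expansion:
6 parameters, their one-frame lags, and both sets squared), and the series
is band-pass filtered to the low-frequency band where resting-state
fluctuations live. Stage order is censor -> confound regression -> band-pass.
"""

from __future__ import annotations

import logging

import numpy as np

from .timeseries import FdSeries, MotionParams, RoiTimeSeries

__all__ = [
    "InsufficientDataError",
    "compute_fd",
    "censor_volumes",
    "friston24",
    "regress_confounds",
    "bandpass",
    "clean",
]

log = logging.getLogger(__name__)


class InsufficientDataError(RuntimeError):
    """Raised when motion censoring leaves too few usable frames."""


def compute_fd(motion: MotionParams, sphere_radius_mm: float = 50.0,
               threshold_mm: float = 0.5) -> FdSeries:
    """Scalar framewise displacement from rigid-body parameters.

    FD(t) = sum |delta translation| + radius * sum |delta rotation|, the
    rotational displacements being converted to mm on a sphere of the given
    radius (default 50 mm). FD of the first frame is 0 by convention.
    """
    if motion.n_timepoints < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(motion.values, axis=0))
    fd = np.concatenate(([0.0], d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)))
    return FdSeries(values=fd, threshold_mm=threshold_mm)


def censor_volumes(
    ts: RoiTimeSeries, fd: FdSeries, min_frames: int = 100
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Remove frames whose FD exceeds the threshold; order preserved.

    Returns the censored series and the (0-based) indices of kept frames.
    Raises :class:`InsufficientDataError` if fewer than ``min_frames``
    survive.
    """
    if fd.values.shape[0] != ts.n_timepoints:
        raise ValueError("FD length must match the time series")
    kept = np.flatnonzero(fd.values <= fd.threshold_mm)
    if kept.size < min_frames:
        raise InsufficientDataError(
            f"only {kept.size} frames below FD {fd.threshold_mm} mm "
            f"(minimum {min_frames})"
        )
    return ts.replace_values(ts.values[kept]), kept


def friston24(motion: MotionParams) -> np.ndarray:
    """24-parameter motion expansion: [R, R(t-1), R^2, R(t-1)^2].

    The lagged block is zero-padded at the first frame. Always returns T x 24.
    """
    if motion.n_timepoints < 2:
        raise ValueError("need at least 2 frames")
    r = motion.values
    lag = np.vstack((np.zeros((1, 6)), r[:-1]))
    return np.hstack((r, lag, r**2, lag**2))


def regress_confounds(ts: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Replace each region's series by its residual against the confounds.

    An intercept column is always included, so the output is mean-centred.
    Collinear confound columns are dropped with a logged warning rather than
    raising; the least-squares fit is then full-rank.
    """
    c = np.asarray(confounds, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != ts.n_timepoints:
        raise ValueError("confounds must be T x K with matching T")
    if c.shape[1] >= ts.n_timepoints:
        raise ValueError("more confounds than timepoints")
    design = np.hstack((np.ones((ts.n_timepoints, 1)), c))
    # drop collinear columns by greedy QR-style rank check
    q = np.linalg.qr(design, mode="r")
    keep = np.abs(np.diag(q)) > 1e-10 * max(1.0, np.abs(np.diag(q)).max())
    if keep.size < design.shape[1]:  # qr returns min(T, K) diag entries
        keep = np.concatenate((keep, np.zeros(design.shape[1] - keep.size, bool)))
    if not keep.all():
        log.warning("dropping %d collinear confound column(s)", (~keep).sum())
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.replace_values(ts.values - design @ beta)


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Zero-phase ideal (Fourier-domain) band-pass filter.

    DFT coefficients whose frequency lies outside [low_hz, high_hz] are set
    to zero and the series is inverse-transformed. The band must lie below
    the Nyquist frequency 1/(2 TR).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 <= low < high < "
            f"Nyquist ({nyquist:g} Hz)"
        )
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(ts.values, axis=0)
    spec[~mask] = 0.0
    return ts.replace_values(np.fft.irfft(spec, n=t, axis=0))


def clean(
    ts: RoiTimeSeries,
    motion: MotionParams | None = None,
    confounds: np.ndarray | None = None,
    fd_threshold_mm: float = 0.5,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    min_frames: int = 100,
    do_censor: bool = True,
    do_bandpass: bool = True,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Full cleaning pipeline: censor -> confound regression -> band-pass.

    Motion parameters, when given, contribute both the FD censoring mask and
    the 24-parameter confound expansion; extra confound columns may be
    supplied and are censored along with the data. Returns the cleaned series
    and the kept-frame indices.
    """
    kept = np.arange(ts.n_timepoints)
    if motion is not None and do_censor:
        fd = compute_fd(motion, threshold_mm=fd_threshold_mm)
        ts, kept = censor_volumes(ts, fd, min_frames=min_frames)
    blocks = []
    if motion is not None:
        blocks.append(friston24(motion)[kept])
    if confounds is not None:
        blocks.append(np.asarray(confounds, dtype=np.float64)[kept])
    if blocks:
        ts = regress_confounds(ts, np.hstack(blocks))
    if do_bandpass:
        ts = bandpass(ts, low_hz=low_hz, high_hz=high_hz)
    return ts, kept
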