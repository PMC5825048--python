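"""Resampling and trimming of raw CoP recordings.

Consumer force platforms acquire the CoP at a variable native rate, so
recordings are first brought onto a uniform grid with SWARII (Sliding Window
Average with Relevance Interval Interpolation): each output sample is the
average of the raw samples falling in a window centred on the output time, and
windows that catch no raw sample are filled by linear interpolation between
the bracketing raw samples.  The first and last seconds of a recording, which
contain stepping-on/off transients, are then trimmed away.
"""

from __future__ import annotations

import numpy as np

from .cop_data import Cohort, RawTrajectory, Statokinesigram, SubjectRecord
from .exceptions import InsufficientDataError, ValidationError

DEFAULT_RATE_HZ = 25.0
DEFAULT_WINDOW_S = 1.0 / DEFAULT_RATE_HZ
DEFAULT_TRIM_S = 2.5


def _windowed_mean(times, values, grid, half_window):
    """Mean of ``values`` within [t - hw, t + hw] per grid point; NaN if empty."""
    lo = np.searchsorted(times, grid - half_window, side="left")
    hi = np.searchsorted(times, grid + half_window, side="right")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    counts = hi - lo
    with np.errstate(invalid="ignore"):
        means = (csum[hi] - csum[lo]) / counts
    empty = counts == 0
    if empty.any():
        means[empty] = np.interp(grid[empty], times, values)
    return means


def swarii_resample(
    raw: RawTrajectory,
    rate: float = DEFAULT_RATE_HZ,
    window: float = DEFAULT_WINDOW_S,
) -> Statokinesigram:
    """Resample an irregular recording onto a uniform grid at ``rate`` Hz.

    The output grid is ``t_k = t_0 + k/rate`` covering the raw time span
    (anchored at the first raw timestamp).  Each output value is the average
    of raw samples with timestamps in the closed window
    ``[t_k - window/2, t_k + window/2]``; an empty window falls back to linear
    interpolation between the nearest bracketing raw samples (nearest-sample
    value beyond the ends).
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if window <= 0:
        raise ValidationError("window must be positive")
    if raw.span < 1.0 / rate:
        raise InsufficientDataError(
            f"raw span {raw.span:.4f}s shorter than one output period {1.0 / rate:.4f}s"
        )
    n_out = int(np.floor(raw.span * rate + 1e-9)) + 1
    grid = raw.times[0] + np.arange(n_out) / rate
    half = window / 2.0
    x = _windowed_mean(raw.times, raw.x, grid, half)
    y = _windowed_mean(raw.times, raw.y, grid, half)
    return Statokinesigram(rate=rate, x=x, y=y, condition=raw.condition)


def trim(traj: Statokinesigram, trim_s: float = DEFAULT_TRIM_S) -> Statokinesigram:
    """Drop ``floor(trim_s * rate)`` samples from each end of a statokinesigram.

    At the default protocol (25 s at 25 Hz, trim 2.5 s) this retains the
    central 20 seconds.
    """
    if trim_s < 0:
        raise ValidationError("trim_s must be non-negative")
    if trim_s == 0:
        return Statokinesigram(
            rate=traj.rate, x=traj.x.copy(), y=traj.y.copy(), condition=traj.condition
        )
    if traj.duration <= 2 * trim_s:
        raise InsufficientDataError(
            f"duration {traj.duration:.3f}s too short to trim {trim_s}s at both ends"
        )
    k = int(np.floor(trim_s * traj.rate))
    return Statokinesigram(
        rate=traj.rate,
        x=traj.x[k : len(traj.x) - k],
        y=traj.y[k : len(traj.y) - k],
        condition=traj.condition,
    )


def preprocess(
    raw: RawTrajectory,
    rate: float = DEFAULT_RATE_HZ,
    window: float = DEFAULT_WINDOW_S,
    trim_s: float = DEFAULT_TRIM_S,
) -> Statokinesigram:
    """SWARII resampling followed by end trimming."""
    return trim(swarii_resample(raw, rate=rate, window=window), trim_s=trim_s)


def preprocess_cohort(
    cohort: Cohort,
    rate: float = DEFAULT_RATE_HZ,
    window: float = DEFAULT_WINDOW_S,
    trim_s: float = DEFAULT_TRIM_S,
) -> Cohort:
    """Apply :func:`preprocess` to every trajectory of every subject."""
    subjects = []
    for s in cohort:
        subjects.append(
            SubjectRecord(
                subject_id=s.subject_id,
                label=s.label,
                eo=None if s.eo is None else preprocess(s.eo, rate, window, trim_s),
                ec=None if s.ec is None else preprocess(s.ec, rate, window, trim_s),
            )
        )
    return Cohort(subjects)
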