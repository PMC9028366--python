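"""Raw 3-axis limb acceleration -> standardized 1-D magnitude series.

The fixed stage order is: cubic-spline interpolation of missing samples
(per axis), collapse to the acceleration magnitude, third-order median
smoothing, then z-scoring of each limb series. Each limb channel of the
output has mean 0 and unit sample standard deviation, so no limb's variance
dominates the joint recurrence analysis.

Edge conventions (deliberate, documented choices where the procedure is
underdetermined): leading/trailing missing samples are filled with the
nearest valid value rather than spline-extrapolated, and the 3-point median
filter uses a truncated window at the endpoints rather than zero padding
(zero padding would inject spurious zeros into magnitudes that hover
around gravity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .synthetic import LIMBS, RawSession


class DegenerateSeriesError(ValueError):
    """A channel cannot be standardized (zero variance)."""


@dataclass
class MultiSeries:
    """N x D matrix of preprocessed, z-scored limb magnitude series."""

    values: np.ndarray
    rate_hz: float
    channels: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    missing_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x channels)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel names must match column count")
        if np.isnan(self.values).any():
            raise ValueError("MultiSeries must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        """Tidy view for inspection: time in seconds + one column per limb."""
        import pandas as pd

        frame = pd.DataFrame(self.values, columns=list(self.channels))
        frame.insert(0, "t", np.arange(self.n_samples) / self.rate_hz)
        return frame


def fill_missing(values: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Replace missing samples by a cubic spline through the valid ones.

    Interior gaps are filled with a not-a-knot cubic spline evaluated at
    the integer sample indices; leading/trailing gaps take the nearest
    valid value. Non-missing samples pass through unchanged. Requires at
    least 4 valid samples (cubic support).
    """
    x = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.isnan(x)
    missing = np.asarray(missing, dtype=bool)
    if missing.shape != x.shape:
        raise ValueError("missing mask must match series shape")
    if not missing.any():
        return x.copy()
    valid = ~missing
    if valid.sum() < 4:
        raise ValueError("need at least 4 valid samples for cubic interpolation")
    idx = np.arange(x.size)
    out = x.copy()
    first, last = idx[valid][0], idx[valid][-1]
    interior = missing & (idx > first) & (idx < last)
    if interior.any():
        spline = CubicSpline(idx[valid], x[valid])
        out[interior] = spline(idx[interior])
    out[:first] = x[first]
    out[last + 1 :] = x[last]
    return out


def accel_magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of the three acceleration axes."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("axis arrays must have equal length")
    return np.sqrt(ax**2 + ay**2 + az**2)


def median_smooth(values: np.ndarray) -> np.ndarray:
    """Third-order median filter with truncated windows at the edges.

    Interior samples become the median of (prev, self, next); each endpoint
    becomes the median (= mean) of the two available samples. Removes
    one-point outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.size <= 1:
        return x.copy()
    out = x.copy()
    if x.size >= 3:
        windows = np.lib.stride_tricks.sliding_window_view(x, 3)
        out[1:-1] = np.median(windows, axis=1)
    out[0] = 0.5 * (x[0] + x[1])
    out[-1] = 0.5 * (x[-2] + x[-1])
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """z-score with sample (N-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateSeriesError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def preprocess_session(session: RawSession) -> MultiSeries:
    """Run the full per-limb pipeline in its fixed order.

    Per limb: fill_missing (each axis) -> accel_magnitude -> median_smooth
    -> standardize. The raw per-limb missing fraction is recorded but no
    exclusion is applied here (that is the pipeline's job).
    """
    columns = []
    for name in LIMBS:
        trace = session.limbs[name]
        axes = [fill_missing(trace.acc[:, i], trace.missing) for i in range(3)]
        magnitude = accel_magnitude(*axes)
        columns.append(standardize(median_smooth(magnitude)))
    return MultiSeries(
        values=np.column_stack(columns),
        rate_hz=session.rate_hz,
        channels=LIMBS,
        meta={
            "subject": session.subject_id,
            "visit": session.visit,
            "task": session.task,
        },
        missing_fraction=session.missing_fraction(),
    )
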