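"""Phase-space embedding and MdRQA hyperparameter estimation.

Three parameters govern the recurrence analysis of a D-channel series:

* the delay ``tau`` — first local minimum of the average mutual
  information (AMI) of each channel with its lagged copy, averaged over
  channels;
* the per-channel embedding dimension ``m`` — smallest dimension at which
  the false-nearest-neighbor (FNN) fraction, by the Kennel criteria,
  drops below a cutoff;
* the radius ``epsilon`` — calibrated by bisection so the recurrence rate
  hits a fixed target (5 % by default), making RR comparable across
  subjects at the anchor visit.

Parameters are estimated once per subject on the earliest available visit
and then held fixed for that subject's later visits, so longitudinal
changes in the measures reflect changes in the dynamics rather than in
the analysis configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .preprocessing import MultiSeries
from .rqa import RQAConfig, recurrence_rate
from .synthetic import VISITS

# Largest state count for which radius calibration pre-sorts the condensed
# distance vector; above this it re-scans distances per bisection step.
_DENSE_LIMIT = 6000


class CalibrationError(RuntimeError):
    """Radius calibration cannot reach the target recurrence rate."""


@dataclass
class EmbeddingParams:
    """Frozen MdRQA hyperparameters for one subject (and task)."""

    tau: int
    m: int
    epsilon: float
    target_rr: float = 5.0
    anchor_visit: str | None = None

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ValueError("tau and m must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.target_rr < 100.0:
            raise ValueError("target_rr must lie in (0, 100)")


@dataclass
class StateMatrix:
    """N' x (D m) matrix of delay-embedded joint states."""

    values: np.ndarray
    tau: int
    m: int
    channels: tuple[str, ...]
    meta: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 embedded states")
        if self.values.shape[1] != len(self.channels) * self.m:
            raise ValueError("column count must equal D * m")

    @property
    def n_states(self) -> int:
        return self.values.shape[0]


def _mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Plug-in MI from an equal-width 2-D histogram, in nats."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / outer[mask])).sum())


def ami_curve(ms: MultiSeries, max_lag: int, n_bins: int = 10) -> np.ndarray:
    """Channel-averaged AMI at lags 0..max_lag."""
    n = ms.n_samples
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    curve = np.zeros(max_lag + 1)
    for col in ms.values.T:
        for lag in range(max_lag + 1):
            y = col[lag:] if lag else col
            x = col[: n - lag] if lag else col
            curve[lag] += _mutual_information(x, y, n_bins)
    return curve / ms.n_channels


def ami_delay(ms: MultiSeries, max_lag: int = 30, n_bins: int = 10) -> int:
    """First local minimum of the channel-averaged AMI curve.

    A lag k is the chosen delay when the curve stops decreasing there
    (AMI(k) <= AMI(k+1)). If the curve decreases through the whole range,
    the argmin over 1..max_lag is returned with a warning.
    """
    curve = ami_curve(ms, max_lag, n_bins)
    for lag in range(1, max_lag):
        if curve[lag] <= curve[lag + 1]:
            return lag
    warnings.warn(
        "AMI has no local minimum within max_lag; returning the argmin",
        stacklevel=2,
    )
    return int(np.argmin(curve[1:]) + 1)


def embed_multidim(ms: MultiSeries, tau: int, m: int) -> StateMatrix:
    """Joint delay embedding: row t holds x_d(t + j tau) for all d, j < m."""
    if tau < 1 or m < 1:
        raise ValueError("tau and m must be >= 1")
    n = ms.n_samples
    n_embedded = n - (m - 1) * tau
    if n_embedded < 2:
        raise ValueError("series too short for this (m, tau)")
    blocks = [
        ms.values[j * tau : j * tau + n_embedded, d]
        for d in range(ms.n_channels)
        for j in range(m)
    ]
    return StateMatrix(
        values=np.column_stack(blocks),
        tau=tau,
        m=m,
        channels=ms.channels,
        meta=dict(ms.meta),
    )


def fnn_fractions(
    ms: MultiSeries,
    tau: int,
    max_dim: int = 12,
    rtol: float = 10.0,
    atol: float = 2.0,
    theiler: int = 1,
) -> np.ndarray:
    """False-nearest-neighbor fraction at each candidate dimension 1..max_dim.

    At dimension m, every joint state (D m coordinates) is paired with its
    nearest neighbor outside the Theiler window; the neighbor is false if
    adding the next delay coordinate stretches the pair by more than
    ``rtol`` times its distance (Kennel criterion 1) or beyond ``atol``
    times the attractor size (criterion 2).
    """
    n, d_chan = ms.n_samples, ms.n_channels
    attractor_size = float(ms.values.std())
    fractions = np.full(max_dim, np.nan)
    for m in range(1, max_dim + 1):
        n_use = n - m * tau
        if n_use < 10:
            raise ValueError("series too short for FNN at this max_dim")
        cols = [
            ms.values[j * tau : j * tau + n_use, d]
            for d in range(d_chan)
            for j in range(m)
        ]
        embedded = np.column_stack(cols)
        extra = ms.values[m * tau : m * tau + n_use, :]
        tree = cKDTree(embedded)
        k = min(n_use, 2 * theiler + 8)
        dist, idx = tree.query(embedded, k=k)
        rows = np.arange(n_use)
        neighbor = np.full(n_use, -1)
        neighbor_dist = np.zeros(n_use)
        for col in range(1, k):
            unset = neighbor < 0
            ok = unset & (np.abs(idx[:, col] - rows) > theiler)
            neighbor[ok] = idx[ok, col]
            neighbor_dist[ok] = dist[ok, col]
        unresolved = np.flatnonzero(neighbor < 0)
        for i in unresolved:  # rare: many co-located temporal neighbors
            d2 = np.einsum("ij,ij->i", embedded - embedded[i], embedded - embedded[i])
            d2[np.abs(rows - i) <= theiler] = np.inf
            neighbor[i] = int(np.argmin(d2))
            neighbor_dist[i] = float(np.sqrt(d2[neighbor[i]]))
        delta = np.linalg.norm(extra - extra[neighbor], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(neighbor_dist > 0, delta / neighbor_dist, np.inf)
        ratio[(neighbor_dist == 0) & (delta == 0)] = 0.0
        grown = np.sqrt(neighbor_dist**2 + delta**2)
        false = (ratio > rtol) | (grown / attractor_size > atol)
        fractions[m - 1] = float(false.mean())
    return fractions


def fnn_dimension(
    ms: MultiSeries,
    tau: int,
    max_dim: int = 12,
    rtol: float = 10.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.10,
    theiler: int = 1,
) -> int:
    """Smallest dimension with FNN fraction below ``fnn_threshold``.

    Returns ``max_dim`` with a warning when no candidate dimension gets
    below the cutoff (e.g., for noise-dominated series).
    """
    fractions = fnn_fractions(ms, tau, max_dim, rtol, atol, theiler)
    below = np.flatnonzero(fractions < fnn_threshold)
    if below.size:
        return int(below[0] + 1)
    warnings.warn(
        "FNN fraction never fell below the threshold; returning max_dim",
        stacklevel=2,
    )
    return max_dim


def _theiler_mask_offsets(n: int, theiler: int) -> np.ndarray:
    """|i - j| for each entry of a condensed (i < j) distance vector."""
    out = np.empty(n * (n - 1) // 2, dtype=np.int32)
    pos = 0
    for i in range(n - 1):
        out[pos : pos + n - 1 - i] = np.arange(1, n - i)
        pos += n - 1 - i
    return out


def calibrate_radius(
    states: StateMatrix | np.ndarray,
    target_rr: float = 5.0,
    tol: float = 0.1,
    max_iter: int = 60,
    config: RQAConfig = RQAConfig(),
) -> float:
    """Bisection on epsilon until the recurrence rate hits ``target_rr``.

    RR is monotone non-decreasing in epsilon, so bisection between 0 and
    the maximum pairwise distance converges; iteration stops when RR is
    within ``tol`` percentage points of the target or after ``max_iter``
    steps (the best epsilon seen is returned). Raises CalibrationError for
    degenerate state sets whose RR exceeds the target at any radius.
    """
    if not 0.0 < target_rr < 100.0:
        raise ValueError("target_rr must lie in (0, 100)")
    values = states.values if isinstance(states, StateMatrix) else np.asarray(states)
    n = values.shape[0]

    if n <= _DENSE_LIMIT:
        distances = pdist(values)
        if config.theiler > 1:
            distances = distances[_theiler_mask_offsets(n, config.theiler) >= config.theiler]
        distances = np.sort(distances)
        if distances.size == 0 or distances[-1] == 0.0:
            raise CalibrationError("degenerate states: all pairwise distances zero")
        # condensed pairs count each off-diagonal cell once; the main
        # diagonal (n always-recurrent cells) enters only when theiler == 0
        diag = n if config.theiler == 0 else 0

        def rr_at(eps: float) -> float:
            hits = np.searchsorted(distances, eps, side="right")
            return 100.0 * (2 * hits + diag) / (2 * distances.size + diag)

        hi = float(distances[-1])
    else:  # streaming path for long sessions
        span = values.max(axis=0) - values.min(axis=0)
        hi = float(np.linalg.norm(span))
        if hi == 0.0:
            raise CalibrationError("degenerate states: all pairwise distances zero")

        def rr_at(eps: float) -> float:
            return recurrence_rate(values, eps, config)

    baseline = rr_at(np.nextafter(0.0, 1.0))
    if baseline > target_rr + tol:
        raise CalibrationError(
            f"duplicate-state baseline RR {baseline:.2f}% already exceeds target"
        )
    lo = 0.0
    best_eps, best_gap = hi, abs(100.0 - target_rr)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rr = rr_at(mid)
        gap = abs(rr - target_rr)
        if gap < best_gap:
            best_eps, best_gap = mid, gap
        if gap <= tol:
            return mid
        if rr < target_rr:
            lo = mid
        else:
            hi = mid
    return best_eps


def fix_params_per_subject(
    series: list[MultiSeries],
    *,
    tau: int | None = 1,
    m: int | None = 14,
    estimate: bool = False,
    target_rr: float = 5.0,
    config: RQAConfig = RQAConfig(),
    per_task: bool = True,
    max_lag: int = 30,
    max_dim: int = 12,
) -> dict[tuple[str, str], EmbeddingParams]:
    """Anchor (tau, m, epsilon) on each subject's earliest available visit.

    With ``estimate=False`` the preset (tau, m) is used (the recommended
    operating point for these signals: delay 1, dimension 14) and only the
    radius is calibrated per subject; with ``estimate=True`` tau and m are
    estimated from the anchor series via AMI and FNN. Keys are
    (subject, task); with ``per_task=False`` a single parameter set,
    anchored on the subject's earliest session regardless of task, is
    shared by both tasks.
    """
    if not series:
        raise ValueError("no sessions supplied")
    order = {v: i for i, v in enumerate(VISITS)}
    anchors: dict[tuple[str, str], MultiSeries] = {}
    keys_seen: list[tuple[str, str]] = []
    for ms in series:
        key = (ms.meta["subject"], ms.meta["task"] if per_task else "*")
        if key not in anchors or order[ms.meta["visit"]] < order[anchors[key].meta["visit"]]:
            anchors[key] = ms
        if key not in keys_seen:
            keys_seen.append(key)

    params: dict[tuple[str, str], EmbeddingParams] = {}
    for key in keys_seen:
        anchor = anchors[key]
        t = ami_delay(anchor, max_lag=max_lag) if estimate else int(tau)
        mm = fnn_dimension(anchor, t, max_dim=max_dim) if estimate else int(m)
        states = embed_multidim(anchor, t, mm)
        eps = calibrate_radius(states, target_rr=target_rr, config=config)
        params[key] = EmbeddingParams(
            tau=t, m=mm, epsilon=eps, target_rr=target_rr,
            anchor_visit=anchor.meta["visit"],
        )
    if not per_task:
        params = {
            (subject, task): p
            for (subject, _), p in params.items()
            for task in ("rattle", "freeplay")
        }
    return params


def params_to_frame(params: dict[tuple[str, str], EmbeddingParams]) -> pd.DataFrame:
    """Flatten a per-subject parameter map for persistence as CSV."""
    rows = [
        {
            "subject": subject,
            "task": task,
            "anchor_visit": p.anchor_visit,
            "tau": p.tau,
            "m": p.m,
            "epsilon": p.epsilon,
            "target_rr": p.target_rr,
        }
        for (subject, task), p in params.items()
    ]
    return pd.DataFrame(rows)


def params_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], EmbeddingParams]:
    return {
        (row.subject, row.task): EmbeddingParams(
            tau=int(row.tau),
            m=int(row.m),
            epsilon=float(row.epsilon),
            target_rr=float(row.target_rr),
            anchor_visit=row.anchor_visit,
        )
        for row in frame.itertuples()
    }
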