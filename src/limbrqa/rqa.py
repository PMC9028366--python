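"""Recurrence plots and the three MdRQA measures: RR, Ent, ML.

A recurrence plot marks pairs of embedded states whose Euclidean distance
falls below a radius epsilon. From the distribution P(L) of maximal
diagonal line lengths L >= lmin (excluding diagonals inside the Theiler
window around the main diagonal) this module derives:

* Recurrence Rate  RR  = 100 x recurrent cells / counted cells (percent),
* Entropy          Ent = Shannon entropy of {P(L)} (nats by default),
* Mean Line        ML  = sum(L P(L)) / sum(P(L)) (samples).

Two equivalent computation paths exist: an explicit boolean-matrix path
(small inputs, tests, plotting) and a streaming per-diagonal path that
never materializes the N' x N' plot (used everywhere else). They agree
exactly and the test suite asserts it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import _kernels


@dataclass(frozen=True)
class RQAConfig:
    """Conventions of the recurrence computation.

    ``theiler`` is the half-width of the main-diagonal exclusion band:
    cells with |i - j| >= theiler are counted, so the default 1 excludes
    exactly the main diagonal and 0 includes it. ``lmin`` is the minimum
    diagonal line length entering the histogram. ``log_base`` selects the
    entropy units ("e" -> nats, "2" -> bits).
    """

    lmin: int = 2
    theiler: int = 1
    norm: str = "euclidean"
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.norm != "euclidean":
            raise ValueError("only the Euclidean norm is supported")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


@dataclass
class RecurrencePlot:
    """Explicit boolean recurrence matrix (kept for small inputs only)."""

    matrix: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("recurrence matrix must be square")
        self.matrix = m

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RQAMeasures:
    """The three reported measures plus the configuration they came from."""

    rr: float
    ent: float
    ml: float
    n_lines: int
    epsilon: float
    lmin: int
    theiler: int


def recurrence_matrix(
    states: np.ndarray, epsilon: float, config: RQAConfig = RQAConfig()
) -> RecurrencePlot:
    """Threshold the full pairwise-distance matrix at ``epsilon``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = np.asarray(states, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("states must be a non-empty 2-D array")
    d2 = cdist(values, values, metric="sqeuclidean")
    return RecurrencePlot(d2 <= epsilon * epsilon, float(epsilon))


def _runs(line: np.ndarray, lmin: int) -> list[int]:
    """Lengths (>= lmin) of maximal runs of True in a 1-D boolean array."""
    padded = np.concatenate(([False], line, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    lengths = edges[1::2] - edges[0::2]
    return [int(l) for l in lengths if l >= lmin]


def diagonal_histogram(
    rp: RecurrencePlot, config: RQAConfig = RQAConfig()
) -> dict[int, int]:
    """Histogram of maximal diagonal line lengths outside the Theiler band."""
    hist: dict[int, int] = {}
    n = rp.n_states
    offsets = range(config.theiler, n) if config.theiler > 0 else range(0, n)
    for k in offsets:
        diagonals = [np.diagonal(rp.matrix, k)]
        if k > 0:
            diagonals.append(np.diagonal(rp.matrix, -k))
        for diag in diagonals:
            for length in _runs(diag, config.lmin):
                hist[length] = hist.get(length, 0) + 1
    return hist


def _measures_from_hist(
    hist: dict[int, int],
    recurrent: int,
    cells: int,
    epsilon: float,
    config: RQAConfig,
) -> RQAMeasures:
    total = sum(hist.values())
    if total == 0:
        ent = 0.0
        ml = 0.0
    else:
        # canonical length order so both computation paths sum identically
        lengths = np.array(sorted(hist), dtype=float)
        counts = np.array([hist[int(l)] for l in lengths], dtype=float)
        p = counts / total
        ent = float(-(p * np.log(p)).sum())
        if config.log_base == "2":
            ent /= math.log(2.0)
        ml = float((lengths * counts).sum() / total)
    rr = 100.0 * recurrent / cells if cells else 0.0
    return RQAMeasures(
        rr=rr,
        ent=ent,
        ml=ml,
        n_lines=int(total),
        epsilon=float(epsilon),
        lmin=config.lmin,
        theiler=config.theiler,
    )


def compute_measures(
    rp: RecurrencePlot, config: RQAConfig = RQAConfig()
) -> RQAMeasures:
    """RR / Ent / ML from an explicit recurrence matrix."""
    n = rp.n_states
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    counted = offsets >= config.theiler
    recurrent = int(rp.matrix[counted].sum())
    cells = int(counted.sum())
    hist = diagonal_histogram(rp, config)
    return _measures_from_hist(hist, recurrent, cells, rp.epsilon, config)


def measures_from_states(
    states: np.ndarray, epsilon: float, config: RQAConfig = RQAConfig()
) -> RQAMeasures:
    """RR / Ent / ML by the streaming per-diagonal pass (O(N') memory)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = np.ascontiguousarray(states, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("states must be a non-empty 2-D array")
    recurrent, cells, hist_arr = _kernels.diag_scan(
        values, float(epsilon) ** 2, config.theiler, config.lmin
    )
    hist = {int(l): int(c) for l, c in enumerate(hist_arr) if c > 0}
    return _measures_from_hist(hist, int(recurrent), int(cells), epsilon, config)


def recurrence_rate(
    states: np.ndarray, epsilon: float, config: RQAConfig = RQAConfig()
) -> float:
    """Percent of counted cells that are recurrent at radius ``epsilon``."""
    values = np.ascontiguousarray(states, dtype=float)
    recurrent, cells = _kernels.recurrence_count(
        values, float(epsilon) ** 2, config.theiler
    )
    return 100.0 * recurrent / cells if cells else 0.0
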