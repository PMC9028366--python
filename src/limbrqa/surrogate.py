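"""Shuffled-surrogate control analysis.

Randomly permuting each limb series destroys its temporal structure while
preserving the distribution of values, so recurrence measures computed on
shuffled data provide a null against which the observed measures are
compared with paired t-tests (one pair per session, grouped by visit).
Surrogates reuse the same per-subject embedding parameters as the observed
data: the control targets temporal structure only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import MultiSeries


@dataclass
class SurrogateResult:
    """Paired t-test of observed vs shuffled values of one measure."""

    measure: str
    t: float
    df: int
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.df != self.n - 1 or self.df < 1:
            raise ValueError("df must equal n - 1 and be >= 1")


def shuffle_channels(ms: MultiSeries, seed: int) -> MultiSeries:
    """Independently permute each channel's values uniformly at random.

    The multiset of values per channel is exactly preserved; deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.column_stack(
        [col[rng.permutation(ms.n_samples)] for col in ms.values.T]
    )
    meta = dict(ms.meta)
    meta["shuffled"] = True
    return MultiSeries(
        values=shuffled,
        rate_hz=ms.rate_hz,
        channels=ms.channels,
        meta=meta,
        missing_fraction=dict(ms.missing_fraction),
    )


def surrogate_test(
    observed: np.ndarray, shuffled: np.ndarray, measure: str = ""
) -> SurrogateResult:
    """Two-sided paired t-test on observed - shuffled differences.

    Degenerate cases: identical vectors give t = 0, p = 1; zero-variance
    differences with a nonzero mean give an infinite t and p = 0 (the
    difference is deterministic at this sample size).
    """
    obs = np.asarray(observed, dtype=float)
    shuf = np.asarray(shuffled, dtype=float)
    if obs.shape != shuf.shape or obs.ndim != 1:
        raise ValueError("observed and shuffled must be equal-length 1-D vectors")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 paired sessions")
    diff = obs - shuf
    mean = diff.mean()
    sd = diff.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return SurrogateResult(measure, 0.0, df, 1.0, n)
        return SurrogateResult(measure, math.copysign(math.inf, mean), df, 0.0, n)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return SurrogateResult(measure, float(t), df, float(p), n)


def control_table(
    observed: pd.DataFrame,
    shuffled: pd.DataFrame,
    measures: tuple[str, ...] = ("ent", "rr", "ml"),
) -> pd.DataFrame:
    """Per-visit paired t-tests for each measure (control-results table).

    Both frames must hold one row per session with columns
    (subject, visit, task) + the measure columns; rows are paired on
    (subject, visit, task).
    """
    keys = ["subject", "visit", "task"]
    merged = observed.merge(shuffled, on=keys, suffixes=("_obs", "_shuf"))
    if len(merged) != len(observed):
        raise ValueError("observed and shuffled tables do not pair one-to-one")
    rows = []
    for visit, group in merged.groupby("visit", sort=True):
        if len(group) < 2:
            continue
        for measure in measures:
            res = surrogate_test(
                group[f"{measure}_obs"].to_numpy(),
                group[f"{measure}_shuf"].to_numpy(),
                measure=measure,
            )
            rows.append(
                {
                    "visit": visit,
                    "measure": measure,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
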