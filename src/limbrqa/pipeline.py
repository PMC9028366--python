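"""End-to-end orchestration: simulate -> preprocess -> embed -> MdRQA ->
surrogate -> stats, with all file I/O, the exclusion rule, and logging.

Sessions travel as tidy CSV (columns subject, visit, task, limb, t, ax,
ay, az; empty acceleration cells mark missing samples). Sessions whose
worst limb channel exceeds the missing-data threshold (15 % by default)
are excluded before analysis. Every stage is deterministic under the
configured seeds and each run writes four artifacts into ``out_dir``:
measures.csv, control.csv, params.csv and stats.json (plus stats.txt).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import embedding as emb
from . import longitudinal as stats_mod
from . import surrogate as surr
from .preprocessing import MultiSeries, preprocess_session
from .rqa import RQAConfig, measures_from_states
from .synthetic import (
    LIMBS,
    TASKS,
    CohortDesign,
    LimbTrace,
    RawSession,
    generate_cohort,
)

log = logging.getLogger("limbrqa")

_SESSION_COLUMNS = ["subject", "visit", "task", "limb", "t", "ax", "ay", "az"]
MEASURES = ("ent", "rr", "ml")


def demo_design(seed: int = 0) -> CohortDesign:
    """Small default cohort (4 subjects, 2 visits, 50 s sessions at the
    desk-scale 12 Hz profile) so an out-of-the-box run finishes in
    seconds. Full-scale runs configure durations, rate and visit counts
    explicitly (see CohortDesign)."""
    from .synthetic import scaled_design

    return scaled_design(seed=seed, n_per_visit=(4, 4, 0, 0), n_subjects=4)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    out_dir: str = "limbrqa_out"
    seed: int = 0
    design: CohortDesign = field(default_factory=demo_design)
    rqa: RQAConfig = field(default_factory=RQAConfig)
    tau: int = 1
    m: int = 14
    estimate_embedding: bool = False
    target_rr: float = 5.0
    exclusion_threshold: float = 0.15
    input_sessions: str | None = None  # read CSV instead of simulating
    do_surrogate: bool = True
    do_stats: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_threshold <= 1.0:
            raise ValueError("exclusion_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design_fields = {f.name for f in dataclasses.fields(CohortDesign)}
        rqa_fields = {f.name for f in dataclasses.fields(RQAConfig)}
        top_fields = {f.name for f in dataclasses.fields(cls)} - {"design", "rqa"}
        design_kw, rqa_kw, top_kw = {}, {}, {}
        for key, value in raw.items():
            if key in top_fields:
                top_kw[key] = value
            elif key in design_fields:
                design_kw[key] = value
            elif key in rqa_fields:
                rqa_kw[key] = value
            else:
                raise ValueError(f"unknown config key: {key}")
        if "n_per_visit" in design_kw:
            design_kw["n_per_visit"] = tuple(design_kw["n_per_visit"])
        return cls(
            design=CohortDesign(**design_kw), rqa=RQAConfig(**rqa_kw), **top_kw
        )


def write_sessions(sessions: list[RawSession], path: str | Path) -> None:
    """Write sessions as one long tidy CSV; missing samples become empty cells."""
    frames = []
    for s in sessions:
        t = np.arange(s.n_samples) / s.rate_hz
        for limb in LIMBS:
            trace = s.limbs[limb]
            frames.append(
                pd.DataFrame(
                    {
                        "subject": s.subject_id,
                        "visit": s.visit,
                        "task": s.task,
                        "limb": limb,
                        "t": t,
                        "ax": trace.acc[:, 0],
                        "ay": trace.acc[:, 1],
                        "az": trace.acc[:, 2],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sessions(path: str | Path) -> list[RawSession]:
    """Parse the tidy session CSV back into validated RawSession objects."""
    frame = pd.read_csv(path)
    missing_cols = [c for c in _SESSION_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"session file lacks required column(s): {missing_cols}")
    if frame.duplicated(subset=["subject", "visit", "task", "limb", "t"]).any():
        raise ValueError("duplicate (subject, visit, task, limb, t) rows")
    sessions = []
    for (subject, visit, task), group in frame.groupby(
        ["subject", "visit", "task"], sort=True
    ):
        limbs = {}
        rate = None
        for limb, sub in group.groupby("limb"):
            t = sub["t"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"non-monotone time for {subject}/{visit}/{task}/{limb}"
                )
            rate = round((len(t) - 1) / (t[-1] - t[0]), 6)
            acc = sub[["ax", "ay", "az"]].to_numpy(dtype=float)
            missing = np.isnan(acc).any(axis=1)
            acc[missing] = np.nan
            limbs[limb] = LimbTrace(acc, missing)
        sessions.append(RawSession(subject, visit, task, rate, limbs))
    return sessions


def apply_exclusions(
    sessions: list[RawSession], threshold: float = 0.15
) -> tuple[list[RawSession], list[tuple[RawSession, str]]]:
    """Drop sessions whose worst limb exceeds the missing-data threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    kept, excluded = [], []
    for s in sessions:
        worst = max(s.missing_fraction().values())
        if worst > threshold:
            excluded.append(
                (s, f"missing fraction {worst:.3f} exceeds {threshold:.2f}")
            )
        else:
            kept.append(s)
    return kept, excluded


def _session_key(ms: MultiSeries) -> dict:
    return {
        "subject": ms.meta["subject"],
        "visit": ms.meta["visit"],
        "task": ms.meta["task"],
    }


def compute_measure_table(
    series: list[MultiSeries],
    params: dict[tuple[str, str], emb.EmbeddingParams],
    config: RQAConfig,
) -> pd.DataFrame:
    """One MdRQA measures row per session, using the anchored parameters."""
    rows = []
    for ms in series:
        p = params[(ms.meta["subject"], ms.meta["task"])]
        states = emb.embed_multidim(ms, p.tau, p.m)
        meas = measures_from_states(states.values, p.epsilon, config)
        rows.append(
            _session_key(ms)
            | {
                "ent": meas.ent,
                "rr": meas.rr,
                "ml": meas.ml,
                "n_lines": meas.n_lines,
                "epsilon": p.epsilon,
                "tau": p.tau,
                "m": p.m,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    measures: pd.DataFrame
    control: pd.DataFrame | None
    params: pd.DataFrame
    stats: dict | None
    excluded: list[tuple[RawSession, str]]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in order and write all outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_sessions:
        sessions = read_sessions(config.input_sessions)
        log.info("stage=read sessions=%d", len(sessions))
    else:
        design = dataclasses.replace(config.design, seed=config.seed)
        sessions = generate_cohort(design)
        log.info("stage=simulate sessions=%d", len(sessions))

    kept, excluded = apply_exclusions(sessions, config.exclusion_threshold)
    log.info("stage=exclude kept=%d excluded=%d", len(kept), len(excluded))
    for s, reason in excluded:
        log.info("excluded %s/%s/%s: %s", s.subject_id, s.visit, s.task, reason)
    if not kept:
        raise RuntimeError("all sessions excluded; nothing to analyze")

    series = [preprocess_session(s) for s in kept]
    log.info("stage=preprocess sessions=%d", len(series))

    params = emb.fix_params_per_subject(
        series,
        tau=config.tau,
        m=config.m,
        estimate=config.estimate_embedding,
        target_rr=config.target_rr,
        config=config.rqa,
    )
    params_frame = emb.params_to_frame(params)
    params_frame.to_csv(out_dir / "params.csv", index=False)
    log.info("stage=embedding subjects=%d", params_frame["subject"].nunique())

    measures = compute_measure_table(series, params, config.rqa)
    measures.to_csv(out_dir / "measures.csv", index=False)
    log.info("stage=mdrqa rows=%d", len(measures))

    control = None
    if config.do_surrogate:
        rng = np.random.default_rng(config.seed + 1)
        shuffled = [
            surr.shuffle_channels(ms, int(rng.integers(0, 2**31 - 1)))
            for ms in series
        ]
        shuffled_measures = compute_measure_table(shuffled, params, config.rqa)
        control = surr.control_table(measures, shuffled_measures, MEASURES)
        control.to_csv(out_dir / "control.csv", index=False)
        log.info("stage=surrogate rows=%d", len(control))

    stats_bundle = None
    if config.do_stats:
        fits = {name: stats_mod.fit_gee(measures, name) for name in MEASURES}
        stats_bundle = {}
        for name, fit in fits.items():
            contrasts = stats_mod.bonferroni_pairwise(fit)
            stats_bundle[name] = {
                "wald": {
                    term: {"chi2": chi2, "df": df, "p": p}
                    for term, (chi2, df, p) in fit.wald.items()
                },
                "cell_means": fit.cell_means.astype(
                    {"task": str, "visit": str}
                ).to_dict(orient="records"),
                "contrasts": contrasts.to_dict(orient="records"),
            }
        (out_dir / "stats.json").write_text(json.dumps(stats_bundle, indent=2))
        (out_dir / "stats.txt").write_text(stats_mod.summarize(fits) + "\n")
        log.info("stage=stats measures=%d", len(fits))

    return PipelineResult(measures, control, params_frame, stats_bundle, excluded)
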