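"""Synthetic four-limb accelerometer sessions and longitudinal cohorts.

Real recordings of this kind come from inertial sensors strapped to an
infant's wrists and ankles, sampled at 60 Hz during two play contexts: a
rhythmic rattle-shaking task (~5 min) and unconstrained free play (~10 min).
This module emulates the statistical structure that the downstream
recurrence analysis assumes, so the whole pipeline is testable without any
recorded data:

* a *rhythmic* regime — all four limbs oscillate at a shared frequency,
  with a tunable phase-coupling weight, arm-dominant amplitudes, and a
  ``regularity`` parameter that scales phase jitter (used to encode
  age-related gains in movement regularity);
* an *unstructured* regime — intermittent random bursts of movement with
  no stable dominant frequency, on a background of sensor noise;
* bursty missing-sample injection (contiguous gaps, geometric lengths)
  reproducing the ~10.1 % overall dropout rate typical of these recordings;
* a longitudinal cohort builder with per-visit sample sizes, subject
  overlap across visits, and a built-in task x visit interaction in which
  the rhythmic task's regularity rises at the later visits only.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

LIMBS = ("left_arm", "right_arm", "left_leg", "right_leg")
ARMS = ("left_arm", "right_arm")
VISITS = ("T1", "T2", "T3", "T4")
TASKS = ("rattle", "freeplay")

GRAVITY = 9.81  # m/s^2, DC component of a raw accelerometer magnitude

# Phase-diffusion rate, rad per sqrt(second), at regularity = 0. Scaled by
# 1/sqrt(rate_hz) per sample so a session's decoherence time in seconds is
# independent of the sampling rate.
_JITTER_RATE = 2.0
# Burst carrier frequencies are drawn uniformly from this band (Hz).
_BURST_BAND = (0.5, 6.0)


@dataclass
class LimbTrace:
    """3-axis acceleration of one limb with a per-sample missing flag.

    ``acc`` is an (n, 3) float array in m/s^2; rows where ``missing`` is
    True hold NaN sentinels.
    """

    acc: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (n, 3) array")
        if self.missing.shape != (self.acc.shape[0],):
            raise ValueError("missing mask length must match acc")


@dataclass
class RawSession:
    """One recorded play session: four limb traces plus metadata."""

    subject_id: str
    visit: str
    task: str
    rate_hz: float
    limbs: dict[str, LimbTrace]

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"visit must be one of {VISITS}, got {self.visit!r}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if set(self.limbs) != set(LIMBS):
            raise ValueError(f"limbs must be exactly {LIMBS}")
        lengths = {t.acc.shape[0] for t in self.limbs.values()}
        if len(lengths) != 1 or lengths.pop() < 2:
            raise ValueError("all four limbs must have equal length >= 2")
        for trace in self.limbs.values():
            nan_rows = np.isnan(trace.acc).any(axis=1)
            if not np.array_equal(nan_rows, trace.missing):
                raise ValueError("missing flags must align with NaN sentinels")

    @property
    def n_samples(self) -> int:
        return self.limbs[LIMBS[0]].acc.shape[0]

    def missing_fraction(self) -> dict[str, float]:
        return {name: float(t.missing.mean()) for name, t in self.limbs.items()}


@dataclass
class RegimeParams:
    """Movement-regime parameters for one simulated session.

    ``regularity`` in [0, 1] scales the phase jitter of the rhythmic
    oscillation (1 = perfectly periodic); it is the knob used to encode
    the age effect. ``coupling`` in [0, 1] is the weight of the shared
    oscillator phase relative to each limb's own phase. Burst fields apply
    to the unstructured regime only.
    """

    regime: str
    duration_s: float
    osc_freq_hz: float = 2.5
    coupling: float = 0.7
    arm_leg_ratio: float = 2.0
    burst_rate_hz: float = 0.8
    burst_len_s: float = 1.2
    noise_sd: float = 0.35
    regularity: float = 0.45
    amplitude: float = 1.5  # leg oscillation / burst amplitude, m/s^2

    def __post_init__(self) -> None:
        if self.regime not in ("rhythmic", "unstructured"):
            raise ValueError("regime must be 'rhythmic' or 'unstructured'")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("coupling", "regularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.osc_freq_hz <= 0 or self.burst_rate_hz < 0 or self.burst_len_s <= 0:
            raise ValueError("frequencies and burst lengths must be positive")


def _unit_vector_vertical_bias(rng: np.random.Generator) -> np.ndarray:
    """Random unit direction with |z| >= ~0.5 (movement visible in magnitude).

    A raw accelerometer magnitude is dominated by gravity along z; only the
    component of movement parallel to gravity survives to first order, so
    directions are biased vertically to keep the simulated oscillation or
    burst visible after the magnitude collapse.
    """
    u = rng.normal(size=3)
    u[2] = np.sign(u[2] or 1.0) * (0.6 + 0.4 * rng.uniform())
    return u / np.linalg.norm(u)


def generate_session(
    params: RegimeParams,
    seed: int,
    *,
    subject_id: str = "S00",
    visit: str = "T1",
    task: str | None = None,
    rate_hz: float = 60.0,
) -> RawSession:
    """Simulate one four-limb session; bit-identical under (params, seed).

    The rhythmic regime gives each limb magnitude a dominant spectral peak
    at ``osc_freq_hz`` (weighted across limbs by ``coupling``); the
    unstructured regime produces intermittent bursts with no stable peak.
    """
    if params.regime == "rhythmic" and params.osc_freq_hz >= rate_hz / 2:
        raise ValueError("osc_freq_hz must be below the Nyquist frequency")
    n = int(round(params.duration_s * rate_hz))
    if n < 2:
        raise ValueError("duration too short for at least 2 samples")
    if task is None:
        task = "rattle" if params.regime == "rhythmic" else "freeplay"

    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate_hz
    gravity = np.array([0.0, 0.0, GRAVITY])
    limbs: dict[str, LimbTrace] = {}

    if params.regime == "rhythmic":
        jitter_sd = _JITTER_RATE * (1.0 - params.regularity) / np.sqrt(rate_hz)
        base_phase = 2.0 * np.pi * params.osc_freq_hz * t
        shared = base_phase + np.cumsum(rng.normal(0.0, jitter_sd, n))
        for name in LIMBS:
            own = (
                base_phase
                + rng.uniform(0.0, 2.0 * np.pi)
                + np.cumsum(rng.normal(0.0, jitter_sd, n))
            )
            phase = params.coupling * shared + (1.0 - params.coupling) * own
            amp = params.amplitude * (params.arm_leg_ratio if name in ARMS else 1.0)
            direction = _unit_vector_vertical_bias(rng)
            acc = (
                gravity
                + amp * np.sin(phase)[:, None] * direction
                + rng.normal(0.0, params.noise_sd, (n, 3))
            )
            limbs[name] = LimbTrace(acc, np.zeros(n, dtype=bool))
    else:
        n_events = rng.poisson(params.burst_rate_hz * params.duration_s * len(LIMBS))
        events = [
            (
                rng.integers(0, len(LIMBS)),           # target limb
                rng.uniform(0.0, params.duration_s),   # onset, s
                max(0.1, rng.exponential(params.burst_len_s)),
                rng.uniform(*_BURST_BAND),             # carrier frequency
                params.amplitude * rng.uniform(0.5, 2.0),
                _unit_vector_vertical_bias(rng),
                rng.uniform(0.0, 2.0 * np.pi),
            )
            for _ in range(n_events)
        ]
        signals = {
            name: rng.normal(0.0, params.noise_sd, (n, 3)) + gravity for name in LIMBS
        }
        for limb_i, onset, length, freq, amp, direction, phi in events:
            name = LIMBS[limb_i]
            freq = min(freq, 0.45 * rate_hz)
            i0 = int(onset * rate_hz)
            i1 = min(n, i0 + int(length * rate_hz))
            if i1 <= i0 + 1:
                continue
            tt = t[i0:i1] - t[i0]
            envelope = np.sin(np.pi * tt / tt[-1])  # half-sine on/off ramp
            carrier = np.sin(2.0 * np.pi * freq * tt + phi)
            arm_gain = params.arm_leg_ratio if name in ARMS else 1.0
            signals[name][i0:i1] += (
                amp * arm_gain * (envelope * carrier)[:, None] * direction
            )
        for name in LIMBS:
            limbs[name] = LimbTrace(signals[name], np.zeros(n, dtype=bool))

    return RawSession(subject_id, visit, task, rate_hz, limbs)


def inject_missing(
    session: RawSession, missing_rate: float, mean_gap: float = 5.0, seed: int = 0
) -> RawSession:
    """Flag contiguous sample gaps so each limb loses ~``missing_rate``.

    Gap lengths are geometric with the given mean (sensor dropouts are
    bursty); gaps are added until the target count is reached, truncating
    the final gap so the achieved fraction is exact to within one sample.
    The first and last sample of every limb are never removed, and
    non-missing values are preserved exactly.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if mean_gap < 1:
        raise ValueError("mean_gap must be >= 1")
    out = copy.deepcopy(session)
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = session.n_samples
    target = int(round(missing_rate * n))
    for name in LIMBS:
        trace = out.limbs[name]
        flags = trace.missing
        while int(flags.sum()) < target:
            start = int(rng.integers(1, n - 1))
            length = int(rng.geometric(1.0 / mean_gap))
            stop = min(start + length, n - 1)
            budget = target - int(flags.sum()) + int(flags[start:stop].sum())
            flags[start : min(stop, start + budget)] = True
        trace.acc[flags] = np.nan
    return out


@dataclass
class CohortDesign:
    """Longitudinal cohort layout: who is seen when, and the built-in effect.

    ``effect`` maps visit -> regularity increment applied to the rhythmic
    (rattle) task only; the default is zero at the first two visits and
    positive at the last two, which builds in a task x visit interaction
    emerging late, while the unstructured free-play task is visit-invariant.
    ``subject_sd`` is the SD of a per-subject latent regularity offset,
    inducing within-subject correlation across that subject's sessions.
    """

    n_per_visit: tuple[int, int, int, int] = (19, 21, 26, 17)
    n_subjects: int = 26
    tasks: tuple[str, ...] = TASKS
    effect: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.0, "T2": 0.0, "T3": 0.40, "T4": 0.45}
    )
    missing_rate: float = 0.101
    mean_gap: float = 5.0
    seed: int = 0
    rate_hz: float = 60.0
    durations_s: dict[str, float] = field(
        default_factory=lambda: {"rattle": 300.0, "freeplay": 600.0}
    )
    rattle_params: RegimeParams | None = None
    freeplay_params: RegimeParams | None = None
    subject_sd: float = 0.05

    def __post_init__(self) -> None:
        if len(self.n_per_visit) != len(VISITS):
            raise ValueError("n_per_visit needs one count per visit")
        if any(c < 0 for c in self.n_per_visit):
            raise ValueError("visit counts must be >= 0")
        if max(self.n_per_visit) > self.n_subjects:
            raise ValueError("visit count exceeds subject pool")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.rattle_params is None:
            self.rattle_params = RegimeParams(
                "rhythmic", self.durations_s["rattle"]
            )
        if self.freeplay_params is None:
            self.freeplay_params = RegimeParams(
                "unstructured", self.durations_s["freeplay"]
            )


def scaled_design(seed: int = 0, duration_s: float = 50.0, rate_hz: float = 12.0,
                  **overrides) -> CohortDesign:
    """Desk-scale cohort profile for simulation studies and tests.

    Same cohort structure and built-in effect as the full design, but short
    sessions at a reduced sampling rate, keeping replicated end-to-end runs
    (hundreds of cohorts) tractable on one CPU. The oscillation frequency
    (2.5 Hz) stays well below the reduced Nyquist limit.
    """
    return CohortDesign(
        seed=seed,
        rate_hz=rate_hz,
        durations_s={"rattle": duration_s, "freeplay": duration_s},
        **overrides,
    )


def generate_cohort(design: CohortDesign) -> list[RawSession]:
    """Generate one session per (subject, visit, task) cell of the design.

    Visit rosters are drawn from a fixed subject pool so subjects overlap
    across visits (longitudinal attrition); the rhythmic task's regularity
    follows ``design.effect`` across visits while the free-play task does
    not. Deterministic under ``design.seed``.
    """
    if sum(design.n_per_visit) == 0:
        raise ValueError("empty design: no sessions to generate")
    rng = np.random.default_rng(design.seed)
    pool = [f"S{i + 1:02d}" for i in range(design.n_subjects)]
    subject_offset = {
        s: design.subject_sd * rng.standard_normal() for s in pool
    }
    sessions: list[RawSession] = []
    for visit, count in zip(VISITS, design.n_per_visit):
        roster = sorted(rng.choice(pool, size=count, replace=False))
        for subject in roster:
            for task in design.tasks:
                if task == "rattle":
                    base = design.rattle_params
                    regularity = float(
                        np.clip(
                            base.regularity
                            + design.effect.get(visit, 0.0)
                            + subject_offset[subject],
                            0.0,
                            1.0,
                        )
                    )
                    params = replace(base, regularity=regularity)
                else:
                    params = design.freeplay_params
                seed = int(rng.integers(0, 2**31 - 1))
                session = generate_session(
                    params,
                    seed,
                    subject_id=subject,
                    visit=visit,
                    task=task,
                    rate_hz=design.rate_hz,
                )
                if design.missing_rate > 0:
                    session = inject_missing(
                        session,
                        design.missing_rate,
                        design.mean_gap,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                sessions.append(session)
    return sessions
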