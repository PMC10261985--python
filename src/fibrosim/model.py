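"""Core continuous-time Markov chain (CTMC) model of fibrosis progression.

The liver fibrosis stage F0-F4 is modelled as a birth-death CTMC on five
states.  Adjacent stages are connected by forward (progression) rates
``p1, p3, p5, p7`` and reverse (regression) rates ``p2, p4, p6, p8``, all in
units of 1/month; the reciprocal of a rate is the mean transition time tau in
months.  A patient starting at F0 is a *progressor* with probability ``p0``
(the progressor fraction); non-progressors remain at F0 forever.  Patients
starting at F1-F4 always evolve.

Two complementary views of the model are provided:

* a stochastic next-reaction simulator (:func:`simulate_patient`,
  :func:`simulate_cohort`) that draws competing exponential waiting times and
  fires the shortest, and
* a deterministic oracle (:func:`transition_probability_matrix`) based on the
  matrix exponential of the generator, giving exact stage-occupancy
  probabilities at any horizon.

The two agree in distribution; the oracle is used for variance-free objective
evaluation and for validating the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_STAGES",
    "STAGE_LABELS",
    "PARAMETER_NAMES",
    "NoTransitionError",
    "AbsorbingStateError",
    "RateParameters",
    "ScaleFactors",
    "PatientTrajectory",
    "CohortDistribution",
    "TransitionTable",
    "sample_waiting_time",
    "step_patient",
    "simulate_patient",
    "simulate_cohort",
    "simulate_final_stages",
    "transition_probability_matrix",
    "average_fibrosis_score",
]

N_STAGES = 5
STAGE_LABELS = ("F0", "F1", "F2", "F3", "F4")

#: rate parameter names in the conventional order: odd indices are forward
#: (progression) rates, even indices reverse (regression) rates.
PARAMETER_NAMES = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")


class NoTransitionError(ValueError):
    """Raised when a waiting time is requested for a disabled transition."""


class AbsorbingStateError(RuntimeError):
    """Raised when no transition with positive rate leaves the current state."""


def _validate_stage(stage: int) -> int:
    stage = int(stage)
    if not 0 <= stage < N_STAGES:
        raise ValueError(f"fibrosis stage must be in 0..4, got {stage}")
    return stage


@dataclass(frozen=True)
class RateParameters:
    """The nine CTMC parameters: progressor fraction plus eight rates.

    Parameters
    ----------
    progressor_fraction
        Probability p0 in [0, 1] that a patient starting at F0 can progress.
    forward
        Rates (1/month) for F0->F1, F1->F2, F2->F3, F3->F4 (p1, p3, p5, p7).
    reverse
        Rates (1/month) for F1->F0, F2->F1, F3->F2, F4->F3 (p2, p4, p6, p8).

    A rate of zero disables the transition (infinite mean time).  Mean
    transition times are ``tau = 1 / rate`` for positive rates.
    """

    progressor_fraction: float
    forward: np.ndarray
    reverse: np.ndarray

    def __post_init__(self) -> None:
        fwd = np.asarray(self.forward, dtype=float)
        rev = np.asarray(self.reverse, dtype=float)
        if fwd.shape != (4,) or rev.shape != (4,):
            raise ValueError("forward and reverse must each hold 4 rates")
        if np.any(fwd < 0) or np.any(rev < 0) or not (
            np.all(np.isfinite(fwd)) and np.all(np.isfinite(rev))
        ):
            raise ValueError("transition rates must be finite and >= 0")
        if not 0.0 <= self.progressor_fraction <= 1.0:
            raise ValueError("progressor_fraction must be in [0, 1]")
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)
        fwd.setflags(write=False)
        rev.setflags(write=False)

    @classmethod
    def from_tau(
        cls,
        tau_forward: Sequence[float],
        tau_backward: Sequence[float],
        progressor_fraction: float,
    ) -> "RateParameters":
        """Build from mean transition times in months (the printed convention).

        ``tau = inf`` (or any non-finite value) maps to a rate of zero.
        """
        tf = np.asarray(tau_forward, dtype=float)
        tb = np.asarray(tau_backward, dtype=float)
        if np.any(tf <= 0) or np.any(tb <= 0):
            raise ValueError("mean transition times must be positive")
        with np.errstate(divide="ignore"):
            fwd = np.where(np.isfinite(tf), 1.0 / tf, 0.0)
            rev = np.where(np.isfinite(tb), 1.0 / tb, 0.0)
        return cls(progressor_fraction, fwd, rev)

    @property
    def tau_forward(self) -> np.ndarray:
        """Mean forward transition times (months); inf where the rate is 0."""
        with np.errstate(divide="ignore"):
            return np.where(self.forward > 0, 1.0 / self.forward, np.inf)

    @property
    def tau_backward(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.reverse > 0, 1.0 / self.reverse, np.inf)

    def rate(self, name: str) -> float:
        """Look up a rate by its conventional name p1..p8."""
        i = PARAMETER_NAMES.index(name)
        return float(self.forward[i // 2] if i % 2 == 0 else self.reverse[i // 2])

    def with_scaled_rate(self, name: str, fold: float) -> "RateParameters":
        """Return a copy with one named rate multiplied by ``fold``."""
        if fold <= 0:
            raise ValueError("fold change must be positive")
        i = PARAMETER_NAMES.index(name)
        fwd = self.forward.copy()
        rev = self.reverse.copy()
        if i % 2 == 0:
            fwd[i // 2] *= fold
        else:
            rev[i // 2] *= fold
        return RateParameters(self.progressor_fraction, fwd, rev)

    def with_alpha(self, alpha: Sequence[float]) -> "RateParameters":
        """Apply placebo scale factors: forward rates only."""
        a = np.asarray(alpha, dtype=float)
        if a.shape != (4,) or np.any(a <= 0):
            raise ValueError("alpha must hold 4 positive multipliers")
        return RateParameters(self.progressor_fraction, self.forward * a, self.reverse)

    def with_beta(self, beta: Sequence[float]) -> "RateParameters":
        """Apply drug scale factors: all eight rates, in p1..p8 order."""
        b = np.asarray(beta, dtype=float)
        if b.shape != (8,) or np.any(b <= 0):
            raise ValueError("beta must hold 8 positive multipliers")
        return RateParameters(
            self.progressor_fraction, self.forward * b[0::2], self.reverse * b[1::2]
        )

    def generator(self) -> np.ndarray:
        """5x5 infinitesimal generator Q of the progressor chain (rows sum to 0)."""
        q = np.zeros((N_STAGES, N_STAGES))
        for i in range(4):
            q[i, i + 1] += self.forward[i]
            q[i + 1, i] += self.reverse[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class ScaleFactors:
    """Intervention scale factors: alpha (placebo) and beta (drug).

    ``alpha`` multiplies the four forward rates (diet/exercise advice in the
    placebo arm slows or speeds progression only); ``beta`` multiplies all
    eight rates on top of alpha (the drug may also accelerate regression).
    ``beta`` is ordered p1..p8 (interleaved forward/reverse).
    """

    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, size in (("alpha", 4), ("beta", 8)):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (size,) or np.any(v <= 0):
                raise ValueError(f"{name} must hold {size} positive multipliers")
            object.__setattr__(self, name, v)
            v.setflags(write=False)

    def apply(self, base: RateParameters) -> RateParameters:
        """Compose base rates with alpha, then beta."""
        params = base
        if self.alpha is not None:
            params = params.with_alpha(self.alpha)
        if self.beta is not None:
            params = params.with_beta(self.beta)
        return params


@dataclass
class PatientTrajectory:
    """One simulated disease course: jump times and the stages entered."""

    initial_stage: int
    is_progressor: bool
    events: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_stage(self.initial_stage)
        prev_t, prev_s = 0.0, self.initial_stage
        for t, s in self.events:
            if t <= prev_t:
                raise ValueError("event times must be strictly increasing and > 0")
            if abs(s - prev_s) != 1:
                raise ValueError("consecutive stages must differ by exactly 1")
            prev_t, prev_s = t, s
        if not self.is_progressor and (self.events or self.initial_stage != 0):
            raise ValueError("non-progressors start at F0 and never move")

    def stage_at(self, time: float) -> int:
        """Stage occupied at an observation time (after the last jump <= time)."""
        if time < 0:
            raise ValueError("observation time must be >= 0")
        stage = self.initial_stage
        for t, s in self.events:
            if t > time:
                break
            stage = s
        return stage

    @property
    def final_stage(self) -> int:
        return self.events[-1][1] if self.events else self.initial_stage


@dataclass(frozen=True)
class CohortDistribution:
    """Patient counts per fibrosis stage F0-F4."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (N_STAGES,):
            raise ValueError("counts must hold one entry per stage F0..F4")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("stage counts must be finite and >= 0")
        object.__setattr__(self, "counts", c)
        c.setflags(write=False)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty cohort")
        return self.counts / self.total

    def stages(self) -> np.ndarray:
        """Expand to one integer stage per patient (counts must be integral)."""
        c = np.rint(self.counts).astype(int)
        if not np.allclose(c, self.counts):
            raise ValueError("cannot expand non-integer counts to patients")
        return np.repeat(np.arange(N_STAGES), c)


@dataclass
class TransitionTable:
    """Initial-stage x final-stage patient counts at one follow-up time."""

    time_months: float
    counts: np.ndarray
    study_id: str = "study"
    arm: str = "observational"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (N_STAGES, N_STAGES):
            raise ValueError("counts must be a 5x5 table")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("cell counts must be finite and >= 0")
        if not self.time_months > 0:
            raise ValueError("time_months must be > 0")
        self.counts = c

    def row_total(self, initial_stage: int) -> float:
        return float(self.counts[_validate_stage(initial_stage)].sum())

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    @property
    def initial_distribution(self) -> CohortDistribution:
        return CohortDistribution(self.counts.sum(axis=1))

    @property
    def final_distribution(self) -> CohortDistribution:
        return CohortDistribution(self.counts.sum(axis=0))

    def row_proportions(self) -> np.ndarray:
        """Per-initial-stage final-stage proportions; zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, self.counts / np.where(totals > 0, totals, 1), 0.0)
        return p


# ---------------------------------------------------------------------------
# stochastic engine


def sample_waiting_time(rate: float, u: float) -> float:
    """Draw an exponential waiting time by inversion: tau = (1/rate) ln(1/u).

    ``u`` is a uniform variate in the open interval (0, 1); over repeated
    draws the returned times are exponential with mean ``1/rate`` months.
    """
    if rate <= 0:
        raise NoTransitionError("transition disabled (rate <= 0): infinite waiting time")
    if not 0.0 < u < 1.0:
        raise ValueError("uniform variate must lie strictly inside (0, 1)")
    return math.log(1.0 / u) / rate


def _draw_uniform(rng: np.random.Generator) -> float:
    # rejection of exact 0 keeps log() finite; hit with probability ~2^-53
    while True:
        u = rng.random()
        if u > 0.0:
            return u


def step_patient(
    current_stage: int, params: RateParameters, rng: np.random.Generator
) -> tuple[int, float]:
    """Fire the next transition: draw a clock per enabled move, keep the minimum.

    Returns ``(next_stage, elapsed_months)``.  Discarding the losing clock is
    statistically exact because exponential clocks are memoryless.  Ties
    (probability zero) resolve forward for reproducibility.
    """
    stage = _validate_stage(current_stage)
    fwd_rate = params.forward[stage] if stage < 4 else 0.0
    rev_rate = params.reverse[stage - 1] if stage > 0 else 0.0
    t_fwd = (
        sample_waiting_time(fwd_rate, _draw_uniform(rng)) if fwd_rate > 0 else math.inf
    )
    t_rev = (
        sample_waiting_time(rev_rate, _draw_uniform(rng)) if rev_rate > 0 else math.inf
    )
    if math.isinf(t_fwd) and math.isinf(t_rev):
        raise AbsorbingStateError(f"no enabled transition out of stage {stage}")
    if t_fwd <= t_rev:
        return stage + 1, t_fwd
    return stage - 1, t_rev


def simulate_patient(
    initial_stage: int,
    params: RateParameters,
    horizon: float,
    rng: np.random.Generator,
) -> PatientTrajectory:
    """Simulate one patient up to ``horizon`` months.

    A patient starting at F0 is designated progressor once, at t=0, with
    probability ``p0``; the designation is never re-drawn (the chain is
    memoryless), so a progressor who regresses to F0 may progress again.
    Patients starting at F1-F4 always evolve.  The jump that would overshoot
    the horizon is discarded.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    stage = _validate_stage(initial_stage)
    is_progressor = True
    if stage == 0:
        is_progressor = bool(rng.random() < params.progressor_fraction)
    traj = PatientTrajectory(stage, is_progressor)
    if not is_progressor:
        return traj
    t = 0.0
    while True:
        try:
            nxt, dt = step_patient(stage, params, rng)
        except AbsorbingStateError:
            return traj
        t += dt
        if t > horizon:
            return traj
        stage = nxt
        traj.events.append((t, stage))


def simulate_final_stages(
    initial_stages: np.ndarray,
    params: RateParameters,
    horizon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized engine: final stage at ``horizon`` for many patients at once.

    Statistically identical to calling :func:`simulate_patient` per patient
    (same competing-clock scheme, same progressor rule), but draws clocks for
    whole batches.  Intended for cohort simulation, sensitivity sweeps and
    virtual trials where only the endpoint stage matters.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    stages = np.asarray(initial_stages, dtype=np.int64).copy()
    if stages.size and (stages.min() < 0 or stages.max() >= N_STAGES):
        raise ValueError("initial stages must be in 0..4")
    n = stages.size
    elapsed = np.zeros(n)
    active = np.ones(n, dtype=bool)
    at_f0 = stages == 0
    if at_f0.any():
        active[at_f0] = rng.random(int(at_f0.sum())) < params.progressor_fraction
    # per-stage exit rates: fwd[s] upward, rev[s] downward (0 at the ends)
    fwd = np.append(params.forward, 0.0)
    rev = np.append(0.0, params.reverse)
    while active.any():
        idx = np.flatnonzero(active)
        s = stages[idx]
        rate_f, rate_r = fwd[s], rev[s]
        u_f = rng.random(idx.size)
        u_r = rng.random(idx.size)
        with np.errstate(divide="ignore"):
            t_f = np.where(rate_f > 0, -np.log1p(u_f - 1.0) / np.where(rate_f > 0, rate_f, 1.0), np.inf)
            t_r = np.where(rate_r > 0, -np.log1p(u_r - 1.0) / np.where(rate_r > 0, rate_r, 1.0), np.inf)
        wait = np.minimum(t_f, t_r)
        fires = np.isfinite(wait) & (elapsed[idx] + wait <= horizon)
        move = np.where(t_f <= t_r, 1, -1)
        hit = idx[fires]
        stages[hit] += move[fires]
        elapsed[hit] += wait[fires]
        active[idx[~fires]] = False
    return stages


def simulate_cohort(
    initial: CohortDistribution,
    params: RateParameters,
    horizon: float,
    rng: np.random.Generator,
    study_id: str = "simulated",
    arm: str = "simulated",
) -> TransitionTable:
    """Simulate every patient independently and tally (initial, final) counts.

    Row sums of the result equal the input counts per stage (conservation).
    """
    if initial.total < 1:
        raise ValueError("cohort must contain at least one patient")
    init_stages = initial.stages()
    finals = simulate_final_stages(init_stages, params, horizon, rng)
    counts = np.zeros((N_STAGES, N_STAGES))
    np.add.at(counts, (init_stages, finals), 1.0)
    # time_months must be positive for a valid table; a zero horizon is a
    # degenerate identity observation, recorded at an epsilon time
    t = horizon if horizon > 0 else np.finfo(float).tiny
    return TransitionTable(t, counts, study_id=study_id, arm=arm)


# ---------------------------------------------------------------------------
# deterministic oracle


def transition_probability_matrix(params: RateParameters, t: float) -> np.ndarray:
    """Exact stage-occupancy probabilities after ``t`` months.

    Rows index the initial stage, columns the final stage.  Rows 1-4 are the
    matrix exponential ``expm(Q t)`` of the progressor generator; the F0 row
    is the progressor mixture ``(1 - p0) e0 + p0 expm(Q t)[0]`` because only a
    fraction p0 of F0 starters can move.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    p = expm(params.generator() * t)
    p0 = params.progressor_fraction
    m = p.copy()
    m[0] = (1.0 - p0) * np.eye(N_STAGES)[0] + p0 * p[0]
    # clip tiny negative round-off and renormalize rows
    m = np.clip(m, 0.0, None)
    return m / m.sum(axis=1, keepdims=True)


def average_fibrosis_score(dist: CohortDistribution) -> float:
    """Cohort mean of the ordinal stage (0-4), the trial endpoint summary."""
    if dist.total < 1:
        raise ValueError("cannot average an empty cohort")
    return float((dist.counts * np.arange(N_STAGES)).sum() / dist.total)
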