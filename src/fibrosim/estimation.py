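"""Staged parameter estimation for the fibrosis CTMC.

The fitting pipeline mirrors how intervention data become interpretable on
top of natural-history data:

1. :func:`fit_observational` — all eight transition rates plus the
   progressor fraction, against observational paired-biopsy tables spanning
   several follow-up times.
2. :func:`fit_alpha` — with the natural-history rates frozen, a per-study
   placebo effect as four multipliers on the forward rates only (diet and
   exercise advice slows progression but is not assumed to reverse fibrosis).
3. :func:`fit_beta` — with rates and alpha frozen, the drug effect as eight
   multipliers on all rates (a drug may also accelerate regression).
4. :func:`predict_arm` — forward simulation of a held-out arm under the
   composed parameters.

The objective is a sum of squared errors between predicted and observed
final-stage proportions, each group weighted by the number of patients
observed in it (completers).  Two objective modes exist: ``expected``
(deterministic, matrix-exponential predictions — the default, stable under
optimization) and ``simulated`` (Monte-Carlo mean of ``n_reps`` stochastic
cohort replicates — the literal trial-simulation procedure, used for final
reporting).

The optimizer is an evolutionary search (differential evolution) over log10
mean transition times and scale factors, with the population size and
generation budget as the tunable budget.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .io import ArmSummary, StudyDataset
from .model import (
    N_STAGES,
    CohortDistribution,
    RateParameters,
    TransitionTable,
    simulate_final_stages,
    transition_probability_matrix,
)

__all__ = [
    "ObjectiveConfig",
    "OptimizerConfig",
    "FitReport",
    "ArmPrediction",
    "objective",
    "fit_observational",
    "fit_alpha",
    "fit_beta",
    "predict_arm",
    "effective_parameters",
    "tau_fold_changes",
    "tau_table",
]

logger = logging.getLogger(__name__)

Entry = TransitionTable | ArmSummary


@dataclass(frozen=True)
class ObjectiveConfig:
    """How model predictions are scored against observed tables."""

    mode: str = "expected"
    n_reps: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("expected", "simulated"):
            raise ValueError("mode must be 'expected' or 'simulated'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class OptimizerConfig:
    """Evolutionary-search budget and box constraints (log10 scale)."""

    population_size: int = 200
    max_generations: int = 100
    log_tau_bounds: tuple[float, float] = (0.0, 5.0)
    log_scale_bounds: tuple[float, float] = (-3.0, 3.0)
    p0_bounds: tuple[float, float] = (0.0, 1.0)
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size > 200:
            raise ValueError("population_size must be in 2..200")
        if not 1 <= self.max_generations <= 100:
            raise ValueError("max_generations must be in 1..100")
        lo, hi = self.p0_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("p0_bounds must be an interval inside [0, 1]")


@dataclass
class FitReport:
    """What the optimizer did and how well the result fits."""

    objective_value: float
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    success: bool = True
    message: str = ""
    identifiability_warning: bool = False
    residuals: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "objective_value": self.objective_value,
            "trace": list(self.trace),
            "n_evaluations": self.n_evaluations,
            "success": self.success,
            "message": self.message,
            "identifiability_warning": self.identifiability_warning,
            "residuals": self.residuals,
        }


def _entries(data) -> list[Entry]:
    if isinstance(data, StudyDataset):
        return list(data.entries)
    if isinstance(data, (TransitionTable, ArmSummary)):
        return [data]
    out: list[Entry] = []
    for item in data:
        out.extend(_entries(item))
    if not out:
        raise ValueError("no data entries to fit against")
    return out


# ---------------------------------------------------------------------------
# objective


def _prepare(entries: list[Entry]) -> list[tuple]:
    """Freeze the observation-side quantities so optimizer loops skip re-tallying.

    Each item: (time, kind, observed proportions, weights, initial stages,
    initial proportions) with kind 'table' or 'arm'.
    """
    prepared = []
    for entry in entries:
        t = float(entry.time_months)
        if isinstance(entry, TransitionTable):
            row_n = entry.counts.sum(axis=1)
            if row_n.sum() == 0:
                logger.warning("transition table at t=%g has no patients; skipped", t)
                continue
            prepared.append(
                (t, "table", entry.row_proportions(), row_n,
                 entry.initial_distribution.stages(), None)
            )
        else:
            if entry.final.total == 0 or entry.initial.total == 0:
                logger.warning("arm %r at t=%g has no patients; skipped", entry.arm, t)
                continue
            prepared.append(
                (t, "arm", entry.final.proportions, entry.final.total,
                 entry.initial.stages(), entry.initial.proportions)
            )
    return prepared


def _objective_prepared(
    params: RateParameters,
    prepared: list[tuple],
    config: ObjectiveConfig,
    rng: np.random.Generator | None,
) -> float:
    total = 0.0
    for t, kind, obs, weight, init_stages, init_props in prepared:
        pred = _predict_rows(params, init_stages, t, config, rng)
        if kind == "table":
            total += float((weight[:, None] * (pred - obs) ** 2).sum())
        else:
            marginal = init_props @ pred
            total += float(weight * ((marginal - obs) ** 2).sum())
    return total


def _predict_rows(
    params: RateParameters,
    initial_stages: np.ndarray,
    t: float,
    config: ObjectiveConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Pooled 5x5 final-stage frequency table for given starting patients."""
    if config.mode == "expected":
        return transition_probability_matrix(params, t)
    if rng is None:
        raise ValueError("simulated objective mode needs an rng")
    tiled = np.tile(initial_stages, config.n_reps)
    finals = simulate_final_stages(tiled, params, t, rng)
    counts = np.zeros((N_STAGES, N_STAGES))
    np.add.at(counts, (tiled, finals), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)


def objective(
    params: RateParameters,
    data,
    config: ObjectiveConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Patient-weighted sum of squared proportion errors.

    For a :class:`TransitionTable`, predictions are per initial stage and each
    row's squared errors are weighted by that row's completer count.  For an
    :class:`ArmSummary`, the predicted marginal final distribution (initial
    proportions propagated through the model) is compared with the observed
    final proportions, weighted by the number of completers in the arm.
    Time points with no observed patients contribute zero (logged).
    """
    config = config or ObjectiveConfig()
    return _objective_prepared(params, _prepare(_entries(data)), config, rng)


# ---------------------------------------------------------------------------
# optimizer plumbing


def _check_identifiability(entries: list[Entry]) -> bool:
    times = {float(e.time_months) for e in entries}
    if len(times) < 2:
        warnings.warn(
            "data span a single follow-up time; rates and progressor fraction "
            "are unlikely to be jointly identifiable",
            UserWarning,
            stacklevel=3,
        )
        return True
    return False


def _residuals(params: RateParameters, entries: list[Entry]) -> list[dict]:
    out = []
    cfg = ObjectiveConfig(mode="expected")
    for e in entries:
        t = float(e.time_months)
        m = transition_probability_matrix(params, t)
        if isinstance(e, TransitionTable):
            res = m - e.row_proportions()
            label = f"{e.study_id}/{e.arm}"
        else:
            res = e.initial.proportions @ m - e.final.proportions
            label = f"{e.study_id}/{e.arm}"
        out.append(
            {
                "entry": label,
                "time_months": t,
                "max_abs_residual": float(np.abs(res).max()),
                "sse": objective(params, e, cfg),
            }
        )
    return out


def _run_de(func, bounds, opt: OptimizerConfig):
    ndim = len(bounds)
    popsize = max(2, int(np.ceil(opt.population_size / ndim)))
    trace: list[float] = []

    def callback(xk, convergence=None):
        trace.append(float(func(xk)))

    result = differential_evolution(
        func,
        bounds,
        seed=opt.seed,
        popsize=popsize,
        maxiter=opt.max_generations,
        tol=opt.tol,
        init="sobol",
        updating="deferred",
        polish=True,
        callback=callback,
    )
    return result, trace


def fit_observational(
    data,
    objective_config: ObjectiveConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RateParameters, FitReport]:
    """Fit all eight rates and the progressor fraction to paired-biopsy data.

    Search is over log10 mean transition times (so the decades from months to
    centuries are covered evenly) plus the progressor fraction on a linear
    scale.  Returns the best parameters found and a :class:`FitReport` with
    the best-objective trace and per-table residuals.
    """
    obj_cfg = objective_config or ObjectiveConfig()
    opt_cfg = optimizer_config or OptimizerConfig()
    entries = _entries(data)
    warned = _check_identifiability(entries)
    if rng is None:
        rng = np.random.default_rng(opt_cfg.seed)
    prepared = _prepare(entries)

    lo, hi = opt_cfg.log_tau_bounds
    bounds = [(lo, hi)] * 8 + [opt_cfg.p0_bounds]

    def func(x):
        p = RateParameters.from_tau(10 ** x[0:4], 10 ** x[4:8], float(x[8]))
        return _objective_prepared(p, prepared, obj_cfg, rng)

    result, trace = _run_de(func, bounds, opt_cfg)
    best = RateParameters.from_tau(
        10 ** result.x[0:4], 10 ** result.x[4:8], float(result.x[8])
    )
    report = FitReport(
        objective_value=float(result.fun),
        trace=trace,
        n_evaluations=int(result.nfev),
        success=bool(result.success),
        message=str(result.message),
        identifiability_warning=warned,
        residuals=_residuals(best, entries),
    )
    return best, report


def fit_alpha(
    base: RateParameters,
    placebo_data,
    objective_config: ObjectiveConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, FitReport]:
    """Fit the four placebo forward-rate multipliers with base rates frozen."""
    obj_cfg = objective_config or ObjectiveConfig()
    opt_cfg = optimizer_config or OptimizerConfig()
    entries = _entries(placebo_data)
    if rng is None:
        rng = np.random.default_rng(opt_cfg.seed)
    prepared = _prepare(entries)
    bounds = [opt_cfg.log_scale_bounds] * 4

    def func(x):
        return _objective_prepared(base.with_alpha(10 ** x), prepared, obj_cfg, rng)

    result, trace = _run_de(func, bounds, opt_cfg)
    alpha = 10 ** result.x
    report = FitReport(
        objective_value=float(result.fun),
        trace=trace,
        n_evaluations=int(result.nfev),
        success=bool(result.success),
        message=str(result.message),
        residuals=_residuals(base.with_alpha(alpha), entries),
    )
    return alpha, report


def fit_beta(
    base: RateParameters,
    alpha: np.ndarray,
    treatment_data,
    objective_config: ObjectiveConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, FitReport]:
    """Fit the eight drug multipliers with base rates and alpha frozen."""
    obj_cfg = objective_config or ObjectiveConfig()
    opt_cfg = optimizer_config or OptimizerConfig()
    entries = _entries(treatment_data)
    if rng is None:
        rng = np.random.default_rng(opt_cfg.seed)
    placebo = base.with_alpha(alpha)
    prepared = _prepare(entries)
    bounds = [opt_cfg.log_scale_bounds] * 8

    def func(x):
        return _objective_prepared(placebo.with_beta(10 ** x), prepared, obj_cfg, rng)

    result, trace = _run_de(func, bounds, opt_cfg)
    beta = 10 ** result.x
    report = FitReport(
        objective_value=float(result.fun),
        trace=trace,
        n_evaluations=int(result.nfev),
        success=bool(result.success),
        message=str(result.message),
        residuals=_residuals(placebo.with_beta(beta), entries),
    )
    return beta, report


# ---------------------------------------------------------------------------
# prediction and reporting


@dataclass
class ArmPrediction:
    """Mean and SD of final stage counts over stochastic replicates."""

    mean: np.ndarray
    sd: np.ndarray
    n_reps: int

    @property
    def mean_distribution(self) -> CohortDistribution:
        return CohortDistribution(self.mean)


def effective_parameters(
    base: RateParameters,
    alpha: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> RateParameters:
    """Compose base rates with placebo (alpha) then drug (beta) factors."""
    params = base
    if alpha is not None:
        params = params.with_alpha(alpha)
    if beta is not None:
        params = params.with_beta(beta)
    return params


def predict_arm(
    params: RateParameters,
    initial: CohortDistribution,
    horizon: float,
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
    alpha: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> ArmPrediction:
    """Simulate an arm ``n_reps`` times; mean +/- SD of final stage counts."""
    if initial.total < 1:
        raise ValueError("cohort must contain at least one patient")
    rng = rng if rng is not None else np.random.default_rng(0)
    eff = effective_parameters(params, alpha, beta)
    stages = initial.stages()
    tiled = np.tile(stages, n_reps)
    finals = simulate_final_stages(tiled, eff, horizon, rng)
    rep_idx = np.repeat(np.arange(n_reps), stages.size)
    per_rep = np.zeros((n_reps, N_STAGES))
    np.add.at(per_rep, (rep_idx, finals), 1.0)
    return ArmPrediction(per_rep.mean(axis=0), per_rep.std(axis=0, ddof=1), n_reps)


def tau_fold_changes(base: RateParameters, effective: RateParameters) -> pd.DataFrame:
    """Fold changes of mean transition times, effective vs base.

    Reported as tau ratios (matching the printed-table convention), one row
    per adjacent stage pair.  A fold > 1 on a forward time means slower
    progression; > 1 on a backward time means slower regression.
    """
    pairs = [f"F{i}<->F{i + 1}" for i in range(4)]
    return pd.DataFrame(
        {
            "transition": pairs,
            "forward_fold": effective.tau_forward / base.tau_forward,
            "backward_fold": effective.tau_backward / base.tau_backward,
        }
    )


def tau_table(params: RateParameters) -> pd.DataFrame:
    """Mean transition times in months, printed-table layout."""
    pairs = [f"F{i}<->F{i + 1}" for i in range(4)]
    return pd.DataFrame(
        {
            "transition": pairs,
            "tau_forward_months": params.tau_forward,
            "tau_backward_months": params.tau_backward,
        }
    )
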