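"""Maximum-likelihood fitting of RW models: grid search, simplex refinement, BIC.

Fitting follows a two-stage procedure: an exhaustive grid search over the
constraint box (0.1 < alpha < 0.9, beta > 0; beta grid log-spaced) locates
reasonably good parameters, which seed a Nelder-Mead simplex refinement run
in an unconstrained space (scaled logit for the learning rates, log for
beta) so the constraints hold by construction.

Two likelihood modes are available:

- ``observed`` (default): the analytic log-likelihood of the recorded
  choices, summing log SoftMax probabilities along the trajectory implied by
  the recorded choices and outcomes.
- ``simulated``: predicted choice probabilities from forward simulations
  (default 1000 per parameter set) in which the model itself determines the
  choices used to update reward expectations; the predicted probability of
  the participant's observed choice on each trial is the mean across
  simulations of that choice's SoftMax probability, and the log-likelihood
  sums the logs of these (floored) means.

Model comparison uses BIC = -2 log L + d log n summed over subjects; the
lower sum wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import DataError, ParameterError
from .models import (
    N_PARAMS, PROB_FLOOR, AgentParams, LatentTrajectory, run_model,
)
from .task import TrialSchedule

#: Column order of an exported fit table (bit-exact contract).
FIT_COLUMNS = [
    "subject", "condition", "block", "model",
    "alpha", "alpha_pos", "alpha_neg", "beta",
    "logl", "n", "d", "bic", "converged", "mode",
]


@dataclass(frozen=True)
class GridSpec:
    """Grid-search layout over the constraint box.

    Learning-rate points are placed strictly inside ``alpha_range`` (the
    constraints are open); beta points are log-spaced over ``beta_range``.
    """

    alpha_range: tuple[float, float] = (0.1, 0.9)
    alpha_steps: int = 17
    beta_range: tuple[float, float] = (0.1, 20.0)
    beta_steps: int = 20

    def __post_init__(self):
        lo, hi = self.alpha_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ParameterError(f"alpha_range must satisfy 0 <= lo < hi <= 1, got {self.alpha_range}")
        if self.beta_range[0] <= 0 or self.beta_range[1] <= self.beta_range[0]:
            raise ParameterError(f"beta_range must have 0 < lo < hi, got {self.beta_range}")
        if self.alpha_steps < 1 or self.beta_steps < 1:
            raise ParameterError("grid steps must be >= 1")

    def alphas(self) -> np.ndarray:
        lo, hi = self.alpha_range
        return np.linspace(lo, hi, self.alpha_steps + 2)[1:-1]

    def betas(self) -> np.ndarray:
        return np.geomspace(self.beta_range[0], self.beta_range[1], self.beta_steps)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-session maximum-likelihood fit."""

    model_id: str
    params: AgentParams
    logl: float
    n_trials: int
    n_params: int
    bic: float
    likelihood_mode: str
    grid_params: AgentParams
    grid_logl: float
    converged: bool


def _session_arrays(trials: pd.DataFrame):
    """Extract numpy arrays for the likelihood kernels; validates choices."""
    block = trials["block"].to_numpy(dtype=np.int64)
    s_left = trials["sym_left"].to_numpy(dtype=np.int64)
    s_right = trials["sym_right"].to_numpy(dtype=np.int64)
    chosen = trials["chosen"].to_numpy(dtype=float)
    outcome = trials["outcome"].to_numpy(dtype=float)
    lost = trials["lost"].to_numpy(dtype=bool)

    keep = ~lost
    if not keep.any():
        raise DataError("session has no non-lost trials")
    base = 3 * block
    la = s_left - base
    lb = s_right - base
    lc = np.where(keep, chosen - base, 0).astype(np.int64)
    bad = keep & (lc != la) & (lc != lb)
    if bad.any():
        t = int(np.nonzero(bad)[0][0])
        raise DataError(f"trial {t}: chosen symbol not in the shown pair")
    l_other = np.where(lc == la, lb, la)
    new_block = np.empty(len(block), dtype=bool)
    new_block[0] = True
    new_block[1:] = block[1:] != block[:-1]
    return dict(
        keep=keep, la=la, lb=lb, lc=lc, l_other=l_other,
        outcome=np.where(keep, outcome, 0.0).astype(np.int64),
        new_block=new_block, n_obs=int(keep.sum()),
    )


def _loglik_many(arr, a_pos, a_neg, beta, v0: float = 0.5) -> np.ndarray:
    """Observed-choice log-likelihood for many parameter triples at once.

    ``a_pos``, ``a_neg``, ``beta`` are equal-length vectors; one pass over
    the trials updates a (P, 3) value matrix. The scalar reference path is
    :func:`revlearn.models.run_model`; tests pin the two routes together.
    """
    a_pos = np.asarray(a_pos, dtype=float)
    a_neg = np.asarray(a_neg, dtype=float)
    beta = np.asarray(beta, dtype=float)
    P = len(beta)
    V = np.full((3, P), v0)  # symbol-major: row views avoid fancy indexing
    ll = np.zeros(P)

    keep, lc, l_other = arr["keep"], arr["lc"], arr["l_other"]
    outcome, new_block = arr["outcome"], arr["new_block"]
    n = len(keep)
    for t in range(n):
        if new_block[t]:
            V[:] = v0
        if not keep[t]:
            continue
        vc = V[lc[t]]
        p = 1.0 / (1.0 + np.exp(-beta * (vc - V[l_other[t]])))
        ll += np.log(np.maximum(p, PROB_FLOOR))
        r = outcome[t]
        alpha = a_pos if r == 1 else a_neg
        V[lc[t]] = vc + alpha * (r - vc)
    return ll


def _loglik_scalar(arr, a_pos: float, a_neg: float, beta: float, v0: float = 0.5) -> float:
    """Observed-choice log-likelihood for a single parameter triple.

    Same recursion as :func:`_loglik_many` in plain floats (the P = 1 case is
    the simplex optimiser's hot path).
    """
    keep, lc, l_other = arr["keep"], arr["lc"], arr["l_other"]
    outcome, new_block = arr["outcome"], arr["new_block"]
    v = [v0, v0, v0]
    ll = 0.0
    for t in range(len(keep)):
        if new_block[t]:
            v = [v0, v0, v0]
        if not keep[t]:
            continue
        c = lc[t]
        vc = v[c]
        p = 1.0 / (1.0 + math.exp(-beta * (vc - v[l_other[t]])))
        ll += math.log(p if p > PROB_FLOOR else PROB_FLOOR)
        r = outcome[t]
        v[c] = vc + (a_pos if r == 1 else a_neg) * (r - vc)
    return ll


def log_likelihood_observed(params: AgentParams, trials: pd.DataFrame) -> float:
    """Log-likelihood of the recorded choices under the model's parameters."""
    arr = _session_arrays(trials)
    a_pos, a_neg = params.rates()
    return _loglik_scalar(arr, a_pos, a_neg, params.beta, params.v0)


def log_likelihood_simulated(
    params: AgentParams,
    schedule: TrialSchedule,
    observed: pd.DataFrame,
    n_sims: int = 1000,
    seed: int | None = None,
) -> float:
    """Simulation-based predicted-choice-probability log-likelihood.

    Runs ``n_sims`` forward simulations on the schedule's pre-drawn outcomes
    in which the model's own choices drive value updating. For each non-lost
    observed trial the predicted probability of the participant's choice is
    the mean across simulations of the SoftMax probability each simulation
    assigns to that choice; the log-likelihood sums the logs of the floored
    means. Deterministic given the seed. Observed lost trials are skipped in
    every simulation (no choice, no update), preserving trial alignment.
    """
    if n_sims < 1:
        raise ParameterError(f"n_sims must be >= 1, got {n_sims}")
    if len(schedule.table) != len(observed):
        raise DataError("schedule and observed session differ in length")
    arr = _session_arrays(observed)
    a_pos, a_neg = params.rates()
    beta, v0 = params.beta, params.v0
    rng = np.random.default_rng(seed)

    draws = schedule.table[["draw_sym0", "draw_sym1", "draw_sym2"]].to_numpy(dtype=np.int64)
    keep, la, lb, lc = arr["keep"], arr["la"], arr["lb"], arr["lc"]
    new_block = arr["new_block"]

    V = np.full((n_sims, 3), v0)
    rows = np.arange(n_sims)
    ll = 0.0
    for t in range(len(keep)):
        if new_block[t]:
            V[:] = v0
        if not keep[t]:
            continue
        p_left = 1.0 / (1.0 + np.exp(-beta * (V[:, la[t]] - V[:, lb[t]])))
        p_obs = p_left if lc[t] == la[t] else 1.0 - p_left
        ll += math.log(max(float(p_obs.mean()), PROB_FLOOR))
        go_left = rng.random(n_sims) < p_left
        c = np.where(go_left, la[t], lb[t])
        r = draws[t, c]
        alpha = np.where(r == 1, a_pos, a_neg)
        vc = V[rows, c]
        V[rows, c] = vc + alpha * (r - vc)
    return float(ll)


def _grid_mesh(model_id: str, grid: GridSpec):
    """Lexicographically ordered parameter mesh (ties resolve to smallest)."""
    alphas, betas = grid.alphas(), grid.betas()
    if model_id == "RW1":
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        return A.ravel(), A.ravel(), B.ravel(), A.ravel()
    AP, AN, B = np.meshgrid(alphas, alphas, betas, indexing="ij")
    return AP.ravel(), AN.ravel(), B.ravel(), None


def _mesh_params(model_id: str, a_pos, a_neg, beta, i: int, v0: float) -> AgentParams:
    if model_id == "RW1":
        return AgentParams(model_id="RW1", alpha=float(a_pos[i]), beta=float(beta[i]), v0=v0)
    return AgentParams(model_id="RW2", alpha_pos=float(a_pos[i]),
                       alpha_neg=float(a_neg[i]), beta=float(beta[i]), v0=v0)


def grid_search(
    trials: pd.DataFrame,
    model_id: str = "RW2",
    grid: GridSpec | None = None,
    likelihood_mode: str = "observed",
    schedule: TrialSchedule | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    v0: float = 0.5,
) -> tuple[AgentParams, float]:
    """Exhaustive likelihood evaluation over the parameter grid.

    Returns the maximising cell's parameters and log-likelihood. Ties are
    broken towards the smallest (alpha, then beta) cell. In ``simulated``
    mode the same seed drives every cell (common random numbers).
    """
    grid = grid or GridSpec()
    a_pos, a_neg, beta, _ = _grid_mesh(model_id, grid)
    if likelihood_mode == "observed":
        arr = _session_arrays(trials)
        ll = _loglik_many(arr, a_pos, a_neg, beta, v0)
    elif likelihood_mode == "simulated":
        if schedule is None:
            raise ParameterError("simulated likelihood mode requires the schedule")
        ll = np.array([
            log_likelihood_simulated(
                _mesh_params(model_id, a_pos, a_neg, beta, i, v0),
                schedule, trials, n_sims=n_sims, seed=seed)
            for i in range(len(beta))
        ])
    else:
        raise ParameterError(f"unknown likelihood_mode {likelihood_mode!r}")
    best = int(np.argmax(ll))
    return _mesh_params(model_id, a_pos, a_neg, beta, best, v0), float(ll[best])


# Smooth reparameterisation: rates through a scaled logit into the open
# constraint interval, beta through log. Simplex moves are unconstrained.

def _to_unconstrained(value: float, lo: float, hi: float) -> float:
    z = (value - lo) / (hi - lo)
    z = min(max(z, 1e-9), 1 - 1e-9)
    return math.log(z / (1 - z))


def _from_unconstrained(x: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) / (1.0 + math.exp(-x))


def refine_simplex(
    start: AgentParams,
    trials: pd.DataFrame,
    likelihood_mode: str = "observed",
    schedule: TrialSchedule | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    grid: GridSpec | None = None,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int = 2000,
) -> FitResult:
    """Nelder-Mead refinement from a grid-search start point.

    The learning rates are optimised through a scaled logit into the open
    ``grid.alpha_range`` interval and beta through a log transform, so the
    final estimate always respects the constraints. The returned
    log-likelihood is never below the start's (the start is a simplex
    vertex); non-convergence within the iteration cap is flagged rather than
    raised.
    """
    grid = grid or GridSpec()
    lo, hi = grid.alpha_range
    model_id = start.model_id
    v0 = start.v0
    arr = _session_arrays(trials)

    def unpack(x) -> AgentParams:
        beta = math.exp(min(x[-1], 50.0))
        if model_id == "RW1":
            return AgentParams(model_id="RW1", alpha=_from_unconstrained(x[0], lo, hi),
                               beta=beta, v0=v0)
        return AgentParams(model_id="RW2",
                           alpha_pos=_from_unconstrained(x[0], lo, hi),
                           alpha_neg=_from_unconstrained(x[1], lo, hi),
                           beta=beta, v0=v0)

    def negll(x) -> float:
        p = unpack(x)
        if likelihood_mode == "observed":
            ap, an = p.rates()
            return -_loglik_scalar(arr, ap, an, p.beta, v0)
        return -log_likelihood_simulated(p, schedule, trials, n_sims=n_sims, seed=seed)

    if model_id == "RW1":
        x0 = [_to_unconstrained(start.alpha, lo, hi), math.log(start.beta)]
    else:
        x0 = [_to_unconstrained(start.alpha_pos, lo, hi),
              _to_unconstrained(start.alpha_neg, lo, hi), math.log(start.beta)]

    res = minimize(negll, x0, method="Nelder-Mead",
                   options=dict(xatol=xatol, fatol=fatol, maxiter=maxiter))
    start_ll = -negll(x0)
    if -res.fun >= start_ll:
        params, logl = unpack(res.x), float(-res.fun)
    else:  # defensive: never regress below the start point
        params, logl = unpack(np.asarray(x0)), float(start_ll)

    n = arr["n_obs"]
    d = N_PARAMS[model_id]
    return FitResult(
        model_id=model_id, params=params, logl=logl, n_trials=n, n_params=d,
        bic=bic(logl, d, n), likelihood_mode=likelihood_mode,
        grid_params=start, grid_logl=start_ll, converged=bool(res.success),
    )


def fit_session(
    trials: pd.DataFrame,
    model_id: str = "RW2",
    grid: GridSpec | None = None,
    likelihood_mode: str = "observed",
    schedule: TrialSchedule | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    v0: float = 0.5,
) -> FitResult:
    """Grid search followed by simplex refinement on one session."""
    start, _ = grid_search(trials, model_id, grid, likelihood_mode,
                           schedule=schedule, n_sims=n_sims, seed=seed, v0=v0)
    return refine_simplex(start, trials, likelihood_mode,
                          schedule=schedule, n_sims=n_sims, seed=seed, grid=grid)


def bic(logl: float, d: int, n: int) -> float:
    """Bayesian Information Criterion: -2 log L + d log n (lower is better)."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if d < 0:
        raise ParameterError(f"d must be >= 0, got {d}")
    return -2.0 * logl + d * math.log(n)


@dataclass(frozen=True)
class ModelComparison:
    """Summed-BIC comparison across models (lower sum wins)."""

    table: pd.DataFrame  # columns: model, total_bic, n_fits
    winner: str | None   # None on an exact tie
    is_tie: bool


def compare_models(fits_by_model: Mapping[str, pd.DataFrame] | dict) -> ModelComparison:
    """Sum per-subject BICs for each model and pick the minimum.

    Each value must be a DataFrame with at least ``subject`` and ``bic``
    columns; every model must cover the same subjects. An exact tie on the
    minimum is reported explicitly (``winner=None``).
    """
    if not fits_by_model:
        raise DataError("no model fits supplied")
    subject_sets = {m: frozenset(df["subject"]) for m, df in fits_by_model.items()}
    reference = next(iter(subject_sets.values()))
    for m, subs in subject_sets.items():
        if subs != reference:
            raise DataError(f"model {m!r} covers a different subject set")
    rows = [{"model": m, "total_bic": float(df["bic"].sum()), "n_fits": len(df)}
            for m, df in fits_by_model.items()]
    table = pd.DataFrame(rows).sort_values("total_bic", kind="stable").reset_index(drop=True)
    best = table["total_bic"].iloc[0]
    ties = table["total_bic"] == best
    is_tie = int(ties.sum()) > 1
    return ModelComparison(table=table, winner=None if is_tie else str(table["model"].iloc[0]),
                           is_tie=is_tie)


def latents_from_fit(fit: FitResult, trials: pd.DataFrame) -> LatentTrajectory:
    """Re-enter the fitted parameters on the observed choices.

    The expected values and prediction errors supplied to the statistics
    layer come from this replay of the participant's own choices, not from
    the forward simulations used by the simulated likelihood.
    """
    return run_model(fit.params, trials)


def fit_dataset(
    trials: pd.DataFrame,
    models: tuple[str, ...] = ("RW1", "RW2"),
    granularity: str = "block",
    grid: GridSpec | None = None,
    likelihood_mode: str = "observed",
    v0: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit every subject x condition (x block) session of a cohort.

    ``granularity`` is ``"block"`` (the default: parameters estimated
    individually per participant, block and condition) or ``"session"``
    (pooled over blocks per participant and condition, a convenience mode).
    Returns a flat table with the :data:`FIT_COLUMNS` layout.
    """
    if granularity not in ("block", "session"):
        raise ParameterError(f"granularity must be 'block' or 'session', got {granularity!r}")
    rows = []
    for (subject, condition), sess in trials.groupby(["subject", "condition"], sort=True):
        units = sess.groupby("block", sort=True) if granularity == "block" else [("all", sess)]
        for blk, unit in units:
            for model_id in models:
                fit = fit_session(unit, model_id=model_id, grid=grid,
                                  likelihood_mode=likelihood_mode, seed=seed, v0=v0)
                p = fit.params
                rows.append({
                    "subject": subject, "condition": condition, "block": blk,
                    "model": model_id,
                    "alpha": p.alpha, "alpha_pos": p.alpha_pos,
                    "alpha_neg": p.alpha_neg, "beta": p.beta,
                    "logl": fit.logl, "n": fit.n_trials, "d": fit.n_params,
                    "bic": fit.bic, "converged": fit.converged,
                    "mode": fit.likelihood_mode,
                })
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
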