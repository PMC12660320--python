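"""Synthetic choosers on reversal-learning schedules, and multi-condition cohorts.

The cohort generator emulates the within-subject three-condition design of a
neuromodulation experiment: every subject performs the task once per
condition (fresh schedule each time), and a condition may shift the agent's
parameters additively (e.g. a higher learning rate after reward in a
stimulation-like condition). The ground-truth parameters of every session are
returned alongside the simulated trials so that downstream parameter- and
model-recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .models import AgentParams
from .task import TaskConfig, TrialSchedule, build_schedule

#: Column order of an exported trial table (bit-exact contract).
TRIAL_COLUMNS = [
    "subject", "condition", "block", "trial",
    "sym_left", "sym_right", "chosen", "outcome", "lost",
]

DEFAULT_CONDITIONS = ("NAcc", "dACC", "Sham")

#: Default base agent for synthetic cohorts: mid-range reversal-learning fits.
DEFAULT_BASE_PARAMS = AgentParams(model_id="RW2", alpha_pos=0.35, alpha_neg=0.35, beta=5.0)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic multi-subject, multi-condition cohort.

    ``condition_effects`` maps a condition label to additive parameter shifts,
    e.g. ``{"NAcc": {"alpha_pos": 0.15}}`` raises the reward learning rate in
    the NAcc-like condition. Shifts that push a parameter out of range raise
    before any simulation runs. ``lost_rate`` injects i.i.d. lost trials.
    """

    n_subjects: int = 26
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    base_params: AgentParams = DEFAULT_BASE_PARAMS
    condition_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    lost_rate: float = 0.02
    counterbalance: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.lost_rate < 1.0:
            raise ParameterError(f"lost_rate must be in [0, 1), got {self.lost_rate}")
        for cond in self.condition_effects:
            if cond not in self.conditions:
                raise ParameterError(f"condition_effects references unknown condition {cond!r}")
        # Validate every shifted parameter set up front (raises ParameterError).
        for cond in self.conditions:
            self.params_for(cond)

    def params_for(self, condition: str) -> AgentParams:
        """The agent parameters in force under a condition."""
        effects = self.condition_effects.get(condition, {})
        return self.base_params.shifted(**effects) if effects else self.base_params


def simulate_agent(
    params: AgentParams,
    schedule: TrialSchedule,
    lost_rate: float = 0.0,
    seed: int | None = None,
    subject: str = "s00",
    condition: str = "none",
) -> pd.DataFrame:
    """Simulate one session of an RW agent on a materialised schedule.

    On each non-lost trial the agent chooses between the two shown symbols by
    the SoftMax rule over its current values, receives the schedule's
    pre-drawn outcome for the chosen symbol, and updates only that symbol's
    value. Lost trials (i.i.d. with probability ``lost_rate``) trigger no
    choice and no update. Deterministic given the seed.

    Returns a trial table with columns ``subject, condition, block, trial,
    sym_left, sym_right, chosen, outcome, lost, hp_symbol`` (chosen/outcome
    are NaN on lost trials).
    """
    if not 0.0 <= lost_rate < 1.0:
        raise ParameterError(f"lost_rate must be in [0, 1), got {lost_rate}")
    a_pos, a_neg = params.rates()
    beta, v0 = params.beta, params.v0
    rng = np.random.default_rng(seed)

    t = schedule.table
    block = t["block"].to_numpy()
    s_left = t["sym_left"].to_numpy()
    s_right = t["sym_right"].to_numpy()
    draws = t[["draw_sym0", "draw_sym1", "draw_sym2"]].to_numpy()
    n = len(block)

    chosen = np.full(n, np.nan)
    outcome = np.full(n, np.nan)
    lost = rng.random(n) < lost_rate if lost_rate > 0 else np.zeros(n, dtype=bool)

    v = [v0, v0, v0]
    current_block = -1
    for i in range(n):
        b = block[i]
        if b != current_block:
            v = [v0, v0, v0]
            current_block = b
        if lost[i]:
            continue
        base = 3 * b
        la = s_left[i] - base
        lb = s_right[i] - base
        p_left = 1.0 / (1.0 + math.exp(-beta * (v[la] - v[lb])))
        c = la if rng.random() < p_left else lb
        r = draws[i, c]
        chosen[i] = base + c
        outcome[i] = r
        v[c] = v[c] + (a_pos if r == 1 else a_neg) * (r - v[c])

    return pd.DataFrame({
        "subject": subject,
        "condition": condition,
        "block": block,
        "trial": t["trial"].to_numpy(),
        "sym_left": s_left,
        "sym_right": s_right,
        "chosen": chosen,
        "outcome": outcome,
        "lost": lost,
        "hp_symbol": t["hp_symbol"].to_numpy(),
    })


def simulate_random_agent(
    schedule: TrialSchedule,
    seed: int | None = None,
    lost_rate: float = 0.0,
    subject: str = "s00",
    condition: str = "none",
) -> pd.DataFrame:
    """A value-free control agent choosing uniformly between shown symbols."""
    return simulate_agent(
        AgentParams(model_id="RW1", alpha=0.0, beta=0.0),
        schedule, lost_rate=lost_rate, seed=seed, subject=subject, condition=condition,
    )


def simulate_cohort(
    spec: CohortSpec,
    config: TaskConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: every subject performs every condition.

    Each subject x condition session gets a fresh schedule and an independent
    random stream spawned from ``spec.seed``. When ``counterbalance`` is set,
    the order in which conditions are simulated is rotated across subjects
    (Latin-square style); the order is recorded in the ground-truth table.

    Returns
    -------
    trials : DataFrame
        Concatenated trial tables (one session per subject x condition).
    truth : DataFrame
        Ground-truth parameters per session: subject, condition,
        session_order, model, alpha, alpha_pos, alpha_neg, beta.
    """
    config = config or TaskConfig()
    ss = np.random.SeedSequence(spec.seed)
    n_cond = len(spec.conditions)
    children = ss.spawn(spec.n_subjects * n_cond * 2)

    frames, truth_rows = [], []
    k = 0
    for s in range(spec.n_subjects):
        subject = f"s{s:02d}"
        order = list(range(n_cond))
        if spec.counterbalance:
            shift = s % n_cond
            order = order[shift:] + order[:shift]
        for pos, ci in enumerate(order):
            cond = spec.conditions[ci]
            params = spec.params_for(cond)
            sched = build_schedule(config, seed=children[k])
            trials = simulate_agent(
                params, sched, lost_rate=spec.lost_rate, seed=children[k + 1],
                subject=subject, condition=cond)
            k += 2
            frames.append(trials)
            truth_rows.append({
                "subject": subject, "condition": cond, "session_order": pos,
                "model": params.model_id,
                "alpha": params.alpha, "alpha_pos": params.alpha_pos,
                "alpha_neg": params.alpha_neg, "beta": params.beta,
            })
    trials = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def nacc_tus_cohort(n_subjects: int = 26, delta_alpha_pos: float = 0.15,
                    seed: int = 0) -> CohortSpec:
    """Preset emulating an excitatory NAcc-stimulation cohort.

    Raises the learning rate after reward in the NAcc-like condition,
    matching the direction of an increased reward sensitivity, without
    claiming a physiological mechanism.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        condition_effects={"NAcc": {"alpha_pos": delta_alpha_pos}},
        seed=seed,
    )


def dbs_on_cohort(n_subjects: int = 3, delta_beta: float = -2.5,
                  seed: int = 0) -> CohortSpec:
    """Preset emulating an inhibitory DBS-ON cohort: blunted reward sensitivity."""
    return CohortSpec(
        n_subjects=n_subjects,
        conditions=("ON", "OFF"),
        condition_effects={"ON": {"beta": delta_beta}},
        seed=seed,
    )
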