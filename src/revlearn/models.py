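"""Rescorla-Wagner value learning with symmetric or valence-split learning rates.

Two model variants are implemented:

- ``RW1``: a single learning rate alpha updates the chosen symbol's expected
  value V via the prediction error, V <- V + alpha * (r - V), with r in {0, 1}.
- ``RW2``: asymmetric rates, alpha_pos applied after rewarded outcomes
  (r = 1) and alpha_neg after non-reward (r = 0). RW2 with equal rates is
  exactly RW1.

Choices follow a SoftMax rule over the two shown symbols' values:
P(A) = logistic(beta * (V_A - V_B)), where beta >= 0 is the inverse
temperature (exploration/exploitation). Only the chosen symbol's value is
updated; the unchosen and the unshown symbol carry their values forward.
Values reset to ``v0`` at block boundaries because each block introduces
three fresh symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

#: Floor applied to choice probabilities before logs are taken downstream.
PROB_FLOOR = 1e-12

MODEL_IDS = ("RW1", "RW2")

#: Free-parameter count per model (alpha/beta vs alpha_pos/alpha_neg/beta).
N_PARAMS = {"RW1": 2, "RW2": 3}


@dataclass(frozen=True)
class AgentParams:
    """Parameters of an RW1 or RW2 agent.

    RW1 uses ``alpha``; RW2 uses ``alpha_pos``/``alpha_neg``. Rates live on
    [0, 1] (the degenerate endpoints are legal for control agents), beta is
    any non-negative inverse temperature, and ``v0`` is the initial expected
    value assigned to every symbol at the start of each block.
    """

    model_id: str = "RW2"
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    beta: float = 5.0
    v0: float = 0.5

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ParameterError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.model_id == "RW1":
            if self.alpha is None:
                raise ParameterError("RW1 requires alpha")
            _check_rate("alpha", self.alpha)
        else:
            if self.alpha_pos is None or self.alpha_neg is None:
                raise ParameterError("RW2 requires alpha_pos and alpha_neg")
            _check_rate("alpha_pos", self.alpha_pos)
            _check_rate("alpha_neg", self.alpha_neg)
        if not self.beta >= 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.v0 <= 1.0:
            raise ParameterError(f"v0 must be in [0, 1], got {self.v0}")

    def rates(self) -> tuple[float, float]:
        """(rate after reward, rate after non-reward)."""
        if self.model_id == "RW1":
            return float(self.alpha), float(self.alpha)
        return float(self.alpha_pos), float(self.alpha_neg)

    def shifted(self, **deltas: float) -> "AgentParams":
        """A copy with additive shifts applied to named parameters.

        Raises ParameterError if a shift pushes a parameter out of range.
        """
        updates = {}
        for name, delta in deltas.items():
            current = getattr(self, name)
            if current is None:
                raise ParameterError(f"cannot shift {name}: unset for model {self.model_id}")
            updates[name] = current + delta
        return replace(self, **updates)


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


def update_value(v: float, outcome: int, alpha: float) -> float:
    """Delta-rule update: v + alpha * (outcome - v). Stays in [0, 1]."""
    _check_rate("alpha", alpha)
    if not 0.0 <= v <= 1.0:
        raise ParameterError(f"value must be in [0, 1], got {v}")
    return v + alpha * (outcome - v)


def prediction_error(outcome: int, v: float) -> float:
    """delta = outcome - v, in [-1, 1] for binary outcomes."""
    return outcome - v


def softmax_prob(v_a: float, v_b: float, beta: float) -> float:
    """P(choose A) = logistic(beta * (v_a - v_b)); beta = 0 gives 0.5."""
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    return 1.0 / (1.0 + math.exp(-beta * (v_a - v_b)))


class LatentTrajectory:
    """Trial-wise latent variables implied by parameters and recorded choices.

    ``table`` has one row per trial with columns ``trial`` (global index),
    ``v_sym0..2`` (expected value of each block-local symbol at trial onset),
    ``pe`` (prediction error of the chosen symbol; NaN on lost trials) and
    ``p_chosen`` (SoftMax probability of the recorded choice; NaN on lost
    trials).
    """

    COLUMNS = ["trial", "v_sym0", "v_sym1", "v_sym2", "pe", "p_chosen"]

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def log_likelihood(self) -> float:
        """Sum of log p_chosen over non-lost trials, probability-floored."""
        p = self.table["p_chosen"].to_numpy()
        p = p[~np.isnan(p)]
        return float(np.log(np.maximum(p, PROB_FLOOR)).sum())

    def to_csv(self, path) -> None:
        self.table[self.COLUMNS].to_csv(path, index=False)


def run_model(params: AgentParams, trials: pd.DataFrame) -> LatentTrajectory:
    """Replay recorded choices through the model, producing latent variables.

    ``trials`` needs columns ``block``, ``sym_left``, ``sym_right``,
    ``chosen``, ``outcome``, ``lost`` (one session, rows in presentation
    order). On each non-lost trial the SoftMax probability of the recorded
    choice is computed from the two shown symbols' current values, the
    prediction error from the recorded outcome, and only the chosen symbol's
    value is updated (alpha_pos after reward, alpha_neg after non-reward for
    RW2). Lost trials propagate values unchanged with NaN latents. Values
    reset to ``v0`` at every block boundary.
    """
    a_pos, a_neg = params.rates()
    beta, v0 = params.beta, params.v0

    block = trials["block"].to_numpy(dtype=np.int64)
    s_left = trials["sym_left"].to_numpy(dtype=np.int64)
    s_right = trials["sym_right"].to_numpy(dtype=np.int64)
    chosen = trials["chosen"].to_numpy(dtype=float)
    outcome = trials["outcome"].to_numpy(dtype=float)
    lost = trials["lost"].to_numpy(dtype=bool)

    n = len(block)
    values = np.empty((n, 3))
    pe = np.full(n, np.nan)
    p_chosen = np.full(n, np.nan)

    v = [v0, v0, v0]
    current_block = None
    for t in range(n):
        b = block[t]
        if b != current_block:
            v = [v0, v0, v0]
            current_block = b
        values[t] = v
        if lost[t]:
            continue
        base = 3 * b
        la = s_left[t] - base
        lb = s_right[t] - base
        c = int(chosen[t]) - base
        if c != la and c != lb:
            raise DataError(
                f"trial {t}: chosen symbol {int(chosen[t])} not in pair "
                f"({s_left[t]}, {s_right[t]})")
        other = lb if c == la else la
        p_chosen[t] = 1.0 / (1.0 + math.exp(-beta * (v[c] - v[other])))
        r = outcome[t]
        delta = r - v[c]
        pe[t] = delta
        v[c] = v[c] + (a_pos if r == 1 else a_neg) * delta

    table = pd.DataFrame({
        "trial": np.arange(n, dtype=np.int64),
        "v_sym0": values[:, 0],
        "v_sym1": values[:, 1],
        "v_sym2": values[:, 2],
        "pe": pe,
        "p_chosen": p_chosen,
    })
    return LatentTrajectory(table)
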