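"""Probabilistic reversal-learning task: design parameters and materialised schedules.

The task presents, in each block, three abstract symbols of which exactly one
carries a high reward probability (default 70%) while the other two carry a
low probability (default 30%). On every trial two of the three symbols are
shown, cycling through the three possible pairs in a fixed order
(AB, BC, CA), with the left/right placement randomised. Every
``reversal_period`` trials (default 25) the high probability is covertly
reassigned to a different symbol of the same block, forcing re-learning.

A materialised :class:`TrialSchedule` pre-draws the Bernoulli outcome of all
three block symbols on every trial, so that the outcome a (simulated or
replayed) chooser receives is fully determined by the schedule and the chosen
symbol. Symbols are numbered globally: block ``b`` owns symbols
``3b, 3b+1, 3b+2``, giving 12 distinct symbols for the default four blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError

#: Column order of an exported schedule table (bit-exact contract).
SCHEDULE_COLUMNS = [
    "block", "trial", "sym_left", "sym_right", "hp_symbol",
    "draw_sym0", "draw_sym1", "draw_sym2",
]

DEFAULT_BLOCK_LENGTHS = (100, 100, 60, 60)
DEFAULT_PAIR_ROTATION = ((0, 1), (1, 2), (2, 0))


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the reversal-learning task.

    Parameters
    ----------
    block_lengths
        Trials per block; the default (100, 100, 60, 60) gives 320 trials.
    n_symbols_per_block
        Number of symbols per block; the pair rotation assumes 3.
    p_high, p_low
        Reward probability of the high-probability symbol and of each of the
        two low-probability symbols.
    reversal_period
        Number of trials between covert contingency reversals within a block.
    pair_rotation
        Fixed cyclic order of block-local symbol pairs shown on successive
        trials; restarts at each block.
    response_window
        Response deadline in seconds; only used to label lost trials when
        simulating, no reaction times are modelled.
    seed
        Seed for side randomisation, reversal draws and outcome pre-draws.
    """

    block_lengths: tuple[int, ...] = DEFAULT_BLOCK_LENGTHS
    n_symbols_per_block: int = 3
    p_high: float = 0.70
    p_low: float = 0.30
    reversal_period: int = 25
    pair_rotation: tuple[tuple[int, int], ...] = DEFAULT_PAIR_ROTATION
    response_window: float = 1.25
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "block_lengths", tuple(int(b) for b in self.block_lengths))
        object.__setattr__(self, "pair_rotation",
                           tuple((int(a), int(b)) for a, b in self.pair_rotation))
        if not self.block_lengths or any(b < 1 for b in self.block_lengths):
            raise ConfigError(f"block_lengths: all entries must be >= 1, got {self.block_lengths}")
        if self.n_symbols_per_block != 3:
            raise ConfigError(
                f"n_symbols_per_block: must be 3 for the fixed pair rotation, got {self.n_symbols_per_block}")
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            if not (0.0 <= self.p_high <= 1.0):
                raise ConfigError(f"p_high: must be in [0, 1], got {self.p_high}")
            if not (0.0 <= self.p_low <= 1.0):
                raise ConfigError(f"p_low: must be in [0, 1], got {self.p_low}")
            raise ConfigError(f"p_low: must be strictly below p_high, got p_low={self.p_low}, p_high={self.p_high}")
        if self.reversal_period < 1:
            raise ConfigError(f"reversal_period: must be >= 1, got {self.reversal_period}")
        for pair in self.pair_rotation:
            if len(set(pair)) != 2 or any(s not in range(self.n_symbols_per_block) for s in pair):
                raise ConfigError(f"pair_rotation: invalid pair {pair}")
        if self.response_window <= 0:
            raise ConfigError(f"response_window: must be positive, got {self.response_window}")

    @property
    def n_trials(self) -> int:
        return sum(self.block_lengths)

    @property
    def n_blocks(self) -> int:
        return len(self.block_lengths)

    @property
    def n_symbols(self) -> int:
        return self.n_blocks * self.n_symbols_per_block


class TrialSchedule:
    """A fully materialised task run.

    Wraps a per-trial table (one row per trial, globally indexed) with the
    columns of :data:`SCHEDULE_COLUMNS`:

    - ``block``: 0-based block id
    - ``trial``: 0-based within-block trial index
    - ``sym_left`` / ``sym_right``: global symbol ids shown left/right
    - ``hp_symbol``: global id of the symbol currently carrying ``p_high``
    - ``draw_sym0..2``: pre-drawn Bernoulli outcome (0/1) for each of the
      block's three symbols on this trial (block-local order)
    """

    def __init__(self, table: pd.DataFrame, config: TaskConfig):
        self.table = table.reset_index(drop=True)
        self.config = config

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def pair(self, global_index: int) -> tuple[int, int]:
        """Global symbol ids (left, right) shown on a trial."""
        row = self._row(global_index)
        return int(row.sym_left), int(row.sym_right)

    def hp_symbol(self, global_index: int) -> int:
        return int(self._row(global_index).hp_symbol)

    def _row(self, global_index: int):
        if not 0 <= global_index < len(self.table):
            raise IndexError(f"trial index {global_index} out of range [0, {len(self.table)})")
        return self.table.iloc[global_index]


def build_schedule(config: TaskConfig | None = None, seed: int | None = None) -> TrialSchedule:
    """Materialise a schedule: pairs, side assignment, reversals, outcome draws.

    Deterministic given the seed (``seed`` overrides ``config.seed``). The
    high-probability symbol of each block starts at a uniformly random symbol
    and, at every within-block multiple of ``reversal_period``, moves
    uniformly to one of the two symbols currently at low probability, so a
    reversal always changes the contingency.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_sym = config.n_symbols_per_block
    rows_block, rows_trial = [], []
    left, right, hp_col = [], [], []
    draws = []

    for b, length in enumerate(config.block_lengths):
        base = b * n_sym
        hp_local = int(rng.integers(n_sym))
        probs = np.empty(n_sym)
        for i in range(length):
            if i > 0 and i % config.reversal_period == 0:
                others = [s for s in range(n_sym) if s != hp_local]
                hp_local = int(rng.choice(others))
            a, c = config.pair_rotation[i % len(config.pair_rotation)]
            if rng.random() < 0.5:
                a, c = c, a
            probs.fill(config.p_low)
            probs[hp_local] = config.p_high
            draw = (rng.random(n_sym) < probs).astype(np.int64)
            rows_block.append(b)
            rows_trial.append(i)
            left.append(base + a)
            right.append(base + c)
            hp_col.append(base + hp_local)
            draws.append(draw)

    draws = np.asarray(draws)
    table = pd.DataFrame({
        "block": np.asarray(rows_block, dtype=np.int64),
        "trial": np.asarray(rows_trial, dtype=np.int64),
        "sym_left": np.asarray(left, dtype=np.int64),
        "sym_right": np.asarray(right, dtype=np.int64),
        "hp_symbol": np.asarray(hp_col, dtype=np.int64),
        "draw_sym0": draws[:, 0],
        "draw_sym1": draws[:, 1],
        "draw_sym2": draws[:, 2],
    })
    return TrialSchedule(table, config)


def reversal_points(schedule: TrialSchedule) -> list[int]:
    """Global trial indices at which the high-probability symbol changes.

    Block starts are not reversals; every returned index is a within-block
    multiple of the reversal period (the first trial of the new contingency
    period).
    """
    t = schedule.table
    hp = t["hp_symbol"].to_numpy()
    block = t["block"].to_numpy()
    idx = np.nonzero((block[1:] == block[:-1]) & (hp[1:] != hp[:-1]))[0] + 1
    return [int(i) for i in idx]


def contingency_periods(schedule: TrialSchedule) -> int:
    """Number of contingency periods (stretches with a constant hp symbol)."""
    return len(reversal_points(schedule)) + schedule.config.n_blocks


def is_hp_on_screen(schedule: TrialSchedule, global_index: int) -> bool:
    """True iff the trial's pair contains the current high-probability symbol."""
    row = schedule._row(global_index)
    return int(row.hp_symbol) in (int(row.sym_left), int(row.sym_right))


def write_schedule(schedule: TrialSchedule, path) -> None:
    """Export the schedule as a comma-delimited table (exact column contract)."""
    schedule.table[SCHEDULE_COLUMNS].to_csv(path, index=False)


def read_schedule(path, config: TaskConfig | None = None) -> TrialSchedule:
    """Read a schedule table written by :func:`write_schedule`.

    The config is only needed for reversal bookkeeping helpers; if omitted, a
    config with matching block lengths and default probabilities is inferred.
    """
    from .exceptions import SchemaError

    table = pd.read_csv(path)
    missing = [c for c in SCHEDULE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"schedule file {path} missing column(s): {', '.join(missing)}")
    if config is None:
        lengths = tuple(
            int((table["block"] == b).sum()) for b in sorted(table["block"].unique()))
        config = TaskConfig(block_lengths=lengths)
    return TrialSchedule(table[SCHEDULE_COLUMNS], config)
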