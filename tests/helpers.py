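"""Shared fixtures-in-code: hand-built sessions and random session generators."""

from __future__ import annotations

import numpy as np
import pandas as pd

ROTATION = ((0, 1), (1, 2), (2, 0))


def make_session(pairs, choices, outcomes, lost=None, hp=None, block=0,
                 subject="s00", condition="none", start_trial=0):
    """Build a single-block trial table from parallel per-trial lists.

    ``pairs`` are (left, right) block-local symbol tuples; ``choices`` and
    ``outcomes`` may contain None for lost trials; ``hp`` is the block-local
    high-probability symbol per trial (default 0).
    """
    n = len(pairs)
    lost = [False] * n if lost is None else list(lost)
    hp = [0] * n if hp is None else list(hp)
    base = 3 * block
    rows = []
    for i in range(n):
        chosen = choices[i]
        outcome = outcomes[i]
        rows.append({
            "subject": subject, "condition": condition, "block": block,
            "trial": start_trial + i,
            "sym_left": base + pairs[i][0], "sym_right": base + pairs[i][1],
            "chosen": np.nan if (lost[i] or chosen is None) else base + chosen,
            "outcome": np.nan if (lost[i] or outcome is None) else float(outcome),
            "lost": lost[i],
            "hp_symbol": base + hp[i],
        })
    return pd.DataFrame(rows)


def random_session(rng, n_blocks=2, block_len=15, lost_rate=0.1,
                   subject="s00", condition="none"):
    """A random (model-free) session for invariance and nesting checks."""
    frames = []
    for b in range(n_blocks):
        pairs, choices, outcomes, lost, hp = [], [], [], [], []
        for i in range(block_len):
            p = list(ROTATION[i % 3])
            if rng.random() < 0.5:
                p = p[::-1]
            pairs.append(tuple(p))
            is_lost = rng.random() < lost_rate
            lost.append(is_lost)
            if is_lost:
                choices.append(None)
                outcomes.append(None)
            else:
                choices.append(p[0] if rng.random() < 0.5 else p[1])
                outcomes.append(int(rng.integers(2)))
            hp.append(int(rng.integers(3)))
        frames.append(make_session(pairs, choices, outcomes, lost, hp,
                                   block=b, subject=subject, condition=condition))
    return pd.concat(frames, ignore_index=True)
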