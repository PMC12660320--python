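"""Materialise a reversal-learning schedule and inspect its structure.

Builds the default session (four blocks of 100/100/60/60 trials, three
symbols per block, one at 70% reward and two at 30%, covert reversal every
25 trials) and prints the design constants plus the realised reward rates of
the pre-drawn outcomes.
"""

import numpy as np

import revlearn as rl

config = rl.TaskConfig(seed=7)
schedule = rl.build_schedule(config)
t = schedule.table

print(f"trials: {len(t)} across {config.n_blocks} blocks {config.block_lengths}")
print(f"symbols: {sorted(set(t['sym_left']) | set(t['sym_right']))}")
print(f"reversal points (global trial indices): {rl.reversal_points(schedule)}")
print(f"contingency periods: {rl.contingency_periods(schedule)}")

draws = t[["draw_sym0", "draw_sym1", "draw_sym2"]].to_numpy()
local_hp = t["hp_symbol"].to_numpy() - 3 * t["block"].to_numpy()
rows = np.arange(len(t))
hp_rate = draws[rows, local_hp].mean()
print(f"realised high-probability reward rate in this draw: {hp_rate:.3f} (target 0.70)")
print("first five trials:")
print(t.head().to_string(index=False))
# The hp_symbol column is the symbol currently carrying the 70% contingency;
# draw_sym* are the pre-drawn outcomes a chooser of each symbol would receive.
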