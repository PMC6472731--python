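"""Simulate the visual-search task and inspect the trial structure.

Builds a short-display condition with moderate external uncertainty, draws
trials from the generative model, and applies the pop-out filter (keeping
only displays with 0, 2, or 4 high-reliability stimuli).
"""

import numpy as np

import imbayes as ib

cond = ib.Condition(display_regime="short", mu_target=5.0, sigma_external=3.4)
ts = ib.generate_dataset(cond, n_trials=1500, seed=42)

print(f"{len(ts)} trials; target present on {ts.target_present.mean():.1%}")
counts = np.bincount(ts.high_counts, minlength=5)
print("high-reliability count histogram (0..4):", counts)

kept = ib.popout_filter(ts)
print(f"pop-out filter keeps {len(kept)} trials ({len(kept) / len(ts):.1%})")
# Expected: presence near 50%, a flat count histogram, and ~60% retention —
# the design frequencies of the task.

trial = next(ts.trials())
print("first trial:", trial.orientations.round(1), trial.reliability,
      "target at", trial.target_location)
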