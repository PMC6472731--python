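"""Compare decision variables and response probabilities across observers.

For one display the optimal (flawless Bayesian) observer pools per-item
posterior evidence weighted by reliability; heuristics reduce the display
to a simple statistic. The printed probabilities are P("target present")
after lapse mixing.
"""

import numpy as np

import imbayes as ib
from imbayes.observers import decision_variable, get_model

cond = ib.Condition(display_regime="short", mu_target=5.0, sigma_external=3.0)
x = np.array([6.2, -4.0, -7.5, -3.1])  # observations: item 1 looks like a target
rel = np.array([True, False, True, False])  # items 1 and 3 high reliability

params = ib.ParamVector(
    sigma_low=5.0, sigma_high=2.0, lapse=0.03,
    mu_late=0.0, sigma_late=1.0, criterion=2.0, beta=2.0,
    sigma_single=3.5, n_samples=5,
)

for name in ("flawless_bayes", "imperfect_bayes", "ignorant_bayes",
             "max", "min_dev", "mean", "variance", "sampling_bayes"):
    spec = get_model(name)
    d = decision_variable(spec, x, rel, params, cond)
    p = ib.response_probability_given_observations(spec, x, rel, params, cond)
    print(f"{name:>16}: d = {d:8.3f}   P(present) = {p:.3f}")
# The Bayesian models report a log posterior ratio (positive = evidence for
# a target); heuristic statistics are in degrees (or squared degrees) and
# are compared against the criterion c.
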