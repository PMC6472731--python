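"""Sensitivity (d'), the optimality index, and the loss decomposition.

Sensitivity is the standard signal-detection index d' = z(HR) - z(FAR).
The optimality index I = d'_empirical / d'_optimal compares a dataset's
sensitivity with that of the flawless Bayesian observer simulated under the
same condition. Two variants:

- *relative* index: the optimal observer keeps the subject's sensory noise
  (loss reflects computational imperfections only);
- *absolute* index: the optimal observer's sensory noise is turned off
  (loss reflects sensory noise plus computational imperfections).

The gap between the two attributes the total optimality loss to its two
sources: with I_rel >= I_abs,

    share_sensory        = 100 (I_rel - I_abs) / (1 - I_abs)
    share_computational  = 100 (1 - I_rel) / (1 - I_abs)

which sum to 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .observers import ObserverSpec, ParamVector, simulate_responses
from .task import Condition, TrialSet, generate_dataset

FLAWLESS = ObserverSpec("flawless_bayes")


@dataclass
class OptimalityReport:
    d_emp: float
    d_opt_relative: float
    d_opt_absolute: float
    index_relative: float
    index_absolute: float
    share_sensory: float | None
    share_computational: float | None


def _corrected_rate(hits: int, n: int) -> float:
    """Rate with the 1/(2n) correction for extreme (0 or 1) proportions."""
    rate = hits / n
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    return min(max(rate, lo), hi)


def dprime(responses: np.ndarray, truth: np.ndarray) -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    ``truth`` is target presence, ``responses`` the "present" reports.
    Extreme rates are adjusted by the 1/(2n) rule before the z-transform.
    """
    truth = np.asarray(truth, dtype=bool)
    responses = np.asarray(responses, dtype=bool)
    n_present = int(truth.sum())
    n_absent = int((~truth).sum())
    if n_present == 0 or n_absent == 0:
        raise ValueError("need at least one trial of each class")
    hr = _corrected_rate(int(responses[truth].sum()), n_present)
    far = _corrected_rate(int(responses[~truth].sum()), n_absent)
    return float(norm.ppf(hr) - norm.ppf(far))


def dprime_of_trialset(ts: TrialSet) -> float:
    if not ts.has_responses:
        raise ValueError("trial set has no responses")
    return dprime(ts.response.astype(bool), ts.target_present)


def optimal_dprime(
    condition: Condition,
    sigma_low: float,
    sigma_high: float,
    lapse: float = 0.0,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> float:
    """d' of the flawless Bayesian simulated on fresh trials of ``condition``.

    The lapse rate is included so that the optimal benchmark guesses on the
    same fraction of trials as the fitted observer. Setting both sigmas to 0
    (with a short-regime condition) gives the noiseless benchmark used by
    the absolute optimality index; in that case the decision variable is
    computed from the true stimuli directly.
    """
    if n_sim < 10_000:
        raise ValueError("n_sim must be >= 1e4 for a stable estimate")
    ts = generate_dataset(condition, n_sim, seed=seed)
    params = ParamVector(
        sigma_low=sigma_low, sigma_high=sigma_high, lapse=lapse
    )
    if condition.display_regime == "short" and sigma_low == sigma_high == 0:
        # noiseless benchmark: evaluate the decision rule on s directly
        cond0 = Condition(
            display_regime="unlimited",
            mu_target=condition.mu_target,
            sigma_external=condition.sigma_external,
            fixed_sensory_sd=0.0,
        )
        ts = TrialSet(
            condition=cond0,
            orientations=ts.orientations,
            reliability_high=ts.reliability_high,
            target_present=ts.target_present,
            target_location=ts.target_location,
            seed=ts.seed,
        )
    sim = simulate_responses(FLAWLESS, ts, params, seed=None if seed is None else seed + 1)
    return dprime_of_trialset(sim)


def optimality_index(d_emp: float, d_opt: float) -> float:
    """I = d'_empirical / d'_optimal."""
    if d_opt <= 0:
        raise ValueError("optimal d' must be > 0")
    return d_emp / d_opt


def loss_decomposition(
    index_relative: float, index_absolute: float
) -> tuple[float, float]:
    """Split the total optimality loss into sensory and computational shares.

    Returns ``(share_sensory, share_computational)`` in percent; they sum
    to 100 exactly.
    """
    if not 0 < index_absolute <= index_relative <= 1:
        raise ValueError("need 0 < I_abs <= I_rel <= 1")
    if index_absolute == 1:
        raise ValueError("no loss to decompose when I_abs = 1")
    total = 1.0 - index_absolute
    share_sensory = 100.0 * (index_relative - index_absolute) / total
    share_computational = 100.0 * (1.0 - index_relative) / total
    return share_sensory, share_computational


def optimality_report(
    trialset: TrialSet,
    sigma_low: float,
    sigma_high: float,
    lapse: float = 0.0,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> OptimalityReport:
    """Empirical d', optimal benchmarks, indices, and the loss split."""
    d_emp = dprime_of_trialset(trialset)
    c = trialset.condition
    if c.display_regime == "unlimited":
        sd = float(c.fixed_sensory_sd)
        d_rel = optimal_dprime(c, sd, sd, lapse, n_sim, seed)
        c0 = Condition(
            display_regime="unlimited",
            mu_target=c.mu_target,
            sigma_external=c.sigma_external,
            fixed_sensory_sd=0.0,
        )
        d_abs = optimal_dprime(c0, 0.0, 0.0, lapse, n_sim, seed)
    else:
        d_rel = optimal_dprime(c, sigma_low, sigma_high, lapse, n_sim, seed)
        d_abs = optimal_dprime(c, 0.0, 0.0, lapse, n_sim, seed)
    i_rel = optimality_index(d_emp, d_rel)
    i_abs = optimality_index(d_emp, d_abs)
    shares: tuple[float | None, float | None]
    try:
        shares = loss_decomposition(i_rel, i_abs)
    except ValueError:
        shares = (None, None)
    return OptimalityReport(
        d_emp=d_emp,
        d_opt_relative=d_rel,
        d_opt_absolute=d_abs,
        index_relative=i_rel,
        index_absolute=i_abs,
        share_sensory=shares[0],
        share_computational=shares[1],
    )
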