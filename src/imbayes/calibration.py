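"""Psychometric fitting and the experiment-design solvers.

The discrimination task estimates each subject's sensory noise levels:
the probability of a "clockwise" report is modeled as a cumulative Gaussian
of stimulus orientation, P(cw | s) = Phi(s / sigma), with the mean fixed at
vertical (no bias term). The dual variant fits one sigma per reliability
level; the single variant shares one sigma.

The design solvers invert the optimal observer's predicted accuracy:
``solve_mu_target`` finds the target tilt at which a flawless Bayesian with
the subject's estimated noise levels scores a given accuracy (85% by
default) with no external uncertainty, and ``solve_sigma_external`` finds
the orientation-distribution SD at which that accuracy drops by a given
number of percentage points (5, 10, or 15) from the subject's own zero-
external-uncertainty baseline. Both use common random numbers so the
accuracy curve is a smooth deterministic function of the design parameter
and a bracketing root-finder applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import norm

from .task import N_ITEMS, DiscriminationTrial

SIGMA_FLOOR = 0.05  # lower cap for separable (perfect-responder) data


@dataclass
class PsychometricFit:
    variant: str  # "single_sigma" / "dual_sigma"
    sigma_tilde_low: float
    sigma_tilde_high: float
    loglik: float
    aic: float
    capped: bool = False


def _nll_single(log_sigma: float, s: np.ndarray, y: np.ndarray) -> float:
    p = norm.cdf(s / np.exp(log_sigma))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_sigma(s: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """ML sigma for one response set; returns (sigma, loglik, capped)."""
    res = minimize_scalar(
        _nll_single,
        args=(s, y),
        bounds=(np.log(SIGMA_FLOOR), np.log(60.0)),
        method="bounded",
    )
    sigma = float(np.exp(res.x))
    capped = sigma <= SIGMA_FLOOR * 1.01
    return max(sigma, SIGMA_FLOOR), -float(res.fun), capped


def fit_psychometric(
    data: Sequence[DiscriminationTrial], variant: str = "dual_sigma"
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of discrimination data.

    ``variant="dual_sigma"`` fits separate noise SDs for low- and high-
    reliability stimuli; ``"single_sigma"`` shares one SD. Perfectly
    separable data cap sigma at a small floor and set the ``capped`` flag.
    """
    s = np.array([t.orientation for t in data])
    y = np.array([t.response_cw for t in data], dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both response classes must be present")
    if variant == "single_sigma":
        sigma, ll, capped = _fit_sigma(s, y)
        k = 1
        lo = hi = sigma
    elif variant == "dual_sigma":
        rel = np.array([t.reliability == "high" for t in data])
        ll = 0.0
        capped = False
        lo, ll_lo, cap_lo = _fit_sigma(s[~rel], y[~rel])
        hi, ll_hi, cap_hi = _fit_sigma(s[rel], y[rel])
        ll = ll_lo + ll_hi
        capped = cap_lo or cap_hi
        k = 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return PsychometricFit(
        variant=variant,
        sigma_tilde_low=lo,
        sigma_tilde_high=hi,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# Design solvers


class _SearchAccuracySimulator:
    """Common-random-numbers simulator of the flawless Bayesian's accuracy.

    All randomness (target presence/location, reliability counts, stimulus
    and sensory noise deviates) is drawn once; accuracy is then a smooth
    deterministic function of (mu_target, sigma_external).
    """

    def __init__(
        self,
        sigma_low: float,
        sigma_high: float,
        n_mc: int = 200_000,
        seed: int = 0,
    ):
        if n_mc < 10_000:
            raise ValueError("n_mc must be >= 1e4")
        rng = np.random.default_rng(seed)
        n = n_mc
        self.present = rng.random(n) < 0.5
        loc = rng.integers(0, N_ITEMS, size=n)
        self.target_mask = np.zeros((n, N_ITEMS), dtype=bool)
        self.target_mask[self.present, loc[self.present]] = True
        counts = rng.integers(0, N_ITEMS + 1, size=n)
        order = np.argsort(rng.random((n, N_ITEMS)), axis=1)
        rel_high = order < counts[:, None]
        self.sd = np.where(rel_high, sigma_high, sigma_low)
        self.z_stim = rng.standard_normal((n, N_ITEMS))
        self.z_sens = rng.standard_normal((n, N_ITEMS))

    def accuracy(self, mu_target: float, sigma_external: float) -> float:
        sign = np.where(self.target_mask, 1.0, -1.0)
        s = sign * mu_target + sigma_external * self.z_stim
        x = s + self.sd * self.z_sens
        var = self.sd**2 + sigma_external**2
        d = logsumexp(2.0 * mu_target * x / var, axis=-1) - np.log(N_ITEMS)
        respond_present = d > 0
        return float(np.mean(respond_present == self.present))


def optimal_accuracy(
    sigma_low: float,
    sigma_high: float,
    mu_target: float,
    sigma_external: float = 0.0,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo accuracy of the flawless Bayesian (lapse 0) under the
    standard trial distribution (targets on half the trials, high-reliability
    count uniform on {0..4})."""
    sim = _SearchAccuracySimulator(sigma_low, sigma_high, n_mc, seed)
    return sim.accuracy(mu_target, sigma_external)


MU_BRACKET = (0.1, 45.0)


def solve_mu_target(
    sigma_tilde_low: float,
    sigma_tilde_high: float,
    target_accuracy: float = 0.85,
    tol: float = 0.002,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Target tilt at which the optimal observer scores ``target_accuracy``
    with no external uncertainty."""
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError("target_accuracy must be in (0.5, 1)")
    sim = _SearchAccuracySimulator(sigma_tilde_low, sigma_tilde_high, n_mc, seed)

    def f(mu: float) -> float:
        return sim.accuracy(mu, 0.0) - target_accuracy

    lo, hi = MU_BRACKET
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target accuracy not bracketed in the mu range")
    mu = float(brentq(f, lo, hi, xtol=1e-3))
    if abs(sim.accuracy(mu, 0.0) - target_accuracy) > max(tol, 2e-3):
        raise RuntimeError("solver did not reach the requested accuracy")
    return mu


def solve_sigma_external(
    sigma_tilde_low: float,
    sigma_tilde_high: float,
    mu_target: float,
    drop_level: float,
    tol: float = 0.002,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Orientation-distribution SD at which the optimal observer's accuracy
    drops by ``drop_level`` percentage points from its zero-external-
    uncertainty baseline."""
    if drop_level not in (5, 10, 15):
        raise ValueError("drop_level must be 5, 10, or 15 percentage points")
    sim = _SearchAccuracySimulator(sigma_tilde_low, sigma_tilde_high, n_mc, seed)
    baseline = sim.accuracy(mu_target, 0.0)
    target = baseline - drop_level / 100.0
    if target <= 0.5:
        raise ValueError("requested drop is unattainable (below chance)")

    def f(sig: float) -> float:
        return sim.accuracy(mu_target, sig) - target

    lo, hi = 1e-6, 60.0
    if f(hi) > 0:
        raise ValueError("requested drop not bracketed")
    sig = float(brentq(f, lo, hi, xtol=1e-3))
    if abs(sim.accuracy(mu_target, sig) - target) > max(tol, 2e-3):
        raise RuntimeError("solver did not reach the requested accuracy")
    return sig
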