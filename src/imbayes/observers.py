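"""Decision variables and response probabilities for the observer models.

The model zoo crosses decision strategy (Bayesian vs. heuristic) with the
presence of computational imperfections ("late" Gaussian noise on the
decision variable):

==  ==========================  =====================================
id  name                        decision variable
==  ==========================  =====================================
1   flawless_bayes              log posterior ratio, reliability-weighted
2   imperfect_bayes             id 1 + Normal(mu_late, sigma_late) noise
3   ignorant_bayes              id 1 with one sigma_single for all items
4   imperfect_ignorant_bayes    id 3 + late noise
5   max                         max_i x_i
6   min_dev                     min_i |x_i - mu_target|
7   minkowski                   (sum_i |x_i - mu_target|^beta)^(1/beta)
8   mean                        mean_i x_i
9   variance                    population variance of x (1/N convention)
10  imperfect_max               id 5 + zero-mean late noise
11  imperfect_min_dev           id 6 + late noise
12  imperfect_minkowski         id 7 + late noise
13  imperfect_mean              id 8 + late noise
14  imperfect_variance          id 9 + late noise
--  sampling_bayes              id 1, read out by Bernoulli sampling
==  ==========================  =====================================

Bayesian models respond "present" when the decision variable exceeds 0 (the
optimal criterion); heuristics compare against a fitted criterion ``c``. For
the deviation-based heuristics (ids 6, 7) *small* values are evidence for a
target, so "present" is d < c. Ties respond "absent" (measure zero under
noise; fixed for determinism). Every model mixes in a lapse rate ``lapse``:
with that probability the response is a fair guess.

The optimal local evidence for item i is

    d_local(x_i) = exp[((x_i + mu_T)^2 - (x_i - mu_T)^2)
                       / (2 (sigma_i^2 + sigma_external^2))]
                 = exp[2 mu_T x_i / (sigma_i^2 + sigma_external^2)]

and the global decision variable is ``log((1/N) sum_i d_local(x_i))``,
evaluated with log-sum-exp to avoid overflow. With no sensory noise
(sigma_i = 0) the same expression applies with sigma_external alone, so the
decision variable is a deterministic function of the stimuli.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.stats import binom, norm

from .task import Condition, ConfigurationError, TrialSet, observation_sds


class Family(str, Enum):
    BAYESIAN = "bayesian"
    HEURISTIC = "heuristic"
    SAMPLING = "sampling"


@dataclass(frozen=True)
class ObserverSpec:
    """Identity of one observer model."""

    name: str

    @property
    def model_id(self) -> int | None:
        return MODEL_IDS.get(self.name)

    @property
    def family(self) -> Family:
        if self.name == "sampling_bayes":
            return Family.SAMPLING
        if "bayes" in self.name:
            return Family.BAYESIAN
        return Family.HEURISTIC

    @property
    def imperfect(self) -> bool:
        return self.name.startswith("imperfect_")

    @property
    def base_name(self) -> str:
        return self.name.removeprefix("imperfect_")

    @property
    def ignores_reliability(self) -> bool:
        return self.base_name == "ignorant_bayes"

    @property
    def invert_direction(self) -> bool:
        """True when small decision variables are evidence for a target."""
        return self.base_name in ("min_dev", "minkowski")

    def free_parameters(self, regime: str = "short") -> tuple[str, ...]:
        """Names of the model's free parameters in the given display regime.

        Sensory noise SDs are free only in the short regime; with unlimited
        display time they are fixed by the condition.
        """
        params: list[str] = []
        if regime == "short":
            params += ["sigma_low", "sigma_high"]
        params.append("lapse")
        if self.name == "sampling_bayes":
            params.append("n_samples")
            return tuple(params)
        if self.ignores_reliability and regime == "short":
            params.append("sigma_single")
        if self.family == Family.HEURISTIC:
            params.append("criterion")
            if self.base_name == "minkowski":
                params.append("beta")
        if self.imperfect:
            if self.family == Family.BAYESIAN:
                params.append("mu_late")
            params.append("sigma_late")
        return tuple(params)

    def k_params(self, regime: str = "short") -> int:
        return len(self.free_parameters(regime))


MODEL_IDS: dict[str, int] = {
    "flawless_bayes": 1,
    "imperfect_bayes": 2,
    "ignorant_bayes": 3,
    "imperfect_ignorant_bayes": 4,
    "max": 5,
    "min_dev": 6,
    "minkowski": 7,
    "mean": 8,
    "variance": 9,
    "imperfect_max": 10,
    "imperfect_min_dev": 11,
    "imperfect_minkowski": 12,
    "imperfect_mean": 13,
    "imperfect_variance": 14,
}
MODEL_NAMES: dict[int, str] = {v: k for k, v in MODEL_IDS.items()}
ALL_MODELS: tuple[str, ...] = tuple(MODEL_IDS) + ("sampling_bayes",)


def get_model(key: int | str) -> ObserverSpec:
    """Look up a model by numeric id (1-14) or by name."""
    if isinstance(key, (int, np.integer)):
        try:
            return ObserverSpec(MODEL_NAMES[int(key)])
        except KeyError:
            raise ConfigurationError(f"unknown model id {key}") from None
    if key not in ALL_MODELS:
        raise ConfigurationError(f"unknown model name {key!r}")
    return ObserverSpec(key)


@dataclass(frozen=True)
class ParamVector:
    """Flat parameter container; inactive fields are None (or unused).

    Units: sigma_* in degrees; mu_late/sigma_late on the decision-variable
    (log-posterior-ratio) scale for Bayesian models and on the heuristic
    statistic's scale otherwise; criterion in the heuristic statistic's
    units; lapse a probability; n_samples a positive integer.
    """

    sigma_low: float = 0.0
    sigma_high: float = 0.0
    lapse: float = 0.0
    mu_late: float | None = None
    sigma_late: float | None = None
    sigma_single: float | None = None
    criterion: float | None = None
    beta: float | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ConfigurationError("lapse must be in [0, 1]")
        for nm in ("sigma_low", "sigma_high", "sigma_late", "sigma_single"):
            v = getattr(self, nm)
            if v is not None and v < 0:
                raise ConfigurationError(f"{nm} must be >= 0")
        if self.beta is not None and self.beta <= 0:
            raise ConfigurationError("beta must be > 0")
        if self.n_samples is not None and self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")

    def require(self, spec: ObserverSpec, regime: str = "short") -> None:
        for nm in spec.free_parameters(regime):
            if getattr(self, nm) is None:
                raise ConfigurationError(
                    f"model {spec.name!r} requires parameter {nm!r}"
                )

    def updated(self, **kwargs) -> "ParamVector":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sigma_low", "sigma_high", "lapse", "mu_late", "sigma_late",
                "sigma_single", "criterion", "beta", "n_samples",
            )
        }


# ---------------------------------------------------------------------------
# Decision variables


def local_evidence(
    x_i: float | np.ndarray, sigma_i: float | np.ndarray, condition: Condition
) -> np.ndarray:
    """Per-item posterior evidence ratio for "target at this location".

    Values < 1 favor a distractor, > 1 a target, exactly 1 is equal evidence.
    """
    var = np.asarray(sigma_i, dtype=float) ** 2 + condition.sigma_external**2
    if np.any(var <= 0):
        raise ConfigurationError(
            "sigma_i and sigma_external cannot both be zero"
        )
    x_i = np.asarray(x_i, dtype=float)
    mu = condition.mu_target
    return np.exp(((x_i + mu) ** 2 - (x_i - mu) ** 2) / (2.0 * var))


def _log_local_evidence(x: np.ndarray, var: np.ndarray, mu: float) -> np.ndarray:
    return 2.0 * mu * x / var


def _log_mean_exp(v: np.ndarray) -> np.ndarray:
    """log((1/N) sum exp(v)) over the last axis, overflow-safe.

    Hand-rolled rather than scipy's logsumexp: the last axis is tiny (N=4)
    and this sits in the innermost loop of likelihood evaluation.
    """
    m = np.max(v, axis=-1, keepdims=True)
    out = m[..., 0] + np.log(np.mean(np.exp(v - m), axis=-1))
    return out


def bayes_decision_variable(
    x: np.ndarray, sigma: np.ndarray | float, condition: Condition
) -> np.ndarray:
    """Global log posterior ratio log((1/N) sum_i d_local(x_i)).

    ``x`` has shape (..., N); ``sigma`` broadcasts against it. Evaluated as
    an overflow-safe log-mean-exp of 2 mu x / (sigma^2 + sigma_ext^2).
    """
    x = np.asarray(x, dtype=float)
    var = np.asarray(sigma, dtype=float) ** 2 + condition.sigma_external**2
    # fully deterministic displays (sigma = sigma_external = 0): take the
    # limit of the rule, where any positive observation is conclusive
    var = np.maximum(var, 1e-18)
    log_dloc = _log_local_evidence(x, var, condition.mu_target)
    return _log_mean_exp(log_dloc)


def heuristic_statistic(
    name: str, x: np.ndarray, condition: Condition, beta: float | None = None
) -> np.ndarray:
    """Decision statistic of a heuristic model; ``x`` shape (..., N)."""
    x = np.asarray(x, dtype=float)
    mu = condition.mu_target
    if name == "max":
        return x.max(axis=-1)
    if name == "min_dev":
        return np.abs(x - mu).min(axis=-1)
    if name == "minkowski":
        if beta is None:
            raise ConfigurationError("minkowski model requires beta")
        return (np.abs(x - mu) ** beta).sum(axis=-1) ** (1.0 / beta)
    if name == "mean":
        return x.mean(axis=-1)
    if name == "variance":
        return x.var(axis=-1)  # population (1/N) convention
    raise ConfigurationError(f"unknown heuristic {name!r}")


def _effective_sigma(
    spec: ObserverSpec,
    reliability_high: np.ndarray,
    params: ParamVector,
    condition: Condition,
) -> np.ndarray | float:
    """Sensory SD the *observer model* assumes per item."""
    if condition.display_regime == "unlimited":
        return float(condition.fixed_sensory_sd)
    if spec.ignores_reliability:
        if params.sigma_single is None:
            raise ConfigurationError("ignorant Bayesian requires sigma_single")
        return float(params.sigma_single)
    return np.where(reliability_high, params.sigma_high, params.sigma_low)


def decision_variable(
    spec: ObserverSpec,
    x: np.ndarray,
    reliability_high: np.ndarray,
    params: ParamVector,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Decision variable of ``spec`` for observations ``x`` (shape (..., N)).

    For imperfect models, passing ``rng`` adds a draw of the late noise;
    ``rng=None`` returns the noise-free decision variable.
    """
    x = np.asarray(x, dtype=float)
    if spec.family in (Family.BAYESIAN, Family.SAMPLING):
        sigma = _effective_sigma(spec, reliability_high, params, condition)
        d = bayes_decision_variable(x, sigma, condition)
    else:
        d = heuristic_statistic(spec.base_name, x, condition, params.beta)
    if spec.imperfect and rng is not None:
        if params.sigma_late is None:
            raise ConfigurationError("imperfect model requires sigma_late")
        mu_late = params.mu_late if spec.family == Family.BAYESIAN else 0.0
        d = d + (mu_late or 0.0) + params.sigma_late * rng.standard_normal(
            np.shape(d)
        )
    return d


# ---------------------------------------------------------------------------
# Response probabilities


def _sampling_present_probability(p1: np.ndarray, n: int) -> np.ndarray:
    """P(more "present" than "absent" samples out of n Bernoulli(p1) draws);
    even-n ties are resolved by a fair coin."""
    p1 = np.asarray(p1, dtype=float)
    # P(X > floor(n/2)) covers both parities; sf is elementwise in p1
    p = binom.sf(n // 2, n, p1)
    if n % 2 == 0:
        p = p + 0.5 * binom.pmf(n // 2, n, p1)
    return p


def core_present_probability(
    spec: ObserverSpec,
    d0: np.ndarray,
    params: ParamVector,
) -> np.ndarray:
    """P("present" | noise-free decision variable), before lapse mixing.

    Late noise is integrated out analytically (Gaussian CDF); the sampling
    read-out uses the exact binomial tail.
    """
    d0 = np.asarray(d0, dtype=float)
    if spec.family == Family.SAMPLING:
        if params.n_samples is None:
            raise ConfigurationError("sampling model requires n_samples")
        p1 = 1.0 / (1.0 + np.exp(-d0))
        return _sampling_present_probability(p1, int(params.n_samples))

    threshold = 0.0 if spec.family == Family.BAYESIAN else params.criterion
    if threshold is None:
        raise ConfigurationError("heuristic model requires criterion")
    sign = -1.0 if spec.invert_direction else 1.0

    if spec.imperfect:
        sigma_late = params.sigma_late
        if sigma_late is None:
            raise ConfigurationError("imperfect model requires sigma_late")
        if sigma_late == 0:
            warnings.warn(
                "sigma_late = 0 for an imperfect model; using the "
                "deterministic rule",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            mu_late = params.mu_late if spec.family == Family.BAYESIAN else 0.0
            return norm.cdf(sign * (d0 + (mu_late or 0.0) - threshold) / sigma_late)
    return (sign * (d0 - threshold) > 0).astype(float)


def lapse_mix(p_core: np.ndarray, lapse: float) -> np.ndarray:
    """Mix a lapse (fair guess) into a core response probability."""
    return lapse / 2.0 + (1.0 - lapse) * np.asarray(p_core, dtype=float)


def response_probability_given_observations(
    spec: ObserverSpec,
    x: np.ndarray,
    reliability_high: np.ndarray,
    params: ParamVector,
    condition: Condition,
) -> np.ndarray:
    """P("target present" | observations x), lapse included."""
    d0 = decision_variable(spec, x, reliability_high, params, condition, rng=None)
    return lapse_mix(core_present_probability(spec, d0, params), params.lapse)


# ---------------------------------------------------------------------------
# Response simulation


def simulate_responses(
    spec: ObserverSpec,
    trialset: TrialSet,
    params: ParamVector,
    seed: int | None = None,
) -> TrialSet:
    """Simulate the observer's responses on every trial of ``trialset``.

    Draws sensory observations (with the condition's fixed SD in the
    unlimited regime, else the parameter vector's reliability-dependent SDs),
    late noise where applicable, the sampling read-out for the sampling
    model, and lapses; returns a copy of the trial set with responses filled.
    """
    rng = np.random.default_rng(seed)
    c = trialset.condition
    if c.display_regime == "unlimited":
        sd = float(c.fixed_sensory_sd)
        x = trialset.orientations + sd * rng.standard_normal(
            trialset.orientations.shape
        ) if sd > 0 else trialset.orientations.copy()
    else:
        params.require(spec, "short")
        sd = observation_sds(trialset, params.sigma_low, params.sigma_high)
        x = trialset.orientations + sd * rng.standard_normal(
            trialset.orientations.shape
        )

    if spec.family == Family.SAMPLING:
        d0 = decision_variable(
            spec, x, trialset.reliability_high, params, c, rng=None
        )
        p1 = 1.0 / (1.0 + np.exp(-d0))
        n = int(params.n_samples)
        wins = rng.binomial(n, p1)
        present = wins > n - wins
        ties = wins * 2 == n
        if np.any(ties):
            present = np.where(ties, rng.random(len(present)) < 0.5, present)
    else:
        d = decision_variable(
            spec, x, trialset.reliability_high, params, c, rng=rng
        )
        threshold = 0.0 if spec.family == Family.BAYESIAN else params.criterion
        sign = -1.0 if spec.invert_direction else 1.0
        present = sign * (d - threshold) > 0

    lapse_mask = rng.random(len(present)) < params.lapse
    guesses = rng.random(len(present)) < 0.5
    present = np.where(lapse_mask, guesses, present)
    return trialset.with_responses(present.astype(np.int8))
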