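"""Trial likelihoods, prior-constrained fitting, and cross-validation.

The probability of a recorded response on one trial requires marginalizing
the response probability over the unobserved sensory observations x given
the presented stimuli s. With short display times this is done by Monte
Carlo: ``n_mc`` draws of x per trial, with *common random numbers* (CRN) —
one fixed block of standard-normal draws reused at every parameter value —
so that the likelihood surface seen by the optimizer is deterministic and
smooth in the parameters. In the unlimited-display regime with the sensory
SD fixed to 0 the observations equal the stimuli and the likelihood is
evaluated in closed form with no Monte Carlo at all. Late (decision) noise
and the sampling read-out are always integrated analytically.

Fitting maximizes log-likelihood plus (optionally) log prior with a
multi-start derivative-free local optimizer (Nelder-Mead on a bounded
reparameterization). The priors implement the constrained regime for the
Bayesian models: log-normal priors on the sensory SDs centered on the
subject's discrimination-task estimates, and a Beta prior concentrating
the lapse rate near zero. The reported AIC always uses the pure
log-likelihood at the optimum (prior excluded), so constrained and
unconstrained fits are comparable on one scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .observers import (
    Family,
    ObserverSpec,
    ParamVector,
    core_present_probability,
    decision_variable,
    heuristic_statistic,
    lapse_mix,
)
from .task import Condition, TrialSet, observation_sds

P_FLOOR = 1e-6  # per-trial probability floor for numerical stability

#: Plausible parameter boxes used for optimizer starts and bounds.
SIGMA_BOX = (0.1, 30.0)
MU_LATE_BOX = (-5.0, 5.0)
SIGMA_LATE_BOX = (1e-3, 10.0)
BETA_BOX = (0.25, 10.0)
N_SAMPLES_GRID = (1, 2, 3, 5, 9, 17, 33, 65, 129, 257, 501)


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo settings for likelihood evaluation."""

    n_mc: int = 2000
    seed: int = 0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.n_mc < 100:
            raise ValueError("n_mc must be >= 100")


@dataclass(frozen=True)
class PriorSpec:
    """Parameter priors for the constrained fitting regime.

    sigma_low/sigma_high: Normal on log sigma, centered at the subject's
    discrimination-task estimates with SD ``log_spread`` (log-units).
    lapse: Beta(lapse_a, lapse_b), concentrating mass near zero (defaults
    give mean 0.04). Other parameters are unconstrained. By default the
    priors apply only to Bayesian-family models; ``apply_to_heuristics``
    extends the lapse constraint to heuristic models (the "constrained Max"
    variant).
    """

    sigma_low_loc: float
    sigma_high_loc: float
    log_spread: float = 0.25
    lapse_a: float = 1.0
    lapse_b: float = 24.0
    apply_to_heuristics: bool = False

    def applies_to(self, spec: ObserverSpec) -> bool:
        return spec.family != Family.HEURISTIC or self.apply_to_heuristics

    def log_density(self, spec: ObserverSpec, params: ParamVector, regime: str) -> float:
        if not self.applies_to(spec):
            return 0.0
        lp = 0.0
        if regime == "short" and spec.family != Family.HEURISTIC:
            for value, loc in (
                (params.sigma_low, self.sigma_low_loc),
                (params.sigma_high, self.sigma_high_loc),
            ):
                lp += norm.logpdf(
                    math.log(value), math.log(loc), self.log_spread
                )
        lp += beta_dist.logpdf(
            np.clip(params.lapse, 1e-12, 1 - 1e-12), self.lapse_a, self.lapse_b
        )
        return float(lp)


@dataclass(frozen=True)
class OptConfig:
    """Multi-start local-optimization settings."""

    n_starts: int = 10
    seed: int = 0
    max_fevals: int = 400
    xatol: float = 1e-3
    fatol: float = 1e-3


@dataclass
class FitResult:
    spec: ObserverSpec
    params_hat: ParamVector
    loglik: float  # at the optimum, prior excluded
    logpost: float
    k_params: int
    aic: float
    converged: bool
    n_starts: int
    seed: int

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.name,
            "model_id": self.spec.model_id,
            "loglik": self.loglik,
            "logpost": self.logpost,
            "k_params": self.k_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }
        d.update(self.params_hat.to_dict())
        return d


# ---------------------------------------------------------------------------
# Likelihood evaluation


class LikelihoodEvaluator:
    """Caches a trial set's arrays and CRN noise block for fast repeated
    likelihood evaluations at different parameter values."""

    def __init__(self, spec: ObserverSpec, trialset: TrialSet, mc: MCConfig):
        if not trialset.has_responses:
            raise ValueError("all trials must have responses")
        if len(trialset) == 0:
            raise ValueError("empty trial set")
        self.spec = spec
        self.trialset = trialset
        self.mc = mc
        self.condition = trialset.condition
        self.regime = self.condition.display_regime
        self.s = trialset.orientations
        self.rel = trialset.reliability_high
        self.resp = trialset.response.astype(bool)
        self._closed_form = (
            self.regime == "unlimited" and self.condition.fixed_sensory_sd == 0
        )
        if not self._closed_form and mc.common_random_numbers:
            rng = np.random.default_rng(mc.seed)
            self._eps = rng.standard_normal(
                (len(trialset), mc.n_mc, self.condition.n_items)
            )
        else:
            self._eps = None

    def response_probabilities(self, params: ParamVector) -> np.ndarray:
        """P(recorded response | s, params) per trial."""
        params.require(self.spec, self.regime)
        c = self.condition
        if self._closed_form:
            d0 = decision_variable(
                self.spec, self.s, self.rel, params, c, rng=None
            )
            p_present = core_present_probability(self.spec, d0, params)
        else:
            if c.display_regime == "unlimited":
                sd = np.full_like(self.s, float(c.fixed_sensory_sd))
            else:
                sd = observation_sds(
                    self.trialset, params.sigma_low, params.sigma_high
                )
            eps = self._eps
            if eps is None:
                rng = np.random.default_rng(self.mc.seed)
                eps = rng.standard_normal(
                    (len(self.trialset), self.mc.n_mc, c.n_items)
                )
            x = self.s[:, None, :] + sd[:, None, :] * eps
            d0 = decision_variable(
                self.spec, x, self.rel[:, None, :], params, c, rng=None
            )
            p_present = core_present_probability(self.spec, d0, params).mean(
                axis=1
            )
        p_present = lapse_mix(p_present, params.lapse)
        p = np.where(self.resp, p_present, 1.0 - p_present)
        return np.clip(p, P_FLOOR, 1.0)

    def loglik(self, params: ParamVector) -> float:
        return float(np.log(self.response_probabilities(params)).sum())


def trial_response_probability(
    spec: ObserverSpec,
    trial,
    params: ParamVector,
    condition: Condition,
    mc: MCConfig,
) -> float:
    """Marginal probability of one trial's recorded response."""
    if trial.response is None:
        raise ValueError("trial has no recorded response")
    ts = TrialSet(
        condition=condition,
        orientations=np.asarray(trial.orientations, dtype=float)[None, :],
        reliability_high=np.array(
            [[r == "high" for r in trial.reliability]]
        ),
        target_present=np.array([trial.target_present]),
        target_location=np.array(
            [trial.target_location if trial.target_location else -1]
        ),
        response=np.array([int(trial.response)], dtype=np.int8),
    )
    return float(LikelihoodEvaluator(spec, ts, mc).response_probabilities(params)[0])


def dataset_log_likelihood(
    spec: ObserverSpec,
    trialset: TrialSet,
    params: ParamVector,
    mc: MCConfig,
) -> float:
    """Summed log probability of the recorded responses."""
    return LikelihoodEvaluator(spec, trialset, mc).loglik(params)


# ---------------------------------------------------------------------------
# Fitting


def _criterion_box(spec: ObserverSpec, trialset: TrialSet) -> tuple[float, float]:
    """Plausible criterion range: the observed range of the heuristic
    statistic on the raw stimuli, widened by 25% of its span."""
    beta = 2.0 if spec.base_name == "minkowski" else None
    stat = heuristic_statistic(
        spec.base_name, trialset.orientations, trialset.condition, beta
    )
    lo, hi = float(stat.min()), float(stat.max())
    pad = 0.25 * max(hi - lo, 1e-6)
    return lo - pad, hi + pad


def _param_boxes(
    spec: ObserverSpec, trialset: TrialSet, constrained: bool
) -> dict[str, tuple[float, float]]:
    lapse_hi = 0.5 if constrained else 1.0
    boxes: dict[str, tuple[float, float]] = {}
    for name in spec.free_parameters(trialset.condition.display_regime):
        if name in ("sigma_low", "sigma_high", "sigma_single"):
            boxes[name] = SIGMA_BOX
        elif name == "lapse":
            boxes[name] = (1e-6, lapse_hi)
        elif name == "mu_late":
            boxes[name] = MU_LATE_BOX
        elif name == "sigma_late":
            boxes[name] = SIGMA_LATE_BOX
        elif name == "beta":
            boxes[name] = BETA_BOX
        elif name == "criterion":
            boxes[name] = _criterion_box(spec, trialset)
        elif name == "n_samples":
            continue  # handled by discrete search
        else:  # pragma: no cover
            raise AssertionError(name)
    return boxes


_LOG_SCALE = {"sigma_low", "sigma_high", "sigma_single", "sigma_late", "beta"}


def _to_z(name: str, value: float, box: tuple[float, float]) -> float:
    lo, hi = box
    if name in _LOG_SCALE:
        lo, hi = math.log(lo), math.log(hi)
        value = math.log(value)
    frac = np.clip((value - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return float(logit(frac))


def _from_z(name: str, z: float, box: tuple[float, float]) -> float:
    lo, hi = box
    if name in _LOG_SCALE:
        lo, hi = math.log(lo), math.log(hi)
        return float(math.exp(lo + (hi - lo) * expit(z)))
    return float(lo + (hi - lo) * expit(z))


def _draw_start(
    names: Sequence[str],
    boxes: dict[str, tuple[float, float]],
    priors: PriorSpec | None,
    spec: ObserverSpec,
    regime: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    start: dict[str, float] = {}
    for nm in names:
        lo, hi = boxes[nm]
        if (
            priors is not None
            and priors.applies_to(spec)
            and nm in ("sigma_low", "sigma_high")
            and regime == "short"
        ):
            loc = priors.sigma_low_loc if nm == "sigma_low" else priors.sigma_high_loc
            v = float(
                np.clip(
                    math.exp(
                        math.log(loc) + priors.log_spread * rng.standard_normal()
                    ),
                    lo,
                    hi,
                )
            )
        elif nm == "lapse":
            v = float(rng.uniform(lo, min(hi, 0.2)))
        elif nm in _LOG_SCALE:
            v = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        else:
            v = float(rng.uniform(lo, hi))
        start[nm] = v
    return start


def _fit_continuous(
    evaluator: LikelihoodEvaluator,
    names: Sequence[str],
    boxes: dict[str, tuple[float, float]],
    priors: PriorSpec | None,
    opt: OptConfig,
    fixed: dict[str, float | int] | None = None,
) -> tuple[ParamVector, float, bool]:
    """Best-of-n-starts Nelder-Mead MAP fit over the named parameters."""
    spec = evaluator.spec
    regime = evaluator.regime
    fixed = fixed or {}
    rng = np.random.default_rng(opt.seed)

    def make_params(values: dict[str, float]) -> ParamVector:
        return ParamVector(**{**values, **fixed})

    def neg_logpost(zvec: np.ndarray) -> float:
        values = {
            nm: _from_z(nm, z, boxes[nm]) for nm, z in zip(names, zvec)
        }
        params = make_params(values)
        lp = evaluator.loglik(params)
        if priors is not None:
            lp += priors.log_density(spec, params, regime)
        return -lp

    best: tuple[float, np.ndarray] | None = None
    any_converged = False
    for _ in range(opt.n_starts):
        start = _draw_start(names, boxes, priors, spec, regime, rng)
        z0 = np.array([_to_z(nm, start[nm], boxes[nm]) for nm in names])
        res = minimize(
            neg_logpost,
            z0,
            method="Nelder-Mead",
            options={
                "maxfev": opt.max_fevals,
                "xatol": opt.xatol,
                "fatol": opt.fatol,
            },
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    assert best is not None
    values = {nm: _from_z(nm, z, boxes[nm]) for nm, z in zip(names, best[1])}
    return make_params(values), -best[0], any_converged


def fit_model(
    spec: ObserverSpec,
    trialset: TrialSet,
    priors: PriorSpec | None = None,
    mc: MCConfig | None = None,
    opt: OptConfig | None = None,
) -> FitResult:
    """Maximum-likelihood / MAP fit of one model to one trial set.

    Maximizes log-likelihood plus log prior (pure ML when ``priors`` is
    None). The sampling model's integer sample count is fitted by discrete
    search over a log-spaced grid, optimizing the continuous parameters at
    each grid point. Returns the best of ``opt.n_starts`` restarts.
    """
    mc = mc or MCConfig()
    opt = opt or OptConfig()
    evaluator = LikelihoodEvaluator(spec, trialset, mc)
    regime = trialset.condition.display_regime
    constrained = priors is not None and priors.applies_to(spec)
    boxes = _param_boxes(spec, trialset, constrained)
    names = [
        nm for nm in spec.free_parameters(regime) if nm != "n_samples"
    ]

    if spec.family == Family.SAMPLING:
        best: tuple[float, ParamVector, bool] | None = None
        for n in N_SAMPLES_GRID:
            params, lp, conv = _fit_continuous(
                evaluator, names, boxes, priors, opt, fixed={"n_samples": n}
            )
            if best is None or lp > best[0]:
                best = (lp, params, conv)
        assert best is not None
        logpost, params_hat, converged = best
    else:
        params_hat, logpost, converged = _fit_continuous(
            evaluator, names, boxes, priors, opt
        )

    loglik = evaluator.loglik(params_hat)
    k = spec.k_params(regime)
    return FitResult(
        spec=spec,
        params_hat=params_hat,
        loglik=loglik,
        logpost=logpost,
        k_params=k,
        aic=2.0 * k - 2.0 * loglik,
        converged=converged,
        n_starts=opt.n_starts,
        seed=opt.seed,
    )


def cross_validated_loglik(
    spec: ObserverSpec,
    trialset: TrialSet,
    k: int = 5,
    priors: PriorSpec | None = None,
    mc: MCConfig | None = None,
    opt: OptConfig | None = None,
    seed: int = 0,
) -> float:
    """Summed held-out log-likelihood over a random k-fold partition.

    Each fold is held out once; the model is fitted to the remaining
    trials and the held-out trials are scored at the fitted parameters.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(trialset)
    if n < k:
        raise ValueError("trial set smaller than number of folds")
    mc = mc or MCConfig()
    opt = opt or OptConfig()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    total = 0.0
    for i, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            raise ValueError("empty cross-validation fold")
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train, test = trialset.subset(~mask), trialset.subset(mask)
        fit = fit_model(
            spec,
            train,
            priors=priors,
            mc=mc,
            opt=OptConfig(
                n_starts=opt.n_starts,
                seed=opt.seed + i,
                max_fevals=opt.max_fevals,
                xatol=opt.xatol,
                fatol=opt.fatol,
            ),
        )
        total += dataset_log_likelihood(spec, test, fit.params_hat, mc)
    return total
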