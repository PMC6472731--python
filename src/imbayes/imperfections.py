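"""Computational-imperfection simulations on the optimal decision variable.

Four specific imperfections are injected into the flawless Bayesian
observer and the induced decision-variable error Δd(x) = d_imperfect(x) -
d_flawless(x) is characterized on trials drawn from the task's generative
model (by default the 10%-external-uncertainty condition):

- ``local_dv_noise``: multiplicative log-normal noise on each local
  evidence value before averaging (Gaussian noise with SD ``magnitude`` on
  the log-evidence scale, preserving positivity);
- ``overestimated_sigma_external``: the observer believes
  sigma_external is ``magnitude`` times its true value;
- ``overestimated_sensory_sigmas``: the observer believes both sensory
  noise SDs are ``magnitude`` times their true values;
- ``trialwise_sigma_noise``: item-to-item and trial-to-trial log-normal
  jitter (SD ``magnitude`` log-units) on the sensory SDs the observer
  assumes.

A Gaussian is fitted to the Δd sample by moments; the accuracy cost of the
imperfection is the flawless accuracy minus the imperfect accuracy on the
same trials. The key qualitative facts are that all four error
distributions are roughly Gaussian and that the overestimation kinds have a
nonzero mean — a computational *bias* indistinguishable from a response
bias, which is why a general late-noise term Normal(mu_late, sigma_late)
can stand in for any of them.

The injected magnitudes are modeling choices (config-overridable), so the
summaries here are descriptive; no published error percentages are targeted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .task import Condition, ConfigurationError, generate_dataset, observation_sds

KINDS = (
    "local_dv_noise",
    "overestimated_sigma_external",
    "overestimated_sensory_sigmas",
    "trialwise_sigma_noise",
)

#: Default injected magnitudes (noise SDs in log-units; factors > 1).
DEFAULT_MAGNITUDES = {
    "local_dv_noise": 0.5,
    "overestimated_sigma_external": 1.5,
    "overestimated_sensory_sigmas": 1.5,
    "trialwise_sigma_noise": 0.3,
}


@dataclass(frozen=True)
class ImperfectionKind:
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown imperfection kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ConfigurationError("magnitude must be > 0")
        if self.kind.startswith("overestimated") and self.magnitude <= 1:
            raise ConfigurationError("overestimation factor must be > 1")


@dataclass
class DeltaDSummary:
    mean: float
    sd: float
    accuracy_loss: float  # percentage points
    n_trials: int
    skewness: float
    excess_kurtosis: float
    tv_distance: float


def _decision_from_log_local(log_dloc: np.ndarray) -> np.ndarray:
    return logsumexp(log_dloc, axis=-1) - np.log(log_dloc.shape[-1])


def simulate_delta_d(
    imperfections: ImperfectionKind | Sequence[ImperfectionKind],
    condition: Condition,
    sigma_low: float,
    sigma_high: float,
    n_trials: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, DeltaDSummary]:
    """Simulate Δd(x) for one imperfection or a combination.

    Each trial draws (s, x) from the generative model; the same x feeds the
    flawless decision rule and the imperfect variant. Returns the Δd sample
    and a moment-fit summary including the accuracy cost.
    """
    if isinstance(imperfections, ImperfectionKind):
        imperfections = [imperfections]
    kinds = {imp.kind: imp.magnitude for imp in imperfections}
    if len(kinds) != len(imperfections):
        raise ConfigurationError("duplicate imperfection kinds")

    rng = np.random.default_rng(seed)
    ts = generate_dataset(condition, n_trials, seed=seed)
    true_sd = observation_sds(ts, sigma_low, sigma_high)
    x = ts.orientations + true_sd * rng.standard_normal(ts.orientations.shape)

    mu = condition.mu_target
    var_true = true_sd**2 + condition.sigma_external**2
    d_flawless = _decision_from_log_local(2.0 * mu * x / var_true)

    # believed quantities under the imperfection(s)
    sd_believed = true_sd.copy()
    sig_ext_believed = condition.sigma_external
    if "overestimated_sensory_sigmas" in kinds:
        sd_believed = sd_believed * kinds["overestimated_sensory_sigmas"]
    if "trialwise_sigma_noise" in kinds:
        sd_believed = sd_believed * np.exp(
            kinds["trialwise_sigma_noise"]
            * rng.standard_normal(sd_believed.shape)
        )
    if "overestimated_sigma_external" in kinds:
        sig_ext_believed = sig_ext_believed * kinds["overestimated_sigma_external"]
    var_believed = sd_believed**2 + sig_ext_believed**2
    log_dloc = 2.0 * mu * x / var_believed
    if "local_dv_noise" in kinds:
        log_dloc = log_dloc + kinds["local_dv_noise"] * rng.standard_normal(
            log_dloc.shape
        )
    d_imp = _decision_from_log_local(log_dloc)

    delta = d_imp - d_flawless
    acc_flawless = np.mean((d_flawless > 0) == ts.target_present)
    acc_imp = np.mean((d_imp > 0) == ts.target_present)
    g = gaussianity_report(delta)
    summary = DeltaDSummary(
        mean=float(delta.mean()),
        sd=float(delta.std()),
        accuracy_loss=float(100.0 * (acc_flawless - acc_imp)),
        n_trials=n_trials,
        skewness=g["skewness"],
        excess_kurtosis=g["excess_kurtosis"],
        tv_distance=g["tv_distance"],
    )
    return delta, summary


def gaussianity_report(sample: np.ndarray, n_bins: int = 100) -> dict[str, float]:
    """Descriptive Gaussianity diagnostics for a Δd sample.

    Reports sample skewness, excess kurtosis, and the total-variation
    distance between the sample histogram and the moment-matched Gaussian.
    Purely descriptive — the Gaussian-approximation claim is qualitative.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 10_000:
        raise ValueError("need at least 1e4 samples for stable diagnostics")
    m, sd = sample.mean(), sample.std()
    z = (sample - m) / sd if sd > 0 else sample * 0.0
    skew = float(np.mean(z**3))
    kurt = float(np.mean(z**4) - 3.0)
    lo, hi = np.quantile(sample, [0.0005, 0.9995])
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(sample, bins=edges)
    emp = hist / sample.size
    cdf = norm.cdf(edges, m, sd)
    gauss = np.diff(cdf)
    # include mass outside the binned range in both measures
    tv = 0.5 * (
        np.abs(emp - gauss).sum()
        + abs((1 - emp.sum()) - (1 - gauss.sum()))
    )
    return {
        "skewness": skew,
        "excess_kurtosis": kurt,
        "tv_distance": float(tv),
    }
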