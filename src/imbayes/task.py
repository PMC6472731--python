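"""Domain types and the generative model of the visual-search detection task.

The task: four oriented ellipses are shown at the cardinal locations. On half
of the trials one of them is a target (mean tilt ``+mu_target`` degrees,
clockwise-positive, vertical = 0) and the rest are distractors (mean tilt
``-mu_target``); on the other half all four are distractors. Orientations are
drawn from Gaussians with SD ``sigma_external`` ("external uncertainty";
``sigma_external = 0`` degenerates to fixed tilts of exactly ``±mu_target``).
Each stimulus is rendered at one of two reliability levels; the number of
high-reliability stimuli per display is uniform on {0, ..., 4} and the labels
are randomly permuted over locations. The observer sees each orientation
corrupted by zero-mean Gaussian sensory noise whose SD depends on the
stimulus's reliability label.

Orientations are plain (non-circular) degrees: the noise levels in play are
small enough that wrapping is irrelevant, so a Gaussian noise model is used
throughout.

Trial sets are stored column-wise (NumPy arrays) for speed; :class:`Trial`
objects are views for per-trial access.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

N_ITEMS = 4

#: Fixed mapping of location indices 1..4 to compass labels (models are
#: location-symmetric; the order is arbitrary but fixed for I/O readability).
LOCATION_LABELS = ("north", "east", "south", "west")


class ConfigurationError(ValueError):
    """Raised for invalid task/condition configuration."""


@dataclass(frozen=True)
class Condition:
    """One experimental cell of the search task.

    Parameters
    ----------
    display_regime:
        ``"short"`` (brief display, reliability-dependent sensory noise is a
        free quantity of the observer) or ``"unlimited"`` (display stays until
        response; sensory noise fixed at ``fixed_sensory_sd``).
    mu_target:
        Mean target tilt in degrees (> 0). Distractor mean is ``-mu_target``.
    sigma_external:
        SD in degrees of the target/distractor orientation distributions.
    n_items:
        Set size; the task uses 4.
    fixed_sensory_sd:
        Required in the unlimited regime (0 or an empirically calibrated
        value such as 0.875 degrees); must be absent in the short regime.
    """

    display_regime: Literal["short", "unlimited"]
    mu_target: float
    sigma_external: float = 0.0
    n_items: int = N_ITEMS
    fixed_sensory_sd: float | None = None

    def __post_init__(self) -> None:
        if self.display_regime not in ("short", "unlimited"):
            raise ConfigurationError(
                f"unknown display regime {self.display_regime!r}"
            )
        if not self.mu_target > 0:
            raise ConfigurationError("mu_target must be > 0")
        if self.sigma_external < 0:
            raise ConfigurationError("sigma_external must be >= 0")
        if self.n_items != N_ITEMS:
            raise ConfigurationError(f"n_items is fixed at {N_ITEMS}")
        if (self.display_regime == "unlimited") != (
            self.fixed_sensory_sd is not None
        ):
            raise ConfigurationError(
                "fixed_sensory_sd must be given exactly in the unlimited regime"
            )
        if self.fixed_sensory_sd is not None and self.fixed_sensory_sd < 0:
            raise ConfigurationError("fixed_sensory_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "display_regime": self.display_regime,
            "mu_target": self.mu_target,
            "sigma_external": self.sigma_external,
            "fixed_sensory_sd": self.fixed_sensory_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        return cls(
            display_regime=d["display_regime"],
            mu_target=float(d["mu_target"]),
            sigma_external=float(d["sigma_external"]),
            fixed_sensory_sd=(
                None
                if d.get("fixed_sensory_sd") is None
                else float(d["fixed_sensory_sd"])
            ),
        )


@dataclass
class Trial:
    """A single search trial (ground truth plus optional behavior)."""

    target_present: bool
    target_location: int | None  # 1..N, present iff target_present
    orientations: np.ndarray  # (N,) degrees
    reliability: tuple[str, ...]  # "low"/"high" per location
    response: bool | None = None
    observations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.target_present != (self.target_location is not None):
            raise ConfigurationError(
                "target_location must be present iff target_present"
            )
        if len(self.orientations) != len(self.reliability):
            raise ConfigurationError("orientations/reliability length mismatch")


@dataclass
class TrialSet:
    """Column-wise container for a batch of trials sharing one condition.

    ``target_location`` uses -1 for "no target"; ``response`` uses -1 for
    "no response recorded". ``reliability_high`` is a boolean mask.
    """

    condition: Condition
    orientations: np.ndarray  # (n, N) float
    reliability_high: np.ndarray  # (n, N) bool
    target_present: np.ndarray  # (n,) bool
    target_location: np.ndarray  # (n,) int, 1..N or -1
    response: np.ndarray | None = None  # (n,) int8: 0/1, -1 = absent
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.target_present)
        if self.orientations.shape != (n, self.condition.n_items):
            raise ConfigurationError("orientations shape mismatch")
        if self.reliability_high.shape != self.orientations.shape:
            raise ConfigurationError("reliability shape mismatch")

    def __len__(self) -> int:
        return len(self.target_present)

    @property
    def high_counts(self) -> np.ndarray:
        return self.reliability_high.sum(axis=1)

    @property
    def has_responses(self) -> bool:
        return self.response is not None and bool(np.all(self.response >= 0))

    def trials(self) -> Iterator[Trial]:
        for i in range(len(self)):
            loc = int(self.target_location[i])
            resp = None
            if self.response is not None and self.response[i] >= 0:
                resp = bool(self.response[i])
            yield Trial(
                target_present=bool(self.target_present[i]),
                target_location=loc if loc > 0 else None,
                orientations=self.orientations[i],
                reliability=tuple(
                    "high" if h else "low" for h in self.reliability_high[i]
                ),
                response=resp,
            )

    def subset(self, mask: np.ndarray) -> "TrialSet":
        return TrialSet(
            condition=self.condition,
            orientations=self.orientations[mask],
            reliability_high=self.reliability_high[mask],
            target_present=self.target_present[mask],
            target_location=self.target_location[mask],
            response=None if self.response is None else self.response[mask],
            seed=self.seed,
        )

    def with_responses(self, response: np.ndarray) -> "TrialSet":
        out = TrialSet(
            condition=self.condition,
            orientations=self.orientations,
            reliability_high=self.reliability_high,
            target_present=self.target_present,
            target_location=self.target_location,
            response=np.asarray(response, dtype=np.int8),
            seed=self.seed,
        )
        return out


@dataclass(frozen=True)
class DiscriminationTrial:
    """One trial of the single-stimulus tilt discrimination task."""

    orientation: float
    reliability: str  # "low" / "high"
    response_cw: bool


# ---------------------------------------------------------------------------
# Sampling


def _sample_reliability(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, N) boolean mask; high-count uniform on {0..N}, permuted per trial."""
    counts = rng.integers(0, N_ITEMS + 1, size=n)
    # row i has counts[i] True values in random positions
    u = rng.random((n, N_ITEMS))
    order = np.argsort(u, axis=1)
    mask = order < counts[:, None]
    return mask


def generate_dataset(
    condition: Condition, n_trials: int, seed: int | None = None
) -> TrialSet:
    """Draw ``n_trials`` search trials from the task's generative model.

    Target present on half the trials (Bernoulli 1/2); on present trials one
    uniformly chosen location holds a draw from Normal(+mu_target,
    sigma_external) and the rest from Normal(-mu_target, sigma_external);
    on absent trials all locations are distractor draws. Reliability labels:
    high-count uniform on {0..4}, randomly placed. Reproducible given seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    c = condition
    present = rng.random(n_trials) < 0.5
    location = np.where(
        present, rng.integers(1, c.n_items + 1, size=n_trials), -1
    )
    s = -c.mu_target + c.sigma_external * rng.standard_normal(
        (n_trials, c.n_items)
    )
    if present.any():
        rows = np.nonzero(present)[0]
        cols = location[rows] - 1
        s[rows, cols] = c.mu_target + c.sigma_external * rng.standard_normal(
            len(rows)
        )
    rel = _sample_reliability(n_trials, rng)
    return TrialSet(
        condition=c,
        orientations=s,
        reliability_high=rel,
        target_present=present,
        target_location=location,
        seed=seed,
    )


def sample_trial(
    condition: Condition,
    rng: np.random.Generator,
    high_count_rule: str = "uniform",
) -> Trial:
    """Draw one trial. ``high_count_rule`` currently only supports the task's
    uniform-on-{0..4} rule."""
    if high_count_rule != "uniform":
        raise ConfigurationError(f"unknown high_count_rule {high_count_rule!r}")
    seed = int(rng.integers(0, 2**31))
    ts = generate_dataset(condition, 1, seed=seed)
    return next(ts.trials())


def sample_observations(
    trial: Trial,
    sigma_low: float,
    sigma_high: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Corrupt a trial's orientations with reliability-dependent Gaussian
    noise: ``x_i = s_i + Normal(0, sigma_label(i))``."""
    if sigma_low < 0 or sigma_high < 0:
        raise ValueError("noise SDs must be >= 0")
    sd = np.where(
        np.array([r == "high" for r in trial.reliability]),
        sigma_high,
        sigma_low,
    )
    return np.asarray(trial.orientations, dtype=float) + sd * rng.standard_normal(
        len(trial.orientations)
    )


def observation_sds(trialset: TrialSet, sigma_low: float, sigma_high: float) -> np.ndarray:
    """Per-location sensory noise SD array, (n, N)."""
    return np.where(trialset.reliability_high, sigma_high, sigma_low)


def popout_filter(trialset: TrialSet) -> TrialSet:
    """Drop trials in which a single stimulus's reliability differs from all
    others (high-reliability count 1 or 3); keeps counts {0, 2, 4}, which is
    60% of the data under the uniform high-count rule."""
    keep = np.isin(trialset.high_counts, (0, 2, 4))
    return trialset.subset(keep)


# ---------------------------------------------------------------------------
# Discrimination task


#: Predicted-accuracy band used by the adaptive placement rule.
ADAPTIVE_ACC_RANGE = (0.55, 0.95)


def _fit_running_sigma(orientations: np.ndarray, responses: np.ndarray) -> float | None:
    """1-D ML fit of P(cw | s) = Phi(s / sigma) on the data so far.

    Returns None when the fit is degenerate (responses carry no usable
    gradient, e.g. all identical).
    """
    from scipy.optimize import minimize_scalar

    if len(set(responses.tolist())) < 2:
        return None

    y = responses.astype(float)

    def nll(log_sigma: float) -> float:
        p = norm.cdf(orientations / np.exp(log_sigma))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    res = minimize_scalar(nll, bounds=(np.log(0.05), np.log(50.0)), method="bounded")
    if not res.success:
        return None
    return float(np.exp(res.x))


def simulate_discrimination_session(
    true_sigma_low: float,
    true_sigma_high: float,
    n_trials: int = 500,
    seed: int | None = None,
) -> list[DiscriminationTrial]:
    """Simulate an adaptive tilt-discrimination session.

    The first 20 trials draw orientations uniformly on [-5, +5] degrees.
    From trial 21 on, a cumulative-Gaussian psychometric function is refit
    per reliability after every trial, and the next orientation is drawn
    uniformly (in orientation) from the symmetric domain where the running
    fit predicts 55-95% correct. Responses are simulated as "clockwise" with
    probability Phi(s / sigma_reliability). A degenerate running fit falls
    back to the uniform rule.
    """
    if n_trials < 21:
        raise ValueError("n_trials must be >= 21")
    if true_sigma_low < 0 or true_sigma_high < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (norm.ppf(a) for a in ADAPTIVE_ACC_RANGE)

    trials: list[DiscriminationTrial] = []
    data: dict[str, list[tuple[float, bool]]] = {"low": [], "high": []}
    true_sigma = {"low": true_sigma_low, "high": true_sigma_high}

    for t in range(n_trials):
        rel = "high" if rng.random() < 0.5 else "low"
        sigma_fit = None
        if t >= 20 and len(data[rel]) >= 2:
            arr = np.array(data[rel])
            sigma_fit = _fit_running_sigma(arr[:, 0], arr[:, 1].astype(bool))
        if sigma_fit is None:
            s = rng.uniform(-5.0, 5.0)
        else:
            lo, hi = sigma_fit * lo_q, sigma_fit * hi_q
            mag = rng.uniform(lo, hi)
            s = mag if rng.random() < 0.5 else -mag
        sig = true_sigma[rel]
        if sig == 0:
            resp = s > 0
        else:
            resp = rng.random() < norm.cdf(s / sig)
        trials.append(DiscriminationTrial(float(s), rel, bool(resp)))
        data[rel].append((float(s), bool(resp)))
    return trials


# ---------------------------------------------------------------------------
# I/O


def trialset_to_frame(ts: TrialSet) -> pd.DataFrame:
    rows = {
        "trial_index": np.arange(len(ts)),
        "target_present": ts.target_present.astype(int),
        "target_location": [
            loc if loc > 0 else pd.NA for loc in ts.target_location
        ],
    }
    for j in range(ts.condition.n_items):
        rows[f"s{j + 1}"] = ts.orientations[:, j]
    for j in range(ts.condition.n_items):
        rows[f"rel{j + 1}"] = np.where(ts.reliability_high[:, j], "high", "low")
    if ts.response is not None:
        rows["response"] = [r if r >= 0 else pd.NA for r in ts.response]
    else:
        rows["response"] = pd.NA
    return pd.DataFrame(rows)


def save_trialset(ts: TrialSet, csv_path: str | Path) -> None:
    """Write a trial set as CSV plus a sidecar JSON with condition metadata."""
    csv_path = Path(csv_path)
    trialset_to_frame(ts).to_csv(csv_path, index=False)
    meta = dict(ts.condition.to_dict(), seed=ts.seed)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trialset(csv_path: str | Path) -> TrialSet:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    seed = meta.pop("seed", None)
    condition = Condition.from_dict(meta)
    df = pd.read_csv(csv_path)
    n_items = condition.n_items
    s = df[[f"s{j + 1}" for j in range(n_items)]].to_numpy(dtype=float)
    rel = (
        df[[f"rel{j + 1}" for j in range(n_items)]].to_numpy() == "high"
    )
    loc = df["target_location"].fillna(-1).to_numpy(dtype=int)
    resp = None
    if "response" in df and not df["response"].isna().all():
        resp = df["response"].fillna(-1).to_numpy(dtype=np.int8)
    return TrialSet(
        condition=condition,
        orientations=s,
        reliability_high=rel,
        target_present=df["target_present"].to_numpy(dtype=bool),
        target_location=loc,
        response=resp,
        seed=seed,
    )
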