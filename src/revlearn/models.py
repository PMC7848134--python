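"""Generative learning models for the two-choice reversal task.

Three models are implemented, all paired with a softmax decision rule
p(A) = 1 / (1 + exp(-beta * (V_A - V_B))):

``rw``
    Anti-correlated Rescorla-Wagner: a single reward prediction error
    delta = R - V_chosen updates both options in opposite directions,
    V_chosen += alpha*delta, V_unchosen -= alpha*delta, so V_A + V_B is
    conserved exactly.

``hgf`` / ``hgf_fixed_theta``
    Three-level hierarchical Gaussian filter for binary outcomes. Level 1 is
    the binary state "option A is rewarded"; level 2 is its log-odds x2,
    evolving as a Gaussian random walk whose step variance exp(kappa*x3 + omega)
    couples it to the level-3 (phasic log-volatility) walk with step variance
    exp(theta). Belief updates are precision-weighted prediction errors; the
    weight sigma2 applied to the level-1 prediction error acts as a per-trial
    learning rate that adapts to inferred volatility. The two variants differ
    only in whether the meta-volatility theta is a free parameter or pinned at
    the group-level value -3.5066 (log scale).

Parameters
----------
beta >= 0   softmax inverse temperature (exploitation vs decision noise)
alpha       RW learning rate in [0, 1]
omega       tonic log-volatility of the level-2 walk
theta       log-variance of the level-3 walk (meta-volatility)
kappa       level-2/3 coupling gain, fixed to 1
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .task import TaskConfig, init_task, step_task

MODEL_IDS = ("rw", "hgf", "hgf_fixed_theta")

THETA_FIXED = -3.5066  # group-level meta-volatility, log scale

_S_EPS = 1e-8  # clamp for s_hat before forming the level-1 precision

# Starting beliefs, shared by simulation and fitting. mu3(0) = -4 places the
# effective tonic log-volatility kappa*mu3 + omega, at the study-scale omega
# values (~0.3-1.0), in the filter's stable and identifiable operating regime
# and yields average learning rates on the empirically observed scale.
MU2_0, SIGMA2_0, MU3_0, SIGMA3_0 = 0.0, 1.0, -4.0, 1.0
RW_V0 = (0.5, 0.5)

# Hard state clamps. The binary HGF is self-destabilising when confident
# beliefs meet large walk variances (sigma2 accumulates ~e^(mu3+omega) per
# trial); beyond these bounds the states carry no additional behavioural
# meaning, so excursions are truncated rather than allowed to overflow.
_MU2_CLAMP = 12.0
_MU3_CLAMP = (-12.0, 3.0)
_SIGMA_MAX = 50.0


class NumericalError(RuntimeError):
    """A belief update produced a non-finite value or a collapsed variance."""

    def __init__(self, message: str, trial_index: Optional[int] = None):
        if trial_index is not None:
            message = f"{message} (trial {trial_index})"
        super().__init__(message)
        self.trial_index = trial_index


def logistic(x):
    """Numerically stable sigmoid 1 / (1 + exp(-x)); accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    z = np.exp(-np.abs(x))  # always in (0, 1], no overflow
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))[()]


def softmax_prob(value_a: float, value_b: float, beta: float) -> float:
    """Probability of choosing option A given two values and inverse temperature."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(logistic(beta * (value_a - value_b)))


# ---------------------------------------------------------------- RW model

@dataclass(frozen=True)
class RWParams:
    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class RWState:
    v_a: float = RW_V0[0]
    v_b: float = RW_V0[1]


def rw_update(state: RWState, chosen: str, reward: int,
              alpha: float) -> tuple[RWState, float]:
    """Anti-correlated RW update; returns the new state and the RPE delta."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if chosen == "A":
        delta = reward - state.v_a
        new = RWState(state.v_a + alpha * delta, state.v_b - alpha * delta)
    elif chosen == "B":
        delta = reward - state.v_b
        new = RWState(state.v_a - alpha * delta, state.v_b + alpha * delta)
    else:
        raise ValueError(f"unknown option {chosen!r}")
    return new, float(delta)


# --------------------------------------------------------------- HGF model

@dataclass(frozen=True)
class HGFParams:
    omega: float
    beta: float
    theta: float = THETA_FIXED
    kappa: float = 1.0
    theta_fixed: bool = True

    def __post_init__(self):
        if self.kappa != 1.0:
            raise ValueError("kappa is fixed to 1 in this task formulation")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class HGFState:
    mu2: float = MU2_0
    sigma2: float = SIGMA2_0
    mu3: float = MU3_0
    sigma3: float = SIGMA3_0

    def __post_init__(self):
        if not (self.sigma2 > 0 and self.sigma3 > 0):
            raise ValueError("variances must be positive")


@dataclass
class TrialBeliefs:
    """Per-trial predictions and (after the update) errors and weights."""

    s_hat: float
    pi_hat_1: float
    pi_hat_2: float
    delta1: Optional[float] = None
    learning_rate: Optional[float] = None
    delta2: Optional[float] = None


def _hgf_step(mu2, sigma2, mu3, sigma3, u, omega, theta, kappa):
    """One HGF prediction+update step on scalars.

    Returns (mu2', sigma2', mu3', sigma3', s_hat, delta1, lr, delta2).
    Kept as plain-float arithmetic: it is the inner loop of every likelihood
    evaluation during fitting.
    """
    s_hat = 1.0 / (1.0 + math.exp(-mu2)) if mu2 > -700 else 0.0
    s_hat = min(max(s_hat, _S_EPS), 1.0 - _S_EPS)
    nu2 = math.exp(min(kappa * mu3 + omega, 30.0))  # level-2 walk variance
    pihat2 = 1.0 / (sigma2 + nu2)
    pihat1 = 1.0 / (s_hat * (1.0 - s_hat))

    delta1 = u - s_hat
    sigma2_new = pihat1 / (pihat2 * pihat1 + 1.0)
    mu2_new = mu2 + sigma2_new * delta1

    # level 3: volatility prediction error and precision-weighted update
    pihat3 = 1.0 / (sigma3 + math.exp(theta))
    w2 = nu2 * pihat2
    delta2 = (sigma2_new + (mu2_new - mu2) ** 2) * pihat2 - 1.0
    pi3 = pihat3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if not math.isfinite(pi3):
        raise NumericalError("level-3 precision collapsed")
    # The quadratic volatility correction can push pi3 <= 0 when w2 < 1/2
    # meets a large volatility surprise; floor it so the filter degrades
    # gracefully instead of aborting (states are clamped below anyway).
    pi3 = max(pi3, 0.05 * pihat3)
    mu3_new = mu3 + kappa / (2.0 * pi3) * w2 * delta2
    sigma3_new = 1.0 / pi3
    if not (math.isfinite(mu2_new) and math.isfinite(mu3_new)
            and sigma2_new > 0.0):
        raise NumericalError("non-finite belief update")
    lr = sigma2_new
    mu2_new = min(max(mu2_new, -_MU2_CLAMP), _MU2_CLAMP)
    mu3_new = min(max(mu3_new, _MU3_CLAMP[0]), _MU3_CLAMP[1])
    sigma2_new = min(sigma2_new, _SIGMA_MAX)
    sigma3_new = min(sigma3_new, _SIGMA_MAX)
    return (mu2_new, sigma2_new, mu3_new, sigma3_new,
            s_hat, delta1, lr, delta2)


def hgf_predict(state: HGFState, params: HGFParams) -> TrialBeliefs:
    """Prediction step: beliefs carried forward from the previous posterior."""
    if not all(map(math.isfinite, (state.mu2, state.sigma2,
                                   state.mu3, state.sigma3))):
        raise NumericalError("non-finite state")
    s_hat = float(logistic(state.mu2))
    s_hat = min(max(s_hat, _S_EPS), 1.0 - _S_EPS)
    nu2 = math.exp(params.kappa * state.mu3 + params.omega)
    return TrialBeliefs(
        s_hat=s_hat,
        pi_hat_1=1.0 / (s_hat * (1.0 - s_hat)),
        pi_hat_2=1.0 / (state.sigma2 + nu2),
    )


def hgf_update(state: HGFState, beliefs: TrialBeliefs, reward: int,
               params: HGFParams) -> HGFState:
    """Update step; fills delta1/learning_rate/delta2 into ``beliefs``."""
    (mu2, sigma2, mu3, sigma3, s_hat, d1, lr, d2) = _hgf_step(
        state.mu2, state.sigma2, state.mu3, state.sigma3,
        float(reward), params.omega, params.theta, params.kappa)
    beliefs.delta1 = d1
    beliefs.learning_rate = lr
    beliefs.delta2 = d2
    return HGFState(mu2, sigma2, mu3, sigma3)


def run_hgf_trajectory(outcomes: np.ndarray, missed: np.ndarray,
                       omega: float, theta: float = THETA_FIXED,
                       kappa: float = 1.0) -> dict[str, np.ndarray]:
    """Forward-filter a whole outcome sequence (outcome = "A rewarded?").

    Missed trials carry the previous beliefs forward without an update; their
    delta/learning-rate entries are NaN. Returns per-trial arrays of the
    *prediction* s_hat (the quantity fed to the softmax) plus the posterior
    trajectories.
    """
    n = len(outcomes)
    out = {k: np.empty(n) for k in
           ("s_hat", "mu2", "sigma2", "mu3", "sigma3",
            "delta1", "delta2", "learning_rate")}
    mu2, sigma2, mu3, sigma3 = MU2_0, SIGMA2_0, MU3_0, SIGMA3_0
    for t in range(n):
        s_hat = 1.0 / (1.0 + math.exp(-mu2)) if mu2 > -700 else 0.0
        out["s_hat"][t] = s_hat
        if missed[t]:
            out["delta1"][t] = out["delta2"][t] = np.nan
            out["learning_rate"][t] = np.nan
        else:
            try:
                (mu2, sigma2, mu3, sigma3, _, d1, lr, d2) = _hgf_step(
                    mu2, sigma2, mu3, sigma3, float(outcomes[t]),
                    omega, theta, kappa)
            except NumericalError as e:
                raise NumericalError(str(e), trial_index=t) from None
            out["delta1"][t], out["delta2"][t] = d1, d2
            out["learning_rate"][t] = lr
        out["mu2"][t], out["sigma2"][t] = mu2, sigma2
        out["mu3"][t], out["sigma3"][t] = mu3, sigma3
    return out


def run_rw_trajectory(chosen: np.ndarray, rewards: np.ndarray,
                      missed: np.ndarray, alpha: float) -> dict[str, np.ndarray]:
    """Forward pass of the anti-correlated RW model on an observed run.

    ``chosen`` holds "A"/"B" (ignored where missed); ``rewards`` is the
    chosen-option feedback. Returns per-trial *pre-update* values (the values
    the softmax acted on) and the RPE series.
    """
    n = len(chosen)
    out = {k: np.empty(n) for k in ("v_a", "v_b", "delta")}
    v_a, v_b = RW_V0
    for t in range(n):
        out["v_a"][t], out["v_b"][t] = v_a, v_b
        if missed[t]:
            out["delta"][t] = np.nan
            continue
        if chosen[t] == "A":
            d = rewards[t] - v_a
            v_a += alpha * d
            v_b -= alpha * d
        else:
            d = rewards[t] - v_b
            v_b += alpha * d
            v_a -= alpha * d
        out["delta"][t] = d
    return out


# ----------------------------------------------------------- agent simulation

def _outcome_a_frame(chosen: str, feedback: int) -> int:
    """Remap chosen-option feedback to the binary state "A was rewarded"."""
    return feedback if chosen == "A" else 1 - feedback


def simulate_agent(model: str, params, config: TaskConfig, seed,
                   subject_id: str = "sim", group: str = "",
                   condition: str = "control") -> pd.DataFrame:
    """Closed-loop simulation of one agent playing one run.

    predict -> softmax choice -> task feedback -> belief update, until the run
    terminates. Returns a trial log with belief columns appended (s_hat,
    delta1, mu2, sigma2, mu3, learning_rate for the HGF; v_a/v_b/delta under
    the same headers' RW analogues).
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    state = init_task(config, rng)

    rows = []
    if model == "rw":
        lstate = RWState()
    else:
        hmu2, hsig2, hmu3, hsig3 = MU2_0, SIGMA2_0, MU3_0, SIGMA3_0
        theta = params.theta

    while not state.terminated:
        if model == "rw":
            v_a, v_b = lstate.v_a, lstate.v_b
        else:
            s_hat = float(logistic(hmu2))
            v_a, v_b = s_hat, 1.0 - s_hat
        p_a = softmax_prob(v_a, v_b, params.beta)

        if config.miss_prob > 0 and rng.random() < config.miss_prob:
            record, state = step_task(state, None, config, rng)
            rows.append({**record.__dict__, "condition": condition,
                         "s_hat": v_a, "delta1": np.nan, "mu2": np.nan,
                         "sigma2": np.nan, "mu3": np.nan,
                         "learning_rate": np.nan})
            continue

        chosen = "A" if rng.random() < p_a else "B"
        record, state = step_task(state, chosen, config, rng)

        if model == "rw":
            lstate, delta = rw_update(lstate, chosen, record.feedback,
                                      params.alpha)
            beliefs = {"s_hat": v_a, "delta1": delta,
                       "mu2": lstate.v_a, "sigma2": np.nan, "mu3": np.nan,
                       "learning_rate": params.alpha}
        else:
            u = _outcome_a_frame(chosen, record.feedback)
            try:
                (hmu2, hsig2, hmu3, hsig3, sh, d1, lr, d2) = _hgf_step(
                    hmu2, hsig2, hmu3, hsig3, float(u),
                    params.omega, theta, params.kappa)
            except NumericalError as e:
                raise NumericalError(str(e),
                                     trial_index=record.trial_index) from None
            beliefs = {"s_hat": sh, "delta1": d1, "mu2": hmu2,
                       "sigma2": hsig2, "mu3": hmu3, "learning_rate": lr}
        rows.append({**record.__dict__, "condition": condition, **beliefs})

    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", subject_id)
    df.insert(1, "group", group)
    return df
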