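"""Single-run model fitting: MAP estimation and Laplace model evidence.

Each model is fit to one subject-run's observed choices by maximising the
log-joint (choice log-likelihood + log-prior) in a transformed parameter
space (log for beta, logit for alpha, identity for omega/theta), with
multiple jittered restarts of a bounded quasi-Newton optimiser. The
"log evidence" reported is a Laplace (Gaussian) approximation of the log
marginal likelihood at the MAP — the negative-free-energy-style quantity
random-effects BMS consumes.

Priors are weakly informative and centred near the study's group-level
parameter means; they are defined directly on the transformed coordinates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .models import (MODEL_IDS, THETA_FIXED, NumericalError,
                     run_hgf_trajectory, run_rw_trajectory)

_LOG_2PI = math.log(2.0 * math.pi)
_PENALTY = 1e10  # neg-log-joint assigned to numerically failed evaluations


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior on one transformed coordinate, with hard box bounds."""

    name: str
    transform: str            # identity | log | logit
    loc: float                # prior mean, transformed space
    scale: float              # prior SD, transformed space
    bounds: tuple[float, float]  # natural-space bounds

    def to_natural(self, z: float) -> float:
        if self.transform == "log":
            return math.exp(z)
        if self.transform == "logit":
            return 1.0 / (1.0 + math.exp(-z))
        return z

    def to_transformed(self, x: float) -> float:
        if self.transform == "log":
            return math.log(x)
        if self.transform == "logit":
            return math.log(x / (1.0 - x))
        return x

    @property
    def z_bounds(self) -> tuple[float, float]:
        lo, hi = self.bounds
        return (self.to_transformed(lo), self.to_transformed(hi))

    def log_pdf(self, z: float) -> float:
        r = (z - self.loc) / self.scale
        return -0.5 * (r * r + _LOG_2PI) - math.log(self.scale)


PriorSpec = tuple[ParamPrior, ...]

_BETA_PRIOR = ParamPrior("beta", "log", math.log(5.0), 1.0, (1e-3, 50.0))

DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "rw": (ParamPrior("alpha", "logit", 0.0, 1.5, (1e-3, 1 - 1e-3)),
           _BETA_PRIOR),
    "hgf": (ParamPrior("omega", "identity", 0.0, 2.0, (-10.0, 5.0)),
            ParamPrior("theta", "identity", -3.5, 1.0, (-10.0, 0.0)),
            _BETA_PRIOR),
    "hgf_fixed_theta": (ParamPrior("omega", "identity", 0.0, 2.0, (-10.0, 5.0)),
                        _BETA_PRIOR),
}


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    log_joint: float
    log_evidence: float
    converged: bool
    n_restarts: int
    at_bounds: list[str] = field(default_factory=list)
    trajectory: Optional[pd.DataFrame] = None
    mean_learning_rate: float = float("nan")


class FitFailure(RuntimeError):
    """All optimiser restarts failed; carries per-restart diagnostics."""

    def __init__(self, diagnostics):
        super().__init__(f"all restarts failed: {diagnostics}")
        self.diagnostics = diagnostics


def _observed_arrays(trial_log: pd.DataFrame):
    """Extract (outcome-in-A-frame, chosen, chosen-feedback, missed) arrays."""
    missed = trial_log["missed"].to_numpy(dtype=bool)
    chosen = trial_log["chosen"].astype(object).to_numpy()
    feedback = pd.to_numeric(trial_log["feedback"], errors="coerce") \
        .fillna(0).to_numpy(dtype=float)
    outcome_a = np.where(chosen == "A", feedback, 1.0 - feedback)
    outcome_a[missed] = 0.0  # placeholder; skipped by the filter
    return outcome_a, chosen, feedback, missed


def _log_softmax_choice(value_diff: np.ndarray, chose_a: np.ndarray,
                        beta: float) -> np.ndarray:
    """log p(observed choice) under p(A) = logistic(beta * value_diff)."""
    x = beta * value_diff
    signed = np.where(chose_a, x, -x)
    return -np.logaddexp(0.0, -signed)


def choice_log_likelihood(trial_log: pd.DataFrame, model: str,
                          params: dict[str, float]) -> float:
    """Sum of log choice probabilities over non-missed trials.

    Beliefs are generated by the model's own forward pass on the observed
    feedback sequence; missed trials contribute nothing and trigger no
    belief update.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    outcome_a, chosen, feedback, missed = _observed_arrays(trial_log)
    valid = ~missed
    if model == "rw":
        traj = run_rw_trajectory(chosen, feedback, missed, params["alpha"])
        value_diff = traj["v_a"] - traj["v_b"]
    else:
        theta = params.get("theta", THETA_FIXED)
        traj = run_hgf_trajectory(outcome_a, missed, params["omega"], theta)
        value_diff = 2.0 * traj["s_hat"] - 1.0  # V_A = s_hat, V_B = 1 - s_hat
    ll = _log_softmax_choice(value_diff[valid], (chosen == "A")[valid],
                             params["beta"])
    total = float(np.sum(ll))
    if not math.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise NumericalError("non-finite log-likelihood", trial_index=bad)
    return total


def _neg_log_joint(z: np.ndarray, trial_log, model, priors) -> float:
    params = {p.name: p.to_natural(zi) for p, zi in zip(priors, z)}
    try:
        ll = choice_log_likelihood(trial_log, model, params)
    except NumericalError:
        return _PENALTY
    lp = sum(p.log_pdf(zi) for p, zi in zip(priors, z))
    return -(ll + lp)


def _hessian_fd(f, z: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian; symmetrised."""
    d = len(z)
    h = np.empty((d, d))
    f0 = f(z)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = step
            if i == j:
                h[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / step ** 2
            else:
                h[i, j] = h[j, i] = (
                    f(z + ei + ej) - f(z + ei - ej)
                    - f(z - ei + ej) + f(z - ei - ej)) / (4 * step ** 2)
    return h


def _laplace_log_evidence(log_joint: float, hessian: np.ndarray) -> float:
    """log Z ~ log p(y, theta_MAP) + d/2 log 2pi - 1/2 log det H."""
    eigvals = np.linalg.eigvalsh(0.5 * (hessian + hessian.T))
    eigvals = np.clip(eigvals, 1e-6, None)  # guard flat/indefinite directions
    d = len(eigvals)
    return log_joint + 0.5 * d * _LOG_2PI - 0.5 * float(np.sum(np.log(eigvals)))


def fit_model(trial_log: pd.DataFrame, model: str,
              priors: Optional[PriorSpec] = None, n_restarts: int = 8,
              seed: int = 0, with_trajectory: bool = True) -> FitResult:
    """MAP-fit one model to one run; returns estimates, evidence, trajectory."""
    if priors is None:
        priors = DEFAULT_PRIORS[model]
    n_valid = int((~trial_log["missed"]).sum())
    if n_valid < 30:
        raise ValueError(f"need >= 30 valid trials, got {n_valid}")

    rng = np.random.default_rng(seed)
    z_bounds = [p.z_bounds for p in priors]
    z0_center = np.array([p.loc for p in priors])

    best = None
    diagnostics = []
    obj = lambda z: _neg_log_joint(z, trial_log, model, priors)
    for k in range(n_restarts):
        z0 = z0_center if k == 0 else z0_center + rng.normal(
            scale=[p.scale for p in priors])
        z0 = np.clip(z0, [b[0] for b in z_bounds], [b[1] for b in z_bounds])
        res = optimize.minimize(obj, z0, method="L-BFGS-B", bounds=z_bounds)
        diagnostics.append((k, res.success, float(res.fun)))
        if not math.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        if (best is None or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9
                    and np.linalg.norm(res.x) < np.linalg.norm(best.x))):
            best = res
    if best is None:
        raise FitFailure(diagnostics)

    z_opt = best.x
    log_joint = -float(best.fun)
    hess = _hessian_fd(obj, z_opt)
    log_evidence = _laplace_log_evidence(log_joint, hess)

    params = {p.name: p.to_natural(zi) for p, zi in zip(priors, z_opt)}
    at_bounds = [p.name for p, zi, (lo, hi) in zip(priors, z_opt, z_bounds)
                 if zi - lo < 1e-6 * max(1, abs(lo))
                 or hi - zi < 1e-6 * max(1, abs(hi))]

    result = FitResult(model=model, params=params, log_joint=log_joint,
                       log_evidence=log_evidence,
                       converged=bool(best.success)
                       and math.isfinite(log_evidence),
                       n_restarts=n_restarts, at_bounds=at_bounds)
    if with_trajectory:
        result.trajectory = _fit_trajectory(trial_log, model, params)
        lr = result.trajectory["learning_rate"].to_numpy()
        result.mean_learning_rate = float(np.nanmean(lr))
    return result


def _fit_trajectory(trial_log: pd.DataFrame, model: str,
                    params: dict[str, float]) -> pd.DataFrame:
    """Per-trial beliefs at the fitted parameters, indexed like the log."""
    outcome_a, chosen, feedback, missed = _observed_arrays(trial_log)
    if model == "rw":
        traj = run_rw_trajectory(chosen, feedback, missed, params["alpha"])
        lr = np.where(missed, np.nan, params["alpha"])
        return pd.DataFrame({
            "trial_index": trial_log["trial_index"].to_numpy(),
            "s_hat": traj["v_a"], "delta1": traj["delta"],
            "mu2": np.nan, "sigma2": np.nan, "mu3": np.nan,
            "learning_rate": lr})
    theta = params.get("theta", THETA_FIXED)
    traj = run_hgf_trajectory(outcome_a, missed, params["omega"], theta)
    return pd.DataFrame({
        "trial_index": trial_log["trial_index"].to_numpy(),
        "s_hat": traj["s_hat"], "delta1": traj["delta1"],
        "mu2": traj["mu2"], "sigma2": traj["sigma2"], "mu3": traj["mu3"],
        "learning_rate": traj["learning_rate"]})


def extract_learning_rates(fit: FitResult) -> tuple[pd.Series, float]:
    """Per-trial effective learning rate and its subject mean.

    For the HGF this is the precision weight sigma2 applied to each level-1
    prediction error; for the RW model it is the constant alpha (NaN on
    missed trials). The mean is over valid trials.
    """
    if fit.trajectory is None:
        raise ValueError("fit carries no trajectory")
    series = fit.trajectory["learning_rate"]
    return series, float(np.nanmean(series.to_numpy()))
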