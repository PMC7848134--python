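"""Random-effects Bayesian model selection across subjects.

Treats the model identity as a random effect: each subject's data may come
from a different model, with population model frequencies r ~ Dirichlet(alpha).
A variational update alternates subject-wise posterior model assignments
(from the log evidences plus digamma terms) with Dirichlet concentration
updates. Exceedance probabilities — the posterior probability that each model
is the most frequent in the population — are estimated by Monte-Carlo
sampling from the fitted Dirichlet.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma


@dataclass
class BMSResult:
    model_labels: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    n_mc_samples: int
    n_iterations: int


class BMSConvergenceError(RuntimeError):
    def __init__(self, trace):
        super().__init__(
            f"variational BMS did not converge in {len(trace)} iterations")
        self.trace = trace


def rfx_bms(log_evidence: np.ndarray, model_labels=None,
            prior_alpha: float = 1.0, n_mc_samples: int = 100_000,
            seed: int = 0, tol: float = 1e-4,
            max_iter: int = 500) -> BMSResult:
    """Variational random-effects BMS on a subjects x models evidence matrix."""
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 1 subject and >= 2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")
    n_sub, n_mod = lme.shape
    if model_labels is None:
        model_labels = tuple(f"m{k}" for k in range(n_mod))
    if prior_alpha < 1.0:
        raise ValueError("prior_alpha must be >= 1")

    alpha0 = np.full(n_mod, float(prior_alpha))
    alpha = alpha0.copy()
    trace = []
    for it in range(max_iter):
        ln_u = lme + digamma(alpha) - digamma(alpha.sum())
        ln_u -= ln_u.max(axis=1, keepdims=True)
        g = np.exp(ln_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        delta = float(np.max(np.abs(alpha_new - alpha)))
        trace.append(delta)
        alpha = alpha_new
        if delta < tol:
            break
    else:
        raise BMSConvergenceError(trace)

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc_samples)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=n_mod)
    return BMSResult(
        model_labels=tuple(model_labels),
        dirichlet_alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance_prob=wins / n_mc_samples,
        n_mc_samples=n_mc_samples,
        n_iterations=it + 1,
    )
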