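"""Observable error taxonomy and reversal-aligned trajectory summaries.

After each reversal, errors (choices of the previously reinforced target,
now incorrect) are split by whether they occur before or after the first
correct choice of the new target:

* perseverative — before the first correct choice (failure to shift);
* regressive — after it (failure to retain the new rule).

Errors in the initial acquisition block have no "previously reinforced
target" and are tallied separately. Missed trials are excluded everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ErrorCounts:
    n_valid_trials: int
    overall_errors: int
    perseverative: int
    regressive: int
    unclassified_first_block: int

    def __post_init__(self):
        parts = self.perseverative + self.regressive \
            + self.unclassified_first_block
        if parts != self.overall_errors:
            raise ValueError("error partition does not sum to overall")

    def _pct(self, k: int) -> float:
        return 100.0 * k / self.n_valid_trials if self.n_valid_trials else 0.0

    @property
    def overall_pct(self) -> float:
        return self._pct(self.overall_errors)

    @property
    def perseverative_pct(self) -> float:
        return self._pct(self.perseverative)

    @property
    def regressive_pct(self) -> float:
        return self._pct(self.regressive)

    @property
    def unclassified_pct(self) -> float:
        return self._pct(self.unclassified_first_block)


def classify_errors(trial_log: pd.DataFrame) -> ErrorCounts:
    """Partition one run's errors into the perseverative/regressive taxonomy."""
    if "block_index" not in trial_log.columns:
        raise ValueError("trial log lacks block structure")
    valid = trial_log.loc[~trial_log["missed"].astype(bool)]
    n_valid = len(valid)
    correct = valid["correct"].astype(bool).to_numpy()
    blocks = valid["block_index"].to_numpy()

    overall = int((~correct).sum())
    persev = regress = first_block = 0
    for b in np.unique(blocks):
        mask = blocks == b
        c = correct[mask]
        errs = ~c
        if b == 0:
            first_block += int(errs.sum())
            continue
        hits = np.flatnonzero(c)
        if len(hits) == 0:
            persev += int(errs.sum())
        else:
            first_hit = hits[0]
            persev += int(errs[:first_hit].sum())
            regress += int(errs[first_hit:].sum())
    return ErrorCounts(n_valid, overall, persev, regress, first_block)


def _reversal_points(run: pd.DataFrame) -> list[tuple[int, str]]:
    """(row position of the first trial of each post-reversal block,
    pre-reversal target) pairs for one run, in trial order."""
    blocks = run["block_index"].to_numpy()
    targets = run["target"].astype(object).to_numpy()
    out = []
    for b in np.unique(blocks):
        if b == 0:
            continue
        pos = int(np.flatnonzero(blocks == b)[0])
        prev_target = targets[np.flatnonzero(blocks == b - 1)[-1]]
        out.append((pos, prev_target))
    return out


def align_to_reversals(trial_log: pd.DataFrame,
                       window: tuple[int, int] = (-2, 5)) -> pd.DataFrame:
    """Average learning rate and value around reversals.

    ``trial_log`` must carry the belief columns ``learning_rate`` and
    ``s_hat`` (probability that option A is rewarded). The value curve is
    re-expressed as the probability assigned to the *pre-reversal* target so
    that A->B and B->A reversals average coherently (it decays from high to
    low as the agent relearns). Offset 0 is the first trial of the new block.
    Runs are pooled over (subject_id, condition) when those columns are
    present; offsets truncated at run boundaries contribute nothing.

    Returns a frame with columns offset, mean_learning_rate, mean_value, n.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    sum_lr = np.zeros(len(offsets))
    n_lr = np.zeros(len(offsets), dtype=int)
    sum_val = np.zeros(len(offsets))
    n_val = np.zeros(len(offsets), dtype=int)

    group_keys = [k for k in ("subject_id", "condition") if k in trial_log]
    runs = ([g for _, g in trial_log.groupby(group_keys, sort=False)]
            if group_keys else [trial_log])
    for run in runs:
        run = run.reset_index(drop=True)
        lr = run["learning_rate"].to_numpy(dtype=float)
        s_hat = run["s_hat"].to_numpy(dtype=float)
        n = len(run)
        for pos, prev_target in _reversal_points(run):
            value = s_hat if prev_target == "A" else 1.0 - s_hat
            for i, off in enumerate(offsets):
                t = pos + off
                if not (0 <= t < n):
                    continue
                if np.isfinite(lr[t]):
                    sum_lr[i] += lr[t]
                    n_lr[i] += 1
                if np.isfinite(value[t]):
                    sum_val[i] += value[t]
                    n_val[i] += 1

    with np.errstate(invalid="ignore"):
        return pd.DataFrame({
            "offset": offsets,
            "mean_learning_rate": np.where(n_lr > 0, sum_lr / np.maximum(n_lr, 1),
                                           np.nan),
            "mean_value": np.where(n_val > 0, sum_val / np.maximum(n_val, 1),
                                   np.nan),
            "n": np.maximum(n_lr, n_val),
        })
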