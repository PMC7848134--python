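"""Inferential statistics over per-subject summaries.

Thin, validated wrappers around scipy/pingouin that return a uniform
GroupComparison record (statistic, value, p, descriptives), matching the
reporting style of the behavioural literature: Mann-Whitney U with a
tie-corrected normal-approximation z (exact p for small untied samples),
mixed within x between ANOVA, and Pearson correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    statistic: str            # "U", "z", "t", "F", "r"
    value: float
    p_value: float
    effect_frame: str         # between | within | interaction | association
    n: tuple[int, ...] = ()
    group_means: tuple[float, ...] = ()
    group_sds: tuple[float, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Reports the U of the first sample, a tie-corrected normal-approximation
    z (no continuity correction), and scipy's p (exact when both n <= 8 and
    there are no ties, asymptotic otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    # tie-corrected variance of U under H0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = (res.statistic - n1 * n2 / 2.0) / np.sqrt(var_u) if var_u > 0 else 0.0
    return GroupComparison(
        statistic="U", value=float(res.statistic), p_value=float(res.pvalue),
        effect_frame="between", n=(n1, n2),
        group_means=(float(np.mean(x)), float(np.mean(y))),
        group_sds=(float(np.std(x, ddof=1)) if n1 > 1 else 0.0,
                   float(np.std(y, ddof=1)) if n2 > 1 else 0.0),
        extra={"z": float(z)})


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str) -> list[GroupComparison]:
    """Mixed ANOVA (one within factor, one between factor) via pingouin.

    Requires a balanced within design: every subject contributes exactly one
    observation per within-factor level. Returns [between, within,
    interaction] comparisons.
    """
    counts = data.groupby([subject, within], observed=True)[dv].count() \
        .unstack(within)
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("missing or duplicated cells in the within design")
    import pingouin as pg
    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between)
    out = []
    frames = {between: "between", within: "within",
              "Interaction": "interaction"}
    for _, row in aov.iterrows():
        frame = frames.get(row["Source"])
        if frame is None:
            continue
        out.append(GroupComparison(
            statistic="F", value=float(row["F"]),
            p_value=float(row["p_unc"]), effect_frame=frame,
            extra={"df1": float(row["DF1"]), "df2": float(row["DF2"])}))
    return out


def pearson_corr(x, y) -> GroupComparison:
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return GroupComparison(
        statistic="r", value=float(r), p_value=float(p),
        effect_frame="association", n=(len(x),),
        group_means=(float(np.mean(x)), float(np.mean(y))),
        group_sds=(float(np.std(x, ddof=1)), float(np.std(y, ddof=1))))


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni-adjusted p-values (capped at 1) and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * len(p), 1.0)
    return adj, adj < alpha
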