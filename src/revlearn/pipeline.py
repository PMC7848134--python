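"""End-to-end analysis over a cohort, mirroring the study's sequence:

fit all three models per subject-run -> random-effects BMS (overall and per
age group) -> parameter tables and Mann-Whitney group comparisons -> error
taxonomy with mixed ANOVAs -> reversal-aligned belief trajectories ->
correlations -> (optionally) repeated model- and error-pattern-recovery
studies on freshly generated cohorts.

Per-subject model evidence is the sum of the three condition-runs' Laplace
log evidences (one evidence per subject per model); a per-run BMS is
available via ``aggregate_runs=False``.
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import align_to_reversals, classify_errors
from .cohort import CohortDataset, GroupSpec, default_study_specs, generate_cohort
from .inversion import fit_model
from .models import MODEL_IDS
from .selection import BMSResult, rfx_bms
from .stats import GroupComparison, mann_whitney, mixed_anova, pearson_corr
from .task import TaskConfig

PARAM_COLS = ("alpha", "omega", "theta", "beta")


def fit_cohort(trials: pd.DataFrame, models: Sequence[str] = MODEL_IDS,
               n_restarts: int = 4, seed: int = 0,
               keep_trajectories: bool = True):
    """Fit every model to every subject-run.

    Returns (fit table, trajectories) where trajectories maps
    (subject_id, condition, model) -> per-trial belief frame.
    """
    rows = []
    trajectories = {}
    runs = list(trials.groupby(["subject_id", "condition"], sort=False))
    seeds = np.random.SeedSequence(seed).spawn(len(runs) * len(models))
    k = 0
    for (sid, cond), run in runs:
        group = run["group"].iloc[0]
        for model in models:
            fit = fit_model(run, model, n_restarts=n_restarts,
                            seed=seeds[k], with_trajectory=keep_trajectories)
            k += 1
            row = {"subject_id": sid, "group": group, "condition": cond,
                   "model": model}
            row.update({p: fit.params.get(p, np.nan) for p in PARAM_COLS})
            row.update({"log_joint": fit.log_joint,
                        "log_evidence": fit.log_evidence,
                        "converged": fit.converged,
                        "mean_learning_rate": fit.mean_learning_rate})
            rows.append(row)
            if keep_trajectories:
                trajectories[(sid, cond, model)] = fit.trajectory
    return pd.DataFrame(rows), trajectories


def evidence_matrix(fits: pd.DataFrame, models: Sequence[str] = MODEL_IDS,
                    aggregate_runs: bool = True) -> pd.DataFrame:
    """Subjects x models log-evidence table (condition runs summed by default)."""
    index = ["subject_id"] if aggregate_runs else ["subject_id", "condition"]
    mat = fits.pivot_table(index=index, columns="model",
                           values="log_evidence", aggfunc="sum")
    return mat.loc[:, list(models)]


def bms_by_group(fits: pd.DataFrame, models: Sequence[str] = MODEL_IDS,
                 seed: int = 0, **kwargs) -> dict[str, BMSResult]:
    """RFX-BMS across all subjects and restricted to each group."""
    out = {}
    groups = fits[["subject_id", "group"]].drop_duplicates() \
        .set_index("subject_id")["group"]
    mat = evidence_matrix(fits, models)
    out["all"] = rfx_bms(mat.to_numpy(), model_labels=models, seed=seed,
                         **kwargs)
    for g in groups.unique():
        sub = mat.loc[groups[groups == g].index]
        out[g] = rfx_bms(sub.to_numpy(), model_labels=models, seed=seed,
                         **kwargs)
    return out


def error_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject-run error taxonomy percentages."""
    rows = []
    for (sid, cond), run in trials.groupby(["subject_id", "condition"],
                                           sort=False):
        counts = classify_errors(run)
        rows.append({"subject_id": sid, "group": run["group"].iloc[0],
                     "condition": cond, "n_valid": counts.n_valid_trials,
                     "overall_pct": counts.overall_pct,
                     "perseverative_pct": counts.perseverative_pct,
                     "regressive_pct": counts.regressive_pct,
                     "unclassified_pct": counts.unclassified_pct})
    return pd.DataFrame(rows)


def error_anovas(errors: pd.DataFrame) -> pd.DataFrame:
    """Mixed condition x group ANOVA for each error-rate measure."""
    rows = []
    for dv in ("overall_pct", "perseverative_pct", "regressive_pct"):
        for comp in mixed_anova(errors, dv=dv, within="condition",
                                subject="subject_id", between="group"):
            rows.append({"measure": dv, "effect": comp.effect_frame,
                         "F": comp.value, "p": comp.p_value,
                         "df1": comp.extra["df1"], "df2": comp.extra["df2"]})
    return pd.DataFrame(rows)


def parameter_comparison(fits: pd.DataFrame, winning_model: str,
                         group_order: Sequence[str]) -> pd.DataFrame:
    """Mann-Whitney group contrasts of the winning model's estimates.

    Compares beta and mean learning rate as per-subject means across
    conditions, and omega both across and within conditions.
    """
    w = fits[fits["model"] == winning_model]
    g1, g2 = group_order
    rows = []

    def add(label, condition, values):
        grp = values.groupby("group")
        x = grp.get_group(g1)["value"].to_numpy()
        y = grp.get_group(g2)["value"].to_numpy()
        comp = mann_whitney(x, y)
        rows.append({"measure": label, "condition": condition,
                     "U": comp.value, "z": comp.extra["z"],
                     "p": comp.p_value,
                     f"mean_{g1}": comp.group_means[0],
                     f"sd_{g1}": comp.group_sds[0],
                     f"mean_{g2}": comp.group_means[1],
                     f"sd_{g2}": comp.group_sds[1]})

    per_subj = w.groupby(["subject_id", "group"], as_index=False) \
        .agg(beta=("beta", "mean"), omega=("omega", "mean"),
             lr=("mean_learning_rate", "mean"))
    for label, col in (("beta", "beta"), ("omega", "omega"),
                       ("learning_rate", "lr")):
        add(label, "all", per_subj.rename(columns={col: "value"}))
    for cond, sub in w.groupby("condition", sort=False):
        add("omega", cond, sub.rename(columns={"omega": "value"}))
        add("learning_rate", cond,
            sub.rename(columns={"mean_learning_rate": "value"}))
    return pd.DataFrame(rows)


def aligned_trajectories(trials: pd.DataFrame, trajectories: dict,
                         model: str, window=(-2, 5)) -> pd.DataFrame:
    """Reversal-aligned learning rate / value curves per group, from the
    fitted trajectories of ``model``."""
    frames = []
    for group, gtrials in trials.groupby("group", sort=False):
        runs = []
        for (sid, cond), run in gtrials.groupby(["subject_id", "condition"],
                                                sort=False):
            traj = trajectories.get((sid, cond, model))
            if traj is None:
                continue
            run = run.drop(columns=[c for c in
                                    ("s_hat", "learning_rate", "delta1",
                                     "mu2", "sigma2", "mu3")
                                    if c in run.columns])
            runs.append(run.merge(traj, on="trial_index"))
        aligned = align_to_reversals(pd.concat(runs, ignore_index=True),
                                     window=window)
        aligned.insert(0, "group", group)
        frames.append(aligned)
    return pd.concat(frames, ignore_index=True)


def correlation_report(fits: pd.DataFrame, errors: pd.DataFrame,
                       subjects: pd.DataFrame,
                       winning_model: str) -> pd.DataFrame:
    """Parameter-behaviour and parameter-rigidity correlations."""
    w = fits[fits["model"] == winning_model]
    per_subj = w.groupby("subject_id") \
        .agg(beta=("beta", "mean"), omega=("omega", "mean"),
             lr=("mean_learning_rate", "mean"))
    err = errors.groupby("subject_id")[
        ["overall_pct", "perseverative_pct", "regressive_pct"]].mean()
    tab = per_subj.join(err).join(
        subjects.set_index("subject_id")[["rigidity"]])
    rows = []
    pairs = [(p, e) for p in ("beta", "omega", "lr")
             for e in ("overall_pct", "perseverative_pct", "regressive_pct")]
    pairs += [("beta", "rigidity"), ("omega", "rigidity")]
    for a, b in pairs:
        comp = pearson_corr(tab[a], tab[b])
        rows.append({"x": a, "y": b, "r": comp.value, "p": comp.p_value,
                     "n": comp.n[0]})
    return pd.DataFrame(rows)


def run_analysis(cohort: CohortDataset, models: Sequence[str] = MODEL_IDS,
                 n_restarts: int = 4, seed: int = 0,
                 outdir: Optional[str] = None,
                 winning_model: str = "hgf_fixed_theta") -> dict:
    """Full analysis bundle over one cohort; optionally write CSV artifacts."""
    fits, trajectories = fit_cohort(cohort.trials, models,
                                    n_restarts=n_restarts, seed=seed)
    bms = bms_by_group(fits, models, seed=seed)
    errors = error_summary(cohort.trials)
    anovas = error_anovas(errors)
    group_order = list(dict.fromkeys(cohort.subjects["group"]))
    params = parameter_comparison(fits, winning_model, group_order)
    aligned = aligned_trajectories(cohort.trials, trajectories, winning_model)
    corrs = correlation_report(fits, errors, cohort.subjects, winning_model)

    bms_table = pd.DataFrame(
        [{"scope": scope, "model": m, "alpha": res.dirichlet_alpha[i],
          "expected_freq": res.expected_freq[i],
          "exceedance_prob": res.exceedance_prob[i]}
         for scope, res in bms.items()
         for i, m in enumerate(res.model_labels)])

    bundle = {"fits": fits, "bms": bms, "bms_table": bms_table,
              "errors": errors, "error_anovas": anovas,
              "param_comparison": params, "aligned": aligned,
              "correlations": corrs,
              "provenance": {"seed": seed, "config_hash": cohort.config_hash}}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("fits", "bms_table", "errors", "error_anovas",
                     "param_comparison", "aligned", "correlations"):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
        pd.DataFrame([bundle["provenance"]]).to_csv(out / "provenance.csv",
                                                    index=False)
    return bundle


# ----------------------------------------------------------- recovery study

def scaled_specs(n_per_group: int = 8) -> list[GroupSpec]:
    """Study specs at reduced cohort size (distributions unchanged)."""
    return [GroupSpec(**{**asdict(s), "n_subjects": n_per_group})
            for s in default_study_specs()]


def scaled_task_config(n_reversals: int = 5) -> TaskConfig:
    """Task at reduced length for repeated-replicate studies.

    Five reversals is the shortest run that still guarantees >= 30 valid
    trials (the fitting minimum) even for an agent that reverses at the
    fastest possible pace.
    """
    return TaskConfig(n_reversals_max=n_reversals,
                      n_trials_max=20 * n_reversals)


def run_recovery_study(n_replicates: int = 10,
                       specs: Optional[list[GroupSpec]] = None,
                       config: Optional[TaskConfig] = None,
                       models: Sequence[str] = MODEL_IDS,
                       n_restarts: int = 3, seed: int = 0,
                       n_bootstrap: int = 2000) -> dict:
    """Generate -> fit -> BMS -> classify errors, repeatedly.

    Aggregates (a) how often BMS awards the generating model
    (hgf_fixed_theta) the top exceedance probability overall and within each
    group, (b) true-vs-recovered correlations for omega and beta with
    bootstrap CIs, and (c) how often the group-level error pattern
    (perseverative: adolescents > children; regressive: children >
    adolescents) is recovered.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    specs = specs if specs is not None else scaled_specs()
    config = config if config is not None else scaled_task_config()
    rep_rows, truth_pairs = [], {"omega": [], "beta": []}
    root = np.random.SeedSequence(seed)
    for rep, (ss_gen, ss_fit) in enumerate(
            zip(root.spawn(n_replicates),
                np.random.SeedSequence((seed, 1)).spawn(n_replicates))):
        cohort = generate_cohort(specs, config,
                                 seed=int(ss_gen.generate_state(1)[0] >> 1))
        fits, _ = fit_cohort(cohort.trials, models, n_restarts=n_restarts,
                             seed=int(ss_fit.generate_state(1)[0] >> 1),
                             keep_trajectories=False)
        bms = bms_by_group(fits, models, seed=rep)
        win = {scope: res.model_labels[int(np.argmax(res.exceedance_prob))]
               for scope, res in bms.items()}

        w = fits[fits["model"] == "hgf_fixed_theta"]
        merged = w.merge(cohort.subjects, on="subject_id",
                         suffixes=("_hat", "_true"))
        true_omega = np.concatenate(
            [merged.loc[merged["condition"] == c, f"omega_{c}"].to_numpy()
             for c in merged["condition"].unique()])
        hat_omega = np.concatenate(
            [merged.loc[merged["condition"] == c, "omega"].to_numpy()
             for c in merged["condition"].unique()])
        truth_pairs["omega"].append((true_omega, hat_omega))
        per_subj = merged.groupby("subject_id").agg(
            beta_true=("beta_true", "first"), beta_hat=("beta_hat", "mean"))
        truth_pairs["beta"].append((per_subj["beta_true"].to_numpy(),
                                    per_subj["beta_hat"].to_numpy()))

        err = error_summary(cohort.trials).groupby("group")[
            ["perseverative_pct", "regressive_pct"]].mean()
        rep_rows.append({
            "replicate": rep,
            **{f"winner_{scope}": m for scope, m in win.items()},
            "exceedance_fixed_all":
                bms["all"].exceedance_prob[
                    list(bms["all"].model_labels).index("hgf_fixed_theta")],
            "persev_adol_gt_child":
                err.loc["adolescents", "perseverative_pct"]
                > err.loc["children", "perseverative_pct"],
            "regress_child_gt_adol":
                err.loc["children", "regressive_pct"]
                > err.loc["adolescents", "regressive_pct"],
            "r_omega": float(np.corrcoef(*truth_pairs["omega"][-1])[0, 1]),
            "r_beta": float(np.corrcoef(*truth_pairs["beta"][-1])[0, 1]),
        })
    reps = pd.DataFrame(rep_rows)

    rng = np.random.default_rng(seed)
    cis = {}
    for name in ("omega", "beta"):
        true = np.concatenate([t for t, _ in truth_pairs[name]])
        hat = np.concatenate([h for _, h in truth_pairs[name]])
        r = float(np.corrcoef(true, hat)[0, 1])
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(len(true), size=len(true))
            boots[b] = np.corrcoef(true[idx], hat[idx])[0, 1]
        cis[name] = {"r": r,
                     "ci_low": float(np.quantile(boots, 0.025)),
                     "ci_high": float(np.quantile(boots, 0.975))}

    win_cols = [c for c in reps.columns if c.startswith("winner_")]
    return {
        "replicates": reps,
        "win_rate_all": float((reps["winner_all"] == "hgf_fixed_theta").mean()),
        "win_rate_every_scope": float(
            (reps[win_cols] == "hgf_fixed_theta").all(axis=1).mean()),
        "error_direction_rate": float(
            (reps["persev_adol_gt_child"]
             & reps["regress_child_gt_adol"]).mean()),
        "recovery": cis,
    }
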