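"""Reading and writing trial logs and cohort datasets as plain CSV."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .task import TaskConfig

TRIAL_COLUMNS = ["subject_id", "group", "condition", "trial_index",
                 "block_index", "chosen", "target", "correct", "feedback",
                 "contingent", "missed"]
BELIEF_COLUMNS = ["s_hat", "delta1", "mu2", "sigma2", "mu3", "learning_rate"]


def write_trial_log(df: pd.DataFrame, path) -> None:
    cols = TRIAL_COLUMNS + [c for c in BELIEF_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log {path} lacks columns {sorted(missing)}")
    for col in ("correct", "contingent"):
        df[col] = df[col].astype("boolean")
    df["missed"] = df["missed"].astype(bool)
    df["feedback"] = df["feedback"].astype("Int64")
    return df


def config_hash(config: TaskConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_task_config(config: TaskConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def read_task_config(path) -> TaskConfig:
    return TaskConfig.from_dict(yaml.safe_load(Path(path).read_text()))
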