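import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import revlearn as rl

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def task_config():
    return rl.TaskConfig()


@pytest.fixture(scope="session")
def hgf_run(task_config):
    """One full simulated fixed-theta HGF run at study-scale parameters."""
    return rl.simulate_agent(
        "hgf_fixed_theta", rl.HGFParams(omega=0.6, beta=6.0),
        task_config, seed=11, subject_id="s0")


@pytest.fixture(scope="session")
def operating_states(task_config):
    """Belief states visited by agents across the study's omega range.

    Used as the sampling distribution for single-step numerical oracles so
    they probe the regime the filter actually works in.
    """
    states = []
    for k, om in enumerate((-1.0, -0.3, 0.3, 0.8, 1.5)):
        df = rl.simulate_agent("hgf_fixed_theta",
                               rl.HGFParams(omega=om, beta=6.0),
                               task_config, seed=900 + k)
        valid = ~df["missed"].to_numpy(dtype=bool)
        for t in range(1, len(df)):
            if valid[t]:
                states.append((df["mu2"][t - 1], df["sigma2"][t - 1],
                               df["mu3"][t - 1]))
    return states


def toy_trial_log(block_patterns):
    """Build a minimal trial log from per-block C/E strings."""
    rows = []
    t = 0
    for b, pattern in enumerate(block_patterns):
        for ch in pattern:
            rows.append({"trial_index": t, "block_index": b,
                         "chosen": "A" if ch == "C" else "B", "target": "A",
                         "correct": ch == "C", "feedback": int(ch == "C"),
                         "contingent": True, "missed": ch == "M"})
            t += 1
    return pd.DataFrame(rows)
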