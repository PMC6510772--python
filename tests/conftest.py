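import numpy as np
import pandas as pd
import pytest

from diallel.data_model import DiallelTable, from_records
from diallel.simulate import SimConfig, simulate


def make_plot_frame(p, envs, reps, traits, value_fn):
    """Build a balanced long-format record frame; value_fn(env, rep, i, j, trait)."""
    rows = []
    for env in envs:
        for rep in reps:
            for i in range(1, p + 1):
                for j in range(i, p + 1):
                    for trait in traits:
                        rows.append((env, rep, i, j, trait, value_fn(env, rep, i, j, trait)))
    return pd.DataFrame(
        rows,
        columns=["environment", "replicate", "parent_a", "parent_b", "trait", "value"],
    )


@pytest.fixture
def paper_shaped_plots():
    """p=11, r=2, two environments, one trait — the published trial's shape."""
    cfg = SimConfig(
        p=11,
        r=2,
        environments=("non-saline", "saline"),
        var_gca=21.39,
        var_sca=62.51,
        var_env=60.0,
        var_gca_env=2.0,
        var_sca_env=1.5,
        var_rep=1.0,
        var_error=19.54,
        grand_mean=40.0,
        seed=42,
        trait="FY",
    )
    plots, truth = simulate(cfg)
    return plots, truth


@pytest.fixture
def small_plots():
    """p=4, r=3, one environment, deterministic pseudo-random values."""
    rng = np.random.default_rng(7)
    df = make_plot_frame(
        4, ["e1"], ["r1", "r2", "r3"], ["y"],
        lambda env, rep, i, j, trait: float(rng.normal(10 + i + j, 2)),
    )
    return from_records(df)


def random_diallel_table(p, seed, trait="y", environment="e1"):
    rng = np.random.default_rng(seed)
    raw = rng.normal(50, 5, size=(p, p))
    means = np.triu(raw) + np.triu(raw, k=1).T
    return DiallelTable(p=p, trait=trait, environment=environment, means=means)
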