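"""Synthetic balanced half-diallel RCBD trials with known truth.

Each plot value is

    value = grand_mean + env + rep(env) + g_i + g_j + s_ij
            + (g x env)_i + (g x env)_j + (s x env)_ij + error

with every effect drawn from a zero-mean normal at its configured variance.
GCA draws are centered to sum exactly to zero so that finite-sample truth
matches the estimator's identifiability constraint; raw draws are kept in
:class:`SimTruth`.

Randomness uses one global seed with fixed per-component substreams, so e.g.
changing ``r`` does not reshuffle the genetic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PlotTable, from_records
from .errors import AnalysisLookupError, ConfigError

__all__ = ["SimConfig", "SimTruth", "simulate", "paper_preset", "PRESETS"]

_VARIANCE_FIELDS = (
    "var_gca",
    "var_sca",
    "var_env",
    "var_gca_env",
    "var_sca_env",
    "var_rep",
    "var_error",
)

# substream indices for the per-component child seeds
_STREAMS = {name: k for k, name in enumerate(
    ("gca", "sca", "env", "gca_env", "sca_env", "rep", "error")
)}


@dataclass(frozen=True)
class SimConfig:
    p: int = 11
    r: int = 2
    environments: tuple[str, ...] = ("env1", "env2")
    var_gca: float = 1.0
    var_sca: float = 1.0
    var_env: float = 0.0
    var_gca_env: float = 0.0
    var_sca_env: float = 0.0
    var_rep: float = 0.0
    var_error: float = 1.0
    grand_mean: float = 0.0
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ConfigError(f"p must be >= 3, got {self.p}")
        if self.r < 1:
            raise ConfigError(f"r must be >= 1, got {self.r}")
        if len(self.environments) < 1:
            raise ConfigError("need at least one environment")
        for name in _VARIANCE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be a finite non-negative variance, got {v}")


@dataclass(frozen=True)
class SimTruth:
    """Realized effects behind one simulated trial."""

    config: SimConfig
    gca: np.ndarray = field(repr=False)  # centered, sums to 0
    gca_raw: np.ndarray = field(repr=False)
    sca: np.ndarray = field(repr=False)  # symmetric p x p
    env: dict[str, float] = field(repr=False, default_factory=dict)
    rep: dict[tuple[str, str], float] = field(repr=False, default_factory=dict)
    gca_env: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    sca_env: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flatten the truth into a long table (for the sidecar file)."""
        rows = []
        p = self.config.p
        for i in range(p):
            rows.append(("<all>", "gca", f"P{i + 1}", self.gca[i]))
        for i in range(p):
            for j in range(i, p):
                rows.append(("<all>", "sca", f"P{i + 1}xP{j + 1}", self.sca[i, j]))
        for env, v in self.env.items():
            rows.append((env, "environment", "", v))
        for (env, rep), v in self.rep.items():
            rows.append((env, "replicate", rep, v))
        for env, arr in self.gca_env.items():
            for i in range(p):
                rows.append((env, "gca_env", f"P{i + 1}", arr[i]))
        for env, mat in self.sca_env.items():
            for i in range(p):
                for j in range(i, p):
                    rows.append((env, "sca_env", f"P{i + 1}xP{j + 1}", mat[i, j]))
        return pd.DataFrame(rows, columns=["environment", "effect", "level", "value"])


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[component]]))


def _symmetric_draws(rng: np.random.Generator, p: int, sd: float) -> np.ndarray:
    draw = rng.normal(0.0, sd, size=(p, p))
    return np.triu(draw) + np.triu(draw, k=1).T


def simulate(config: SimConfig) -> tuple[PlotTable, SimTruth]:
    """Draw one balanced trial; bit-identical for identical configs."""
    p, r = config.p, config.r
    envs = config.environments

    gca_raw = _rng(config.seed, "gca").normal(0.0, np.sqrt(config.var_gca), size=p)
    gca = gca_raw - gca_raw.mean()
    sca = _symmetric_draws(_rng(config.seed, "sca"), p, np.sqrt(config.var_sca))

    env_rng = _rng(config.seed, "env")
    env_eff = {e: float(env_rng.normal(0.0, np.sqrt(config.var_env))) for e in envs}
    rep_rng = _rng(config.seed, "rep")
    rep_labels = tuple(f"rep{k + 1}" for k in range(r))
    rep_eff = {
        (e, lab): float(rep_rng.normal(0.0, np.sqrt(config.var_rep)))
        for e in envs
        for lab in rep_labels
    }
    ge_rng = _rng(config.seed, "gca_env")
    gca_env = {
        e: ge_rng.normal(0.0, np.sqrt(config.var_gca_env), size=p) for e in envs
    }
    se_rng = _rng(config.seed, "sca_env")
    sca_env = {
        e: _symmetric_draws(se_rng, p, np.sqrt(config.var_sca_env)) for e in envs
    }
    err_rng = _rng(config.seed, "error")

    rows = []
    for env in envs:
        for lab in rep_labels:
            for i in range(p):
                for j in range(i, p):
                    value = (
                        config.grand_mean
                        + env_eff[env]
                        + rep_eff[(env, lab)]
                        + gca[i]
                        + gca[j]
                        + sca[i, j]
                        + gca_env[env][i]
                        + gca_env[env][j]
                        + sca_env[env][i, j]
                        + err_rng.normal(0.0, np.sqrt(config.var_error))
                    )
                    rows.append((env, lab, i + 1, j + 1, config.trait, value))
    df = pd.DataFrame(
        rows,
        columns=["environment", "replicate", "parent_a", "parent_b", "trait", "value"],
    )
    table = from_records(df)
    truth = SimTruth(
        config=config,
        gca=gca,
        gca_raw=gca_raw,
        sca=sca,
        env=env_eff,
        rep=rep_eff,
        gca_env=gca_env,
        sca_env=sca_env,
    )
    return table, truth


# (var_gca, var_sca, var_error) per trait, per environment, at the magnitudes
# the analysis reports for the 11-parent melon trial; grand means chosen to
# give plot CVs in the usual 5-15% range for each trait.
PRESETS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "non-saline": {
        "FWT": (0.11, 0.07, 0.05, 2.0),
        "NF": (0.03, 0.09, 0.12, 2.3),
        "FY": (21.39, 62.51, 19.54, 40.0),
        "FL": (0.74, 1.98, 0.82, 15.0),
        "FW": (1.50, 0.51, 1.03, 16.0),
        "SCL": (0.54, 1.74, 0.57, 10.0),
        "SCW": (0.71, 0.18, 0.62, 9.0),
        "FT": (0.11, 0.02, 0.08, 3.5),
        "PT": (0.001, 0.06, 0.05, 2.0),
        "TSS": (0.25, 0.34, 0.28, 10.5),
    },
    "saline": {
        "FWT": (0.03, 0.07, 0.04, 1.3),
        "NF": (0.01, 0.06, 0.08, 1.5),
        "FY": (1.80, 22.01, 11.16, 23.0),
        "FL": (0.28, 2.07, 0.71, 12.7),
        "FW": (0.88, 0.68, 0.80, 14.0),
        "SCL": (0.28, 1.42, 0.48, 8.0),
        "SCW": (0.44, 0.22, 0.29, 8.0),
        "FT": (0.05, 0.05, 0.06, 3.0),
        "PT": (0.002, 0.09, 0.04, 2.5),
        "TSS": (0.32, 0.74, 0.20, 11.8),
    },
}


def paper_preset(trait: str, environment: str, seed: int = 0) -> SimConfig:
    """Single-environment preset at the published variance magnitudes.

    Interaction and replicate variances default to 0 (these presets describe
    one environment at a time).
    """
    try:
        env_presets = PRESETS[environment]
    except KeyError:
        raise AnalysisLookupError(
            f"unknown environment {environment!r}; known: {sorted(PRESETS)}"
        ) from None
    try:
        var_gca, var_sca, var_error, mean = env_presets[trait]
    except KeyError:
        raise AnalysisLookupError(
            f"unknown trait {trait!r}; known: {sorted(env_presets)}"
        ) from None
    return SimConfig(
        p=11,
        r=2,
        environments=(environment,),
        var_gca=var_gca,
        var_sca=var_sca,
        var_error=var_error,
        grand_mean=mean,
        seed=seed,
        trait=trait,
    )
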