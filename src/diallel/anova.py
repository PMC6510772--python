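"""Balanced ANOVA for half-diallel RCBD trials.

``rcbd_anova`` gives the per-environment replicate/genotype/error
decomposition; ``combined_anova`` gives the multi-environment table with the
genotype and genotype-by-environment sums of squares each partitioned into
their GCA and SCA parts. All F tests are against the residual (fixed-effects
model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import DiallelTable, PlotTable, validate_design
from .errors import DiallelError
from .griffing import estimate_effects, partition_genotype_ss

__all__ = ["AnovaRow", "AnovaTable", "rcbd_anova", "combined_anova", "significance_stars"]


def significance_stars(p_value: float | None) -> str:
    """Star code: ** below 0.01, * below 0.05, ns otherwise."""
    if p_value is None:
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None
    f: float | None = None
    p_value: float | None = None
    stars: str = ""


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    cv_percent: float
    r_squared: float
    grand_mean: float = float("nan")
    ms_error: float = float("nan")
    df_error: int = 0

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(r.source for r in self.rows)


def _row(source: str, df: int, ss: float, ms_err: float, df_err: int) -> AnovaRow:
    ms = ss / df if df > 0 else None
    if ms is None or ms_err <= 0:
        return AnovaRow(source, df, ss, ms)
    f = ms / ms_err
    p = float(stats.f.sf(f, df, df_err))
    return AnovaRow(source, df, ss, ms, f, p, significance_stars(p))


def rcbd_anova(plots: PlotTable, environment: str, trait: str) -> AnovaTable:
    """Randomized-complete-block ANOVA on one environment's plots."""
    sub = plots.subset(environment=environment, trait=trait)
    design = validate_design(sub)
    g, r = design.n_entries, design.replicates_per_env
    df = sub.df
    y = df["value"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    rep_means = df.groupby("replicate")["value"].mean()
    ss_rep = float(g * ((rep_means - grand) ** 2).sum())
    ent_means = df.groupby(["parent_a", "parent_b"])["value"].mean()
    ss_gen = float(r * ((ent_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rep - ss_gen

    df_rep, df_gen = r - 1, g - 1
    df_err = (g - 1) * (r - 1)
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    rows = (
        _row("replicate", df_rep, ss_rep, ms_err, df_err),
        _row("genotype", df_gen, ss_gen, ms_err, df_err),
        AnovaRow("error", df_err, ss_err, ms_err if df_err > 0 else None),
        AnovaRow("total", len(y) - 1, ss_total, None),
    )
    cv = 100.0 * np.sqrt(ms_err) / grand if grand != 0 else float("nan")
    r2 = 1.0 - ss_err / ss_total if ss_total > 0 else float("nan")
    return AnovaTable(rows, float(cv), float(r2), float(grand), float(ms_err), df_err)


def combined_anova(plots: PlotTable, trait: str) -> AnovaTable:
    """Combined multi-environment ANOVA with GCA/SCA partitions.

    Sources: environment, rep(environment), genotype, gca, sca,
    genotype x env, gca x env, sca x env, residual, total. Interaction SS for
    GCA and SCA are obtained by differencing per-environment partitions
    against the pooled-mean partition, which keeps every additivity identity
    exact on balanced data.
    """
    sub = plots.subset(trait=trait)
    design = validate_design(sub)
    envs = design.environments
    if len(envs) < 2:
        raise DiallelError("combined_anova needs >= 2 environments; use rcbd_anova")
    g, r, e, p = design.n_entries, design.replicates_per_env, len(envs), design.p
    df = sub.df
    y = df["value"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_means = df.groupby("environment")["value"].mean()
    ss_env = float(g * r * ((env_means - grand) ** 2).sum())

    rep_means = df.groupby(["environment", "replicate"])["value"].mean()
    ss_rep = float(
        g * sum((rep_means.loc[env] - env_means[env]).pow(2).sum() for env in envs)
    )

    pooled = df.groupby(["parent_a", "parent_b"])["value"].mean()
    ss_gen = float(e * r * ((pooled - grand) ** 2).sum())

    cell = df.groupby(["environment", "parent_a", "parent_b"])["value"].mean()
    ss_cells = float(r * ((cell - grand) ** 2).sum())
    ss_gxe = ss_cells - ss_gen - ss_env

    # GCA/SCA partition of the pooled genotype SS
    means = np.zeros((p, p))
    for (i, j), m in pooled.items():
        means[i - 1, j - 1] = means[j - 1, i - 1] = m
    eff = estimate_effects(DiallelTable(p=p, trait=trait, environment="<pooled>", means=means))
    iu = np.triu_indices(p)
    ss_gca = float(e * r * (p + 2) * np.sum(eff.gca**2))
    ss_sca = float(e * r * np.sum(eff.sca[iu] ** 2))

    # per-environment partitions; interaction SS by differencing
    ss_gca_env_total = 0.0
    ss_sca_env_total = 0.0
    ss_err = 0.0
    for env in envs:
        sg, ss_, _, _ = partition_genotype_ss(sub, env, trait)
        ss_gca_env_total += sg
        ss_sca_env_total += ss_
        per = rcbd_anova(sub, env, trait)
        ss_err += per["error"].ss
    ss_gca_x = ss_gca_env_total - ss_gca
    ss_sca_x = ss_sca_env_total - ss_sca

    df_env = e - 1
    df_rep = e * (r - 1)
    df_gen = g - 1
    df_gxe = (g - 1) * (e - 1)
    df_gca = p - 1
    df_sca = p * (p - 1) // 2
    df_err = e * (g - 1) * (r - 1)
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    rows = (
        _row("environment", df_env, ss_env, ms_err, df_err),
        _row("rep(environment)", df_rep, ss_rep, ms_err, df_err),
        _row("genotype", df_gen, ss_gen, ms_err, df_err),
        _row("genotype x environment", df_gxe, ss_gxe, ms_err, df_err),
        _row("gca", df_gca, ss_gca, ms_err, df_err),
        _row("sca", df_sca, ss_sca, ms_err, df_err),
        _row("gca x environment", df_gca * df_env, ss_gca_x, ms_err, df_err),
        _row("sca x environment", df_sca * df_env, ss_sca_x, ms_err, df_err),
        AnovaRow("residual", df_err, ss_err, ms_err if df_err > 0 else None),
        AnovaRow("total", len(y) - 1, ss_total, None),
    )
    cv = 100.0 * np.sqrt(ms_err) / grand if grand != 0 else float("nan")
    r2 = 1.0 - ss_err / ss_total if ss_total > 0 else float("nan")
    return AnovaTable(rows, float(cv), float(r2), float(grand), float(ms_err), df_err)
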