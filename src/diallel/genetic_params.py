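"""Variance components, Baker's ratio and heritabilities for one environment.

Component estimators follow the half-diallel random-effects expectations of
the combining-ability mean squares (plot basis, entry totals over r
replicates):

    sigma2_GCA = (MS_GCA - MS_SCA) / (r (p + 2))
    sigma2_SCA = (MS_SCA - MS_error) / r
    sigma2_A   = 2 sigma2_GCA
    sigma2_D   = sigma2_SCA

Heritabilities are on the entry-mean error basis: the phenotypic denominator
is sigma2_A + sigma2_D + sigma2_E / r with sigma2_E the plot-basis residual
mean square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

from .data_model import PlotTable, validate_design
from .anova import rcbd_anova, significance_stars
from .griffing import partition_genotype_ss

__all__ = [
    "VarianceComponents",
    "GeneticParams",
    "variance_components",
    "baker_ratio",
    "heritability",
    "component_significance",
    "estimate_genetic_params",
]


class NegativeVarianceWarning(UserWarning):
    """A method-of-moments variance component came out negative."""


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_gca: float
    sigma2_sca: float
    sigma2_a: float
    sigma2_d: float
    gca_truncated: bool  # estimate negative, would be 0 if truncated
    sca_truncated: bool


@dataclass(frozen=True)
class GeneticParams:
    """Per-environment genetic-parameter summary (one trait)."""

    environment: str
    trait: str
    ms_gca: float
    ms_sca: float
    ms_error: float
    sigma2_gca: float
    sigma2_sca: float
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    ratio: float | None
    h2_broad: float | None
    h2_narrow: float | None
    flag_gca: str
    flag_sca: str
    cv_percent: float
    r_squared: float


def variance_components(
    ms_gca: float, ms_sca: float, ms_error: float, r: int, p: int
) -> VarianceComponents:
    """Method-of-moments variance components from plot-basis mean squares.

    Negative estimates are returned as computed, flagged as
    ``*_truncated`` and accompanied by a :class:`NegativeVarianceWarning`.
    """
    s2_gca = (ms_gca - ms_sca) / (r * (p + 2))
    s2_sca = (ms_sca - ms_error) / r
    for name, v in (("sigma2_GCA", s2_gca), ("sigma2_SCA", s2_sca)):
        if v < 0:
            warnings.warn(
                f"{name} estimate is negative ({v:.4g}); would be 0 if truncated",
                NegativeVarianceWarning,
                stacklevel=2,
            )
    return VarianceComponents(
        sigma2_gca=s2_gca,
        sigma2_sca=s2_sca,
        sigma2_a=2.0 * s2_gca,
        sigma2_d=s2_sca,
        gca_truncated=s2_gca < 0,
        sca_truncated=s2_sca < 0,
    )


def baker_ratio(sigma2_gca: float, sigma2_sca: float) -> float | None:
    """Baker's ratio 2 sigma2_GCA / (2 sigma2_GCA + sigma2_SCA); None if 0/0."""
    denom = 2.0 * sigma2_gca + sigma2_sca
    if denom == 0:
        return None
    return 2.0 * sigma2_gca / denom


def heritability(
    sigma2_a: float, sigma2_d: float, sigma2_e: float, r: int
) -> tuple[float | None, float | None]:
    """Broad- and narrow-sense heritability on the entry-mean error basis."""
    denom = sigma2_a + sigma2_d + sigma2_e / r
    if denom == 0:
        return None, None
    return (sigma2_a + sigma2_d) / denom, sigma2_a / denom


def component_significance(
    ms_gca: float,
    ms_sca: float,
    ms_error: float,
    df_gca: int,
    df_sca: int,
    df_error: int,
) -> tuple[str, str]:
    """Star codes for the two variance components.

    sigma2_GCA is tested by F = MS_GCA / MS_SCA on (df_gca, df_sca);
    sigma2_SCA by F = MS_SCA / MS_error on (df_sca, df_error).
    """
    flags = []
    for ms_num, ms_den, dfn, dfd in (
        (ms_gca, ms_sca, df_gca, df_sca),
        (ms_sca, ms_error, df_sca, df_error),
    ):
        if ms_den <= 0:
            flags.append("ns")
            continue
        p = float(stats.f.sf(ms_num / ms_den, dfn, dfd))
        flags.append(significance_stars(p))
    return flags[0], flags[1]


def estimate_genetic_params(plots: PlotTable, environment: str, trait: str) -> GeneticParams:
    """Full Table-4-style parameter set for one environment and trait."""
    ss_gca, ss_sca, df_gca, df_sca = partition_genotype_ss(plots, environment, trait)
    per_env = rcbd_anova(plots, environment, trait)
    ms_gca = ss_gca / df_gca
    ms_sca = ss_sca / df_sca
    ms_err = per_env.ms_error
    df_err = per_env.df_error
    design = validate_design(plots.subset(environment=environment, trait=trait))
    design_r = design.replicates_per_env
    p = design.p
    comps = variance_components(ms_gca, ms_sca, ms_err, design_r, p)
    if comps.gca_truncated or comps.sca_truncated:
        warnings.warn(
            "ratio/heritability use raw (possibly negative) component estimates",
            NegativeVarianceWarning,
            stacklevel=2,
        )
    ratio = baker_ratio(comps.sigma2_gca, comps.sigma2_sca)
    h2b, h2n = heritability(comps.sigma2_a, comps.sigma2_d, ms_err, design_r)
    flag_gca, flag_sca = component_significance(
        ms_gca, ms_sca, ms_err, df_gca, df_sca, df_err
    )
    return GeneticParams(
        environment=environment,
        trait=trait,
        ms_gca=ms_gca,
        ms_sca=ms_sca,
        ms_error=ms_err,
        sigma2_gca=comps.sigma2_gca,
        sigma2_sca=comps.sigma2_sca,
        sigma2_a=comps.sigma2_a,
        sigma2_d=comps.sigma2_d,
        sigma2_e=ms_err,
        ratio=ratio,
        h2_broad=h2b,
        h2_narrow=h2n,
        flag_gca=flag_gca,
        flag_sca=flag_sca,
        cv_percent=per_env.cv_percent,
        r_squared=per_env.r_squared,
    )
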