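"""Griffing Method 2 / Model 1 combining-ability estimation.

Closed-form estimates for a half diallel with parents (entries include the
diagonal), the GCA/SCA partition of the genotype sum of squares, and LSDs for
effect contrasts. All formulas are the classical Method-2 ones; the error
variance on the entry-mean basis is ``MS_error / r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .data_model import DiallelTable, PlotTable, entry_means, validate_design
from .errors import DesignTooSmallError, DiallelError

__all__ = [
    "GriffingEffects",
    "EffectContrastLSD",
    "ContrastKind",
    "estimate_effects",
    "partition_genotype_ss",
    "lsd_effect_contrast",
    "gca_variance",
    "sca_variance",
]


def _stars(p_value: float) -> str:
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GriffingEffects:
    """Estimated grand mean, GCA and SCA effects with optional tests.

    Satisfies ``sum(gca) == 0`` and the saturated reconstruction
    ``mu_hat + gca[i] + gca[j] + sca[i, j] == table.means[i, j]``.
    """

    p: int
    mu_hat: float
    gca: np.ndarray = field(repr=False)
    sca: np.ndarray = field(repr=False)
    se_gca: float | None = None
    se_sca_hybrid: float | None = None
    se_sca_parent: float | None = None
    star_gca: tuple[str, ...] | None = None
    star_sca: np.ndarray | None = field(default=None, repr=False)

    def reconstruct(self) -> np.ndarray:
        g = self.gca
        return self.mu_hat + g[:, None] + g[None, :] + self.sca


class ContrastKind(str, Enum):
    GCA_PAIR = "gca_pair"
    SCA_HALFSIB = "sca_halfsib"
    SCA_DISJOINT = "sca_disjoint"


@dataclass(frozen=True)
class EffectContrastLSD:
    kind: ContrastKind
    alpha: float
    df_error: int
    value: float


def gca_variance(p: int, sigma2_entry: float) -> float:
    """Sampling variance of a single GCA effect: (p-1)/(p(p+2)) * sigma2."""
    return (p - 1) / (p * (p + 2)) * sigma2_entry


def sca_variance(p: int, sigma2_entry: float, parent: bool = False) -> float:
    """Sampling variance of a single SCA effect.

    Hybrid (i != j): (p^2+p+2)/((p+1)(p+2)); parent diagonal: p(p-1)/((p+1)(p+2)).
    """
    if parent:
        return p * (p - 1) / ((p + 1) * (p + 2)) * sigma2_entry
    return (p * p + p + 2) / ((p + 1) * (p + 2)) * sigma2_entry


def estimate_effects(
    table: DiallelTable,
    ms_error: float | None = None,
    r: int | None = None,
    df_error: int | None = None,
) -> GriffingEffects:
    """Method-2 closed-form combining-ability estimates from entry means.

    With ``x_i.`` the i-th row sum of the symmetric mean table and ``x..`` the
    sum over the p(p+1)/2 distinct entries:

        mu = 2 x.. / (p (p+1))
        g_i = [x_i. + x_ii - 2 x.. / p] / (p + 2)
        s_ij = x_ij - mu - g_i - g_j

    When ``ms_error``, ``r`` and ``df_error`` are supplied, standard errors and
    two-sided t-test star codes are attached (entry-mean error variance
    ``ms_error / r``).
    """
    p = table.p
    if p < 3:
        raise DesignTooSmallError(f"Griffing Method 2 needs p >= 3, got p={p}")
    x = table.means
    row = x.sum(axis=1)
    total = (x.sum() + np.trace(x)) / 2.0  # sum over distinct entries i <= j
    mu = 2.0 * total / (p * (p + 1))
    g = (row + np.diag(x) - 2.0 * total / p) / (p + 2)
    g = g - g.mean()  # exact zero-sum despite rounding noise
    s = x - mu - g[:, None] - g[None, :]

    se_g = se_s_h = se_s_p = None
    star_g = star_s = None
    if ms_error is not None:
        if r is None or df_error is None:
            raise DiallelError("ms_error requires r and df_error for significance tests")
        sigma2 = ms_error / r
        se_g = float(np.sqrt(gca_variance(p, sigma2)))
        se_s_h = float(np.sqrt(sca_variance(p, sigma2)))
        se_s_p = float(np.sqrt(sca_variance(p, sigma2, parent=True)))
        pg = 2 * stats.t.sf(np.abs(g) / se_g, df_error)
        star_g = tuple(_stars(v) for v in pg)
        se_mat = np.full((p, p), se_s_h)
        np.fill_diagonal(se_mat, se_s_p)
        ps = 2 * stats.t.sf(np.abs(s) / se_mat, df_error)
        star_s = np.vectorize(_stars)(ps)

    return GriffingEffects(
        p=p,
        mu_hat=float(mu),
        gca=g,
        sca=s,
        se_gca=se_g,
        se_sca_hybrid=se_s_h,
        se_sca_parent=se_s_p,
        star_gca=star_g,
        star_sca=star_s,
    )


def partition_genotype_ss(
    plots: PlotTable, environment: str, trait: str
) -> tuple[float, float, int, int]:
    """Split the RCBD genotype SS into GCA and SCA components (plot basis).

    Returns ``(ss_gca, ss_sca, df_gca, df_sca)`` with ``df_gca = p - 1`` and
    ``df_sca = p(p-1)/2``. On balanced data
    ``ss_gca + ss_sca == ss_genotype`` exactly.
    """
    sub = plots.subset(environment=environment, trait=trait)
    design = validate_design(sub)
    r = design.replicates_per_env
    table = entry_means(sub, environment, trait)
    eff = estimate_effects(table)
    p = design.p
    iu = np.triu_indices(p)
    ss_gca = float(r * (p + 2) * np.sum(eff.gca**2))
    ss_sca = float(r * np.sum(eff.sca[iu] ** 2))
    return ss_gca, ss_sca, p - 1, p * (p - 1) // 2


_CONTRAST_COEF = {
    ContrastKind.GCA_PAIR: lambda p: 2.0 / (p + 2),
    ContrastKind.SCA_HALFSIB: lambda p: 2.0 * (p + 1) / (p + 2),
    ContrastKind.SCA_DISJOINT: lambda p: 2.0 * p / (p + 2),
}


def lsd_effect_contrast(
    kind: ContrastKind | str,
    ms_error: float,
    r: int,
    p: int,
    df_error: int,
    alpha: float = 0.05,
) -> EffectContrastLSD:
    """LSD for a combining-ability effect contrast.

    ``LSD = t(1 - alpha/2, df) * sqrt(c(p) * ms_error / r)`` where c(p) is
    2/(p+2) for g_i - g_j, 2(p+1)/(p+2) for s_ij - s_ik (half sibs) and
    2p/(p+2) for s_ij - s_kl (disjoint).
    """
    kind = ContrastKind(kind)
    if ms_error <= 0:
        raise DiallelError(f"ms_error must be positive, got {ms_error}")
    if not 0 < alpha < 1:
        raise DiallelError(f"alpha must be in (0, 1), got {alpha}")
    sigma2 = ms_error / r
    var = _CONTRAST_COEF[kind](p) * sigma2
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return EffectContrastLSD(kind=kind, alpha=alpha, df_error=df_error, value=float(t * np.sqrt(var)))
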