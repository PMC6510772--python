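"""End-to-end analysis orchestration and table rendering.

``run_analyze`` computes every statistic once into a machine-readable summary
(full precision), then renders the delimited report tables purely from that
summary — rendering never recomputes, so a rendered cell always equals the
summary value rounded to the configured precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .anova import combined_anova, rcbd_anova
from .data_model import PlotTable, entry_means, read_phenotypes, validate_design
from .errors import ConfigError
from .genetic_params import estimate_genetic_params
from .griffing import ContrastKind, estimate_effects, lsd_effect_contrast
from .heterosis import TraitDirection, fisher_lsd_means, heterosis_table

__all__ = ["RunConfig", "run_analyze", "render_bundle"]


@dataclass(frozen=True)
class RunConfig:
    input_path: Path
    output_dir: Path
    trait_directions: dict[str, bool]  # trait -> higher_is_better
    alpha: float = 0.05
    rounding: int = 2
    seed: int | None = None
    delimiter: str | None = None

    def __post_init__(self) -> None:
        if not self.trait_directions:
            raise ConfigError("trait list must be non-empty")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rounding < 0:
            raise ConfigError("rounding must be >= 0")


def _anova_rows(table) -> list[dict]:
    return [
        {
            "source": row.source,
            "df": row.df,
            "ss": row.ss,
            "ms": row.ms,
            "f": row.f,
            "p": row.p_value,
            "stars": row.stars,
        }
        for row in table.rows
    ]


def build_summary(plots: PlotTable, config: RunConfig) -> dict:
    """Compute the full analysis into one nested, JSON-serializable dict."""
    design = validate_design(plots)
    traits = [t for t in plots.traits if t in config.trait_directions]
    unknown = set(config.trait_directions) - set(plots.traits)
    if unknown:
        raise ConfigError(f"configured trait(s) not in data: {sorted(unknown)}")
    if not traits:
        raise ConfigError("no configured trait present in the input")

    summary: dict = {
        "design": {
            "p": design.p,
            "environments": list(design.environments),
            "replicates_per_env": design.replicates_per_env,
            "n_entries": design.n_entries,
        },
        "alpha": config.alpha,
        "traits": {},
    }
    p, r = design.p, design.replicates_per_env

    for trait in traits:
        tinfo: dict = {"higher_is_better": config.trait_directions[trait]}
        if len(design.environments) >= 2:
            comb = combined_anova(plots, trait)
            tinfo["combined_anova"] = {
                "rows": _anova_rows(comb),
                "cv_percent": comb.cv_percent,
                "r_squared": comb.r_squared,
            }
        tinfo["environments"] = {}
        direction = TraitDirection(trait, config.trait_directions[trait])
        for env in design.environments:
            per = rcbd_anova(plots, env, trait)
            params = estimate_genetic_params(plots, env, trait)
            table = entry_means(plots, env, trait)
            eff = estimate_effects(
                table, ms_error=per.ms_error, r=r, df_error=per.df_error
            )
            lsds = {
                kind.value: lsd_effect_contrast(
                    kind, per.ms_error, r, p, per.df_error, config.alpha
                ).value
                for kind in ContrastKind
            }
            het = heterosis_table(
                table, per.ms_error, r, per.df_error, direction, config.alpha
            )
            means = {
                f"P{i}" if i == j else f"P{i}xP{j}": table.entry(i, j)
                for i in range(1, p + 1)
                for j in range(i, p + 1)
            }
            lsd_mean, _, letters = fisher_lsd_means(
                means, per.ms_error, r, per.df_error, config.alpha
            )
            tinfo["environments"][env] = {
                "anova": {
                    "rows": _anova_rows(per),
                    "cv_percent": per.cv_percent,
                    "r_squared": per.r_squared,
                },
                "genetic_params": {
                    k: getattr(params, k)
                    for k in (
                        "ms_gca", "ms_sca", "ms_error",
                        "sigma2_gca", "sigma2_sca", "sigma2_a", "sigma2_d",
                        "ratio", "h2_broad", "h2_narrow",
                        "flag_gca", "flag_sca", "cv_percent", "r_squared",
                    )
                },
                "effects": {
                    "mu_hat": eff.mu_hat,
                    "gca": {
                        f"P{i + 1}": {"value": float(eff.gca[i]), "stars": eff.star_gca[i]}
                        for i in range(p)
                    },
                    "sca": {
                        f"P{i + 1}xP{j + 1}": {
                            "value": float(eff.sca[i, j]),
                            "stars": str(eff.star_sca[i, j]),
                        }
                        for i in range(p)
                        for j in range(i + 1, p)
                    },
                    "lsd": lsds,
                },
                "heterosis": {
                    f"P{i}xP{j}": {
                        "f1": rec.f1_mean,
                        "mp": rec.mp,
                        "bp": rec.bp,
                        "heterosis_pct": rec.heterosis_pct,
                        "heterobeltiosis_pct": rec.heterobeltiosis_pct,
                        "sig_mp": rec.sig_mp,
                        "sig_bp": rec.sig_bp,
                        "favorable_mp": rec.favorable_mp,
                        "favorable_bp": rec.favorable_bp,
                    }
                    for rec in het
                    for (i, j) in [rec.hybrid]
                },
                "mean_comparison": {
                    "lsd": lsd_mean,
                    "means": means,
                    "letters": letters,
                },
            }
        summary["traits"][trait] = tinfo
    return summary


def _fmt(value, ndigits: int) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        if not np.isfinite(value):
            return ""
        return f"{round(value, ndigits):.{ndigits}f}"
    return str(value)


def render_bundle(summary: dict, out_dir: Path, rounding: int = 2) -> list[Path]:
    """Write the delimited report tables from a summary dict. Returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nd = rounding
    written: list[Path] = []

    def write(name: str, header: list[str], rows: list[list[str]]) -> None:
        path = out_dir / name
        lines = [",".join(header)] + [",".join(row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    traits = list(summary["traits"])
    environments = summary["design"]["environments"]

    # combined ANOVA: one file per trait
    for trait, tinfo in summary["traits"].items():
        if "combined_anova" in tinfo:
            rows = [
                [
                    r["source"],
                    str(r["df"]),
                    _fmt(r["ss"], nd),
                    _fmt(r["ms"], nd),
                    _fmt(r["f"], nd),
                    _fmt(r["p"], 4),
                    r["stars"],
                ]
                for r in tinfo["combined_anova"]["rows"]
            ]
            rows.append(["CV%", "", "", "", "", _fmt(tinfo["combined_anova"]["cv_percent"], nd), ""])
            rows.append(["R2", "", "", "", "", _fmt(tinfo["combined_anova"]["r_squared"], nd), ""])
            write(
                f"anova_combined_{trait}.csv",
                ["source", "df", "SS", "MS", "F", "p", "stars"],
                rows,
            )

    # per-environment genetic parameters: rows = traits
    param_cols = [
        "ms_gca", "ms_sca", "ms_error", "cv_percent", "r_squared",
        "sigma2_gca", "flag_gca", "sigma2_sca", "flag_sca",
        "sigma2_a", "sigma2_d", "ratio", "h2_broad", "h2_narrow",
    ]
    for env in environments:
        rows = []
        for trait in traits:
            gp = summary["traits"][trait]["environments"][env]["genetic_params"]
            rows.append(
                [trait] + [gp[c] if c.startswith("flag") else _fmt(gp[c], nd) for c in param_cols]
            )
        write(f"genetic_params_{env}.csv", ["trait"] + param_cols, rows)

    # GCA effects: parents x traits per environment, LSD footer
    for env in environments:
        header = ["parent"] + [f"{t}" for t in traits] + [f"{t}_stars" for t in traits]
        p = summary["design"]["p"]
        rows = []
        for i in range(1, p + 1):
            vals, stars = [], []
            for t in traits:
                cell = summary["traits"][t]["environments"][env]["effects"]["gca"][f"P{i}"]
                vals.append(_fmt(cell["value"], nd))
                stars.append(cell["stars"])
            rows.append([f"P{i}"] + vals + stars)
        lsd_row = ["LSD(gca_pair)"]
        for t in traits:
            lsd_row.append(
                _fmt(summary["traits"][t]["environments"][env]["effects"]["lsd"]["gca_pair"], nd)
            )
        rows.append(lsd_row + [""] * len(traits))
        write(f"gca_effects_{env}.csv", header, rows)

    # SCA effects: hybrids x traits per environment, two LSD footers
    for env in environments:
        header = ["hybrid"] + [f"{t}" for t in traits] + [f"{t}_stars" for t in traits]
        p = summary["design"]["p"]
        rows = []
        for i in range(1, p + 1):
            for j in range(i + 1, p + 1):
                vals, stars = [], []
                for t in traits:
                    cell = summary["traits"][t]["environments"][env]["effects"]["sca"][f"P{i}xP{j}"]
                    vals.append(_fmt(cell["value"], nd))
                    stars.append(cell["stars"])
                rows.append([f"P{i}xP{j}"] + vals + stars)
        for kind in ("sca_halfsib", "sca_disjoint"):
            lsd_row = [f"LSD({kind})"]
            for t in traits:
                lsd_row.append(
                    _fmt(summary["traits"][t]["environments"][env]["effects"]["lsd"][kind], nd)
                )
            rows.append(lsd_row + [""] * len(traits))
        write(f"sca_effects_{env}.csv", header, rows)

    # heterosis tables
    for env in environments:
        header = ["hybrid"]
        for t in traits:
            header += [f"{t}_mp_pct", f"{t}_mp_sig", f"{t}_bp_pct", f"{t}_bp_sig"]
        p = summary["design"]["p"]
        rows = []
        for i in range(1, p + 1):
            for j in range(i + 1, p + 1):
                row = [f"P{i}xP{j}"]
                for t in traits:
                    rec = summary["traits"][t]["environments"][env]["heterosis"][f"P{i}xP{j}"]
                    row += [
                        _fmt(rec["heterosis_pct"], nd),
                        rec["sig_mp"],
                        _fmt(rec["heterobeltiosis_pct"], nd),
                        rec["sig_bp"],
                    ]
                rows.append(row)
        write(f"heterosis_{env}.csv", header, rows)

    # mean comparison with letter groups
    for env in environments:
        header = ["entry"]
        for t in traits:
            header += [t, f"{t}_group"]
        entries = list(
            summary["traits"][traits[0]]["environments"][env]["mean_comparison"]["means"]
        )
        rows = []
        for entry in entries:
            row = [entry]
            for t in traits:
                mc = summary["traits"][t]["environments"][env]["mean_comparison"]
                row += [_fmt(mc["means"][entry], nd), mc["letters"][entry]]
            rows.append(row)
        write(f"mean_comparison_{env}.csv", header, rows)

    return written


def run_analyze(config: RunConfig) -> dict:
    """Read, analyze, render; returns the machine-readable summary."""
    plots = read_phenotypes(config.input_path, delimiter=config.delimiter)
    summary = build_summary(plots, config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = render_bundle(summary, out_dir, config.rounding)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    checksum = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    log_lines = [
        f"diallel version: {__version__}",
        f"input: {config.input_path}",
        f"input sha256: {checksum}",
        f"alpha: {config.alpha}",
        f"rounding: {config.rounding} d.p.",
        f"seed: {config.seed}",
        "conventions: fixed-effects F tests against the residual;"
        " effect tests use entry-mean error variance ms_error/r;"
        " negative variance components reported raw with truncation flags;"
        " best parent = max parent mean regardless of trait direction;"
        " strict inequality at LSD boundaries.",
        "tables written: " + ", ".join(p.name for p in written),
    ]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summary
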