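"""Mid-parent heterosis, heterobeltiosis, LSD tests and mean comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DiallelTable
from .errors import ConfigError, DiallelError

__all__ = [
    "TraitDirection",
    "HeterosisRecord",
    "heterosis",
    "heterosis_lsd",
    "favorability",
    "heterosis_table",
    "fisher_lsd_means",
    "letter_groups",
]


@dataclass(frozen=True)
class TraitDirection:
    trait: str
    higher_is_better: bool


@dataclass(frozen=True)
class HeterosisRecord:
    hybrid: tuple[int, int]
    f1_mean: float
    mp: float
    bp: float
    heterosis_pct: float | None
    heterobeltiosis_pct: float | None
    sig_mp: str = ""
    sig_bp: str = ""
    favorable_mp: bool | None = None
    favorable_bp: bool | None = None


def heterosis(f1: float, p1: float, p2: float) -> tuple[float | None, float | None]:
    """Percent superiority of the F1 over the mid-parent and the best parent.

    MP = (p1 + p2)/2; BP = max(p1, p2), irrespective of trait direction.
    Returns None for a percentage whose reference mean is zero.
    """
    mp = (p1 + p2) / 2.0
    bp = max(p1, p2)
    het = 100.0 * (f1 - mp) / mp if mp != 0 else None
    hbt = 100.0 * (f1 - bp) / bp if bp != 0 else None
    return het, hbt


def heterosis_lsd(
    ms_error: float, r: int, df_error: int, alpha: float = 0.05
) -> tuple[float, float]:
    """LSDs (trait units) for F1 - MP and F1 - BP differences.

    lsd_mp = t * sqrt(3 Me / (2 r)); lsd_bp = t * sqrt(2 Me / r).
    """
    if ms_error <= 0:
        raise DiallelError(f"ms_error must be positive, got {ms_error}")
    if not 0 < alpha < 1:
        raise DiallelError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return (
        float(t * np.sqrt(3.0 * ms_error / (2.0 * r))),
        float(t * np.sqrt(2.0 * ms_error / r)),
    )


def favorability(pct: float | None, direction: TraitDirection) -> bool:
    """A percentage is favorable when it moves the trait in its better direction."""
    if pct is None:
        return False
    if direction.higher_is_better:
        return pct > 0
    return pct < 0


def heterosis_table(
    table: DiallelTable,
    ms_error: float,
    r: int,
    df_error: int,
    direction: TraitDirection | None = None,
    alpha: float = 0.05,
) -> list[HeterosisRecord]:
    """Heterosis statistics for every hybrid of one environment's mean table.

    Significance compares |F1 - MP| against lsd_mp and |F1 - BP| against
    lsd_bp (strict inequality), with the alpha-0.01 LSD promoting * to **.
    """
    lsd_mp_05, lsd_bp_05 = heterosis_lsd(ms_error, r, df_error, alpha)
    lsd_mp_01, lsd_bp_01 = heterosis_lsd(ms_error, r, df_error, 0.01)
    records = []
    for i in range(1, table.p + 1):
        for j in range(i + 1, table.p + 1):
            f1 = table.entry(i, j)
            p1, p2 = table.entry(i, i), table.entry(j, j)
            mp, bp = (p1 + p2) / 2.0, max(p1, p2)
            het, hbt = heterosis(f1, p1, p2)

            def sig(diff: float, lsd05: float, lsd01: float) -> str:
                if abs(diff) > lsd01:
                    return "**"
                if abs(diff) > lsd05:
                    return "*"
                return "ns"

            rec = HeterosisRecord(
                hybrid=(i, j),
                f1_mean=f1,
                mp=mp,
                bp=bp,
                heterosis_pct=het,
                heterobeltiosis_pct=hbt,
                sig_mp=sig(f1 - mp, lsd_mp_05, lsd_mp_01),
                sig_bp=sig(f1 - bp, lsd_bp_05, lsd_bp_01),
                favorable_mp=favorability(het, direction) if direction else None,
                favorable_bp=favorability(hbt, direction) if direction else None,
            )
            records.append(rec)
    return records


def fisher_lsd_means(
    means: dict, ms_error: float, r: int, df_error: int, alpha: float = 0.05
) -> tuple[float, dict, dict]:
    """Fisher LSD all-pairwise comparison of entry means.

    Returns ``(lsd, significant, letters)`` where ``significant[(a, b)]`` is
    True iff |mean_a - mean_b| > LSD (strict), and ``letters`` is a compact
    letter display (presentation only; the pairwise booleans are the
    contract).
    """
    if ms_error < 0:
        raise DiallelError("ms_error must be non-negative")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    lsd = float(t * np.sqrt(2.0 * ms_error / r))
    keys = list(means)
    significant = {}
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            ka, kb = keys[a], keys[b]
            significant[(ka, kb)] = abs(means[ka] - means[kb]) > lsd
    return lsd, significant, letter_groups(means, lsd)


def letter_groups(means: dict, lsd: float) -> dict:
    """Compact letter display via the insert-and-absorb sweep.

    Entries are sorted by decreasing mean; a maximal run of entries whose
    spread is within the LSD shares a letter.
    """
    order = sorted(means, key=lambda k: -means[k])
    groups: list[list] = []
    for start in range(len(order)):
        run = [order[start]]
        for nxt in order[start + 1 :]:
            if abs(means[order[start]] - means[nxt]) <= lsd:
                run.append(nxt)
            else:
                break
        if not any(set(run) <= set(g) for g in groups):
            groups.append(run)
    letters = {k: "" for k in order}
    if len(groups) > 26:
        raise ConfigError("too many letter groups for a compact letter display")
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for k in grp:
            letters[k] += letter
    return letters
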