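"""Domain types and long-format IO for balanced half-diallel RCBD trials.

A trial is stored as one long-format table with one row per plot per trait:

    environment, replicate, parent_a, parent_b, trait, value

``parent_a == parent_b`` denotes a parent entry; crosses are canonicalized so
that ``parent_a <= parent_b``. Parent indices are 1-based throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AnalysisLookupError,
    DiallelError,
    DuplicateEntryError,
    ImbalanceError,
    ParentLabelError,
    ParseError,
    SchemaError,
)

REQUIRED_COLUMNS = ("environment", "replicate", "parent_a", "parent_b", "trait", "value")

_PARENT_RE = re.compile(r"^[Pp]?(\d+)$")


def parse_parent_label(label: object) -> int:
    """Map a parent label (``3``, ``"3"`` or ``"P3"``) onto its 1-based index."""
    if isinstance(label, (int, np.integer)):
        idx = int(label)
    else:
        m = _PARENT_RE.match(str(label).strip())
        if m is None:
            raise ParentLabelError(f"cannot map parent label {label!r} onto 1..p")
        idx = int(m.group(1))
    if idx < 1:
        raise ParentLabelError(f"parent index must be >= 1, got {idx}")
    return idx


@dataclass(frozen=True)
class PlotTable:
    """Canonicalized long-format plot observations.

    The backing frame always has the six required columns, with
    ``parent_a <= parent_b``, string environment/replicate/trait labels and
    finite float values.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["environment"]))

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["trait"]))

    @property
    def parents(self) -> tuple[int, ...]:
        seen = set(self.df["parent_a"]) | set(self.df["parent_b"])
        return tuple(sorted(seen))

    def subset(self, environment: str | None = None, trait: str | None = None) -> "PlotTable":
        df = self.df
        if environment is not None:
            if environment not in set(df["environment"]):
                raise AnalysisLookupError(f"unknown environment {environment!r}")
            df = df[df["environment"] == environment]
        if trait is not None:
            if trait not in set(df["trait"]):
                raise AnalysisLookupError(f"unknown trait {trait!r}")
            df = df[df["trait"] == trait]
        return PlotTable(df)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class DiallelDesign:
    """Shape of a balanced multi-environment half-diallel RCBD trial."""

    p: int
    environments: tuple[str, ...]
    replicates_per_env: int
    parent_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.parent_names:
            object.__setattr__(
                self, "parent_names", tuple(f"P{i}" for i in range(1, self.p + 1))
            )

    @property
    def n_entries(self) -> int:
        return self.p * (self.p + 1) // 2

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def entries(self) -> list[tuple[int, int]]:
        """All p(p+1)/2 entries (i, j) with i <= j, 1-based."""
        return [(i, j) for i in range(1, self.p + 1) for j in range(i, self.p + 1)]


@dataclass(frozen=True)
class DiallelTable:
    """Symmetric p x p table of entry means for one environment and trait.

    ``means[i-1, j-1]`` is the mean over replicates of entry (i, j); the
    diagonal holds parent means.
    """

    p: int
    trait: str
    environment: str
    means: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.shape != (self.p, self.p):
            raise DiallelError(f"means must be {self.p}x{self.p}, got {means.shape}")
        if not np.allclose(means, means.T, rtol=0, atol=1e-10):
            raise DiallelError("diallel table of entry means must be symmetric")
        object.__setattr__(self, "means", means)

    def entry(self, i: int, j: int) -> float:
        return float(self.means[i - 1, j - 1])


def _normalize_header(columns: list[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if key in REQUIRED_COLUMNS:
            mapping[col] = key
    return mapping


def read_phenotypes(path: str | Path, delimiter: str | None = None) -> PlotTable:
    """Read a long-format phenotype file into a canonicalized :class:`PlotTable`.

    The delimiter is auto-detected (comma or tab) unless forced. Column names
    are matched case-insensitively. Rows are canonicalized so that
    ``parent_a <= parent_b``; duplicate plots after canonicalization are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)

    rename = _normalize_header(list(raw.columns))
    missing = [c for c in REQUIRED_COLUMNS if c not in rename.values()]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(raw.columns)})"
        )
    raw = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)]
    return from_records(raw)


def from_records(df: pd.DataFrame) -> PlotTable:
    """Canonicalize a raw record frame into a :class:`PlotTable`."""
    df = df.copy().reset_index(drop=True)
    for col in ("environment", "replicate", "trait"):
        df[col] = df[col].astype(str).str.strip()

    values = np.empty(len(df), dtype=float)
    for k, v in enumerate(df["value"]):
        try:
            values[k] = float(v)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric value {v!r} in data row {k + 1}", row=k + 1)
        if not np.isfinite(values[k]):
            raise ParseError(f"non-finite value {v!r} in data row {k + 1}", row=k + 1)
    df["value"] = values

    pa = df["parent_a"].map(parse_parent_label).to_numpy()
    pb = df["parent_b"].map(parse_parent_label).to_numpy()
    df["parent_a"] = np.minimum(pa, pb)
    df["parent_b"] = np.maximum(pa, pb)

    key_cols = ["environment", "replicate", "parent_a", "parent_b", "trait"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0]
        raise DuplicateEntryError(
            "duplicate plot after canonicalization: "
            + ", ".join(f"{c}={first[c]}" for c in key_cols)
        )
    return PlotTable(df)


def validate_design(table: PlotTable) -> DiallelDesign:
    """Infer the trial shape and confirm full balance.

    Every (environment, replicate, entry, trait) combination must occur
    exactly once; missing plots raise :class:`ImbalanceError` listing the
    absent cells.
    """
    if len(table) == 0:
        raise DiallelError("empty plot table")
    df = table.df
    parents = table.parents
    p = max(parents)
    if set(parents) != set(range(1, p + 1)):
        raise ParentLabelError(
            f"parent indices must cover 1..{p} contiguously, found {sorted(parents)}"
        )
    environments = table.environments
    replicates = tuple(dict.fromkeys(df["replicate"]))
    traits = table.traits

    expected = {
        (env, rep, i, j, trait)
        for env in environments
        for rep in replicates
        for i in range(1, p + 1)
        for j in range(i, p + 1)
        for trait in traits
    }
    observed = {
        (row.environment, row.replicate, row.parent_a, row.parent_b, row.trait)
        for row in df.itertuples()
    }
    missing = sorted(expected - observed)
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ImbalanceError(
            f"design is unbalanced: {len(missing)} plot(s) missing, e.g. {shown}",
            missing=missing,
        )
    # expected == observed and no duplicates => fully balanced
    return DiallelDesign(p=p, environments=environments, replicates_per_env=len(replicates))


def entry_means(table: PlotTable, environment: str, trait: str) -> DiallelTable:
    """Average the replicate plot values of each entry into a symmetric table."""
    sub = table.subset(environment=environment, trait=trait)
    design = validate_design(sub)
    p = design.p
    means = np.zeros((p, p))
    grouped = sub.df.groupby(["parent_a", "parent_b"])["value"].mean()
    for (i, j), m in grouped.items():
        means[i - 1, j - 1] = m
        means[j - 1, i - 1] = m
    return DiallelTable(p=p, trait=trait, environment=environment, means=means)
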