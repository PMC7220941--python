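"""Shared data containers for the pattern-matching pipeline.

The universal carrier is :class:`ExpressionMatrix`: positive, linear-scale
probe-set signals (rows) across samples (columns), with a group label per
sample and an optional probe-set -> gene-symbol map. All pipeline stages
consume and produce these containers or plain pandas objects derived from
them, so every intermediate is a TSV-serialisable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "PipelineError",
    "ConfigurationError",
]


class PipelineError(ValueError):
    """Base class for user-facing pipeline errors."""


class ConfigurationError(PipelineError):
    """Invalid configuration or specification input."""


@dataclass
class ExpressionMatrix:
    """Positive linear-scale signals, probe-sets x samples.

    Parameters
    ----------
    values
        DataFrame indexed by probe-set ID with one column per sample.
        All entries must be strictly positive and finite.
    groups
        Series mapping sample ID -> group label; must cover every column.
    gene_map
        Optional Series mapping probe-set ID -> gene symbol. Probe-sets
        without a mapping are carried through under their own ID.
    """

    values: pd.DataFrame
    groups: pd.Series
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise PipelineError(f"duplicate probe-set IDs: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise PipelineError(f"duplicate sample IDs: {list(dupes[:5])}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise PipelineError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise PipelineError("expression values must be finite")
        if np.any(arr <= 0):
            raise PipelineError(
                "expression values must be strictly positive; floor signals first"
            )
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise PipelineError(f"samples without group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def probe_sets(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def log2(self) -> pd.DataFrame:
        """Log2-transformed signals (safe: values are validated positive)."""
        return np.log2(self.values)

    def floored(self, floor: float = 1.0) -> "ExpressionMatrix":
        """Return a copy with signals clipped from below at ``floor``."""
        if floor <= 0:
            raise ConfigurationError("signal floor must be positive")
        return ExpressionMatrix(
            self.values.clip(lower=floor), self.groups.copy(), self.gene_map
        )

    def subset(self, samples: list[str]) -> "ExpressionMatrix":
        unknown = [s for s in samples if s not in self.values.columns]
        if unknown:
            raise PipelineError(f"unknown samples: {unknown[:5]}")
        return ExpressionMatrix(
            self.values[samples], self.groups.loc[samples], self.gene_map
        )

    def symbol_for(self, probe_set: str) -> str:
        if self.gene_map is not None and probe_set in self.gene_map.index:
            return str(self.gene_map[probe_set])
        return probe_set


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT record).

    Symbols are uppercase-normalised on construction; empty sets are
    rejected because an empty annotation filter is always a user error.
    """

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise PipelineError("gene set needs a name")
        normalised = frozenset(str(m).upper() for m in self.members if str(m).strip())
        if not normalised:
            raise PipelineError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", normalised)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in self.members

    def __len__(self) -> int:
        return len(self.members)
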