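"""Shared containers and exceptions for the stratified-omics pipeline.

Matrices are analytes x samples :class:`pandas.DataFrame` objects wrapped in
:class:`AnalyteMatrix` to carry dataset/batch provenance.  Missing values are
``NaN`` internally and blank fields on disk; zero is a valid abundance and is
never conflated with missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class StratomicsError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(StratomicsError):
    """Invalid configuration value."""


class FormatError(StratomicsError):
    """Malformed input file."""


class StateError(StratomicsError):
    """Operation called out of order."""


class DegenerateInputError(StratomicsError):
    """Input is structurally valid but statistically unusable."""


@dataclass
class AnalyteMatrix:
    """Analytes x samples abundance matrix with provenance.

    Parameters
    ----------
    data
        DataFrame indexed by analyte id, columns are sample ids.  Raw
        matrices hold strictly positive RFU-like values; normalized
        matrices hold log10 values.  ``NaN`` marks missing.
    dataset
        Optional dataset identifier (collection wave), used when merging.
    scale
        ``"raw"`` or ``"log10"``; bookkeeping only, enforced by the
        normalization module.
    """

    data: pd.DataFrame
    dataset: str | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate analyte ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")

    @property
    def analytes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "AnalyteMatrix":
        return AnalyteMatrix(self.data.copy(), dataset=self.dataset, scale=self.scale)


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics).

    ``sets`` is a list of ``(name, description, members)`` with unique names
    and non-empty member sets.  Gene symbols are matched case-sensitively
    throughout the package.
    """

    sets: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise FormatError(f"duplicate gene-set name: {dup!r}")
        for name, _, members in self.sets:
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def members(self, name: str) -> frozenset[str]:
        for set_name, _, members in self.sets:
            if set_name == name:
                return members
        raise KeyError(name)


# Fixed column order for all written association/meta result tables.
RESULT_COLUMNS = [
    "analyte_id",
    "stratum",
    "stage",
    "beta",
    "se",
    "p",
    "fdr",
    "called",
    "direction",
]
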