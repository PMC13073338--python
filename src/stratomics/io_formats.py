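"""Readers and writers for the plain-text formats the pipeline touches.

All tables are tab-separated.  Abundance matrices carry analyte ids in the
first column and one header row of sample ids; blank cells are missing
values (``NaN`` in memory — zero is a legal abundance and is kept distinct).
Gene sets use the standard GMT dialect; interactomes are two-column
undirected edge lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, FormatError, GeneSetCollection

logger = logging.getLogger(__name__)


def read_analyte_matrix(path: str | Path, dataset: str | None = None,
                        scale: str = "raw") -> AnalyteMatrix:
    """Read a tab-separated analyte x sample matrix.

    Blank fields become ``NaN``; any non-numeric non-blank cell raises
    :class:`FormatError` naming the offending row and column.  Duplicate
    analyte or sample ids are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        seen: set[str] = set()
        dup = next(h for h in header if h in seen or seen.add(h))
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, na_values=[""])
    raw.columns = header
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate analyte id(s) {dupes[:5]}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} "
                f"at analyte {row!r}, sample {col!r}"
            )
        values[col] = converted.astype(float)
    logger.info("read %s: %d analytes x %d samples", path, *values.shape)
    return AnalyteMatrix(values, dataset=dataset, scale=scale)


def write_analyte_matrix(matrix: AnalyteMatrix, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_analyte_matrix` reads.

    Missing values are written as blank fields; numeric values use repr-level
    precision so a round trip reproduces them bit-for-bit.
    """
    df = matrix.data.copy()
    df.index.name = "analyte_id"
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata table (sample_id, status, age, sex,
    stratum, batch, dataset)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "status": str,
                                              "sex": str, "stratum": str,
                                              "batch": str, "dataset": str})
    required = {"sample_id", "status", "age", "sex", "stratum", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id values")
    return meta.set_index("sample_id", drop=False)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>member...``.

    Duplicate members within one line are deduplicated; duplicate set names
    across lines are an error.  Order of sets is preserved.
    """
    path = Path(path)
    sets: list[tuple[str, str, frozenset[str]]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            sets.append((name, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, description, members in collection:
            handle.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column tab-separated undirected edge list.

    Self-loops are dropped with a logged warning; duplicate edges (in either
    orientation) collapse to one.
    """
    path = Path(path)
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: edge line needs exactly 2 fields, "
                    f"got {len(fields)}"
                )
            a, b = fields
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        for a, b in sorted(tuple(sorted(edge)) for edge in graph.edges()):
            handle.write(f"{a}\t{b}\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the analyte annotation table (analyte_id, gene, super_pathway,
    sub_pathway)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "analyte_id" not in ann.columns:
        raise FormatError(f"{path}: annotation table needs an analyte_id column")
    if ann["analyte_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate analyte_id in annotation table")
    return ann.set_index("analyte_id", drop=False)


def read_celltype_reference(path: str | Path) -> pd.DataFrame:
    """Read a genes x cell-types mean-expression matrix."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    if ref.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids in cell-type reference")
    if (ref.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression in cell-type reference")
    return ref


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association/meta results table with the fixed column order
    (extra columns are appended after the fixed block)."""
    from .datatypes import RESULT_COLUMNS

    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, na_rep="NA",
                         float_format="%.10g")
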