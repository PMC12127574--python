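"""Readers and writers for the formats the tool touches.

Dense expression matrices travel as TSV/CSV with gene identifiers in the
first column and a header row of sample identifiers; sparse matrices as
MatrixMarket coordinate files with gene/barcode sidecar lists (10x-style
triplet layout). Gene sets use the GMT format (tab-separated: name,
description, member genes). Identifiers are opaque strings, matched
case-sensitively unless ``fold_case=True`` is requested explicitly, and are
never coerced to numbers. The declared orientation of a matrix file is
honored without auto-guessing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, GeneSetCollection
from .errors import ConfigurationError, DataError, ParseError

__all__ = [
    "read_expression",
    "read_dense_expression",
    "read_mtx_expression",
    "write_dense_expression",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "attach_labels",
    "write_enrichment",
    "read_enrichment",
]


def _dup_lines(ids: pd.Index, offset: int) -> str:
    """Describe duplicated identifiers with their 1-based line numbers."""
    dup_mask = ids.duplicated(keep=False)
    positions = np.flatnonzero(dup_mask)[:10]
    return ", ".join(f"{ids[i]!r} (line {i + offset})" for i in positions)


def read_dense_expression(
    path,
    sep: str | None = None,
    orientation: str = "genes_by_samples",
    fold_case: bool = False,
) -> pd.DataFrame:
    """Read a dense TSV/CSV matrix into a genes x samples DataFrame.

    ``sep`` defaults to ',' for ``.csv`` files and tab otherwise. With
    ``orientation='samples_by_genes'`` the file holds samples as rows and is
    transposed on read. Duplicate identifiers, ragged rows and non-numeric
    cells are parse errors naming the offending location.
    """
    path = Path(path)
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed matrix file: {exc}", path=path) from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError("empty matrix file", path=path) from exc
    if raw.shape[1] < 2:
        raise ParseError("matrix file needs an identifier column and data columns", path=path)
    df = raw.iloc[:, 1:]
    df.index = pd.Index(raw.iloc[:, 0].astype(str).str.strip())
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        raise ParseError(f"duplicate row identifiers: {_dup_lines(df.index, 2)}", path=path)
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicate column identifiers in header: {dupes[:10]}", path=path)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}",
            path=path,
            line=r + 2,
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r} "
            "(ragged row?)",
            path=path,
            line=r + 2,
        )
    numeric = numeric.astype(float)
    if orientation == "samples_by_genes":
        numeric = numeric.T
    if fold_case:
        numeric.index = numeric.index.str.upper()
    return numeric


def read_mtx_expression(
    mtx_path, genes_path, samples_path, fold_case: bool = False
) -> pd.DataFrame:
    """Read a MatrixMarket triplet (matrix + gene list + barcode list).

    The .mtx file holds genes as rows and samples as columns; the sidecar
    files list one identifier per line in matrix order (a second
    tab-separated column, as in 10x features files, is ignored). Explicit
    zero entries and absent entries both read as 0 in the dense view.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise ParseError(f"malformed MatrixMarket file: {exc}", path=mtx_path) from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)

    def _ids(p) -> list[str]:
        out = []
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if line:
                out.append(line.split("\t")[0])
        return out

    genes, samples = _ids(genes_path), _ids(samples_path)
    if len(genes) != mat.shape[0]:
        raise ParseError(
            f"gene list length {len(genes)} does not match matrix rows {mat.shape[0]}",
            path=genes_path,
        )
    if len(samples) != mat.shape[1]:
        raise ParseError(
            f"sample list length {len(samples)} does not match matrix columns "
            f"{mat.shape[1]}",
            path=samples_path,
        )
    df = pd.DataFrame(mat, index=genes, columns=samples)
    if df.index.has_duplicates:
        raise ParseError(f"duplicate gene identifiers: {_dup_lines(df.index, 1)}", path=genes_path)
    if df.columns.has_duplicates:
        raise ParseError(
            f"duplicate sample identifiers: {_dup_lines(df.columns, 1)}", path=samples_path
        )
    if fold_case:
        df.index = df.index.str.upper()
    return df


def read_expression(
    path,
    layout: str = "dense_tsv",
    orientation: str = "genes_by_samples",
    genes_path=None,
    samples_path=None,
    fold_case: bool = False,
) -> pd.DataFrame:
    """Dispatch on layout: ``dense_tsv``, ``dense_csv`` or ``mtx_triplet``."""
    if layout == "dense_tsv":
        return read_dense_expression(path, sep="\t", orientation=orientation, fold_case=fold_case)
    if layout == "dense_csv":
        return read_dense_expression(path, sep=",", orientation=orientation, fold_case=fold_case)
    if layout == "mtx_triplet":
        if genes_path is None or samples_path is None:
            raise ConfigurationError("mtx_triplet layout needs genes_path and samples_path")
        return read_mtx_expression(path, genes_path, samples_path, fold_case=fold_case)
    raise ConfigurationError(f"unknown layout {layout!r}")


def write_dense_expression(values: pd.DataFrame | ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a genes x samples matrix as dense TSV/CSV (round-trip safe)."""
    df = values.values if isinstance(values, ExpressionMatrix) else values
    df.to_csv(path, sep=sep, index_label="gene_id", lineterminator="\n")


def read_gmt(path, fold_case: bool = False) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...).

    Lines with fewer than three tab-separated fields are parse errors with
    their line number; duplicate set names are errors; duplicate members
    within a set are collapsed with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line has {len(fields)} field(s); need name, description and "
                "at least one member",
                path=path,
                line=lineno,
            )
        name = fields[0].strip()
        if name in sets:
            raise ParseError(f"duplicate gene set name {name!r}", path=path, line=lineno)
        members = [f.upper() for f in fields[2:]] if fold_case else fields[2:]
        sets[name] = members
        descriptions[name] = fields[1]
    if not sets:
        raise ParseError("no gene sets in file", path=path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT; write(read(x)) is the identity on canonical files."""
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV into a Series."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError("empty labels file", path=path) from exc
    # tolerate an optional header line
    if df.shape[1] < 2:
        raise ParseError("labels file needs two tab-separated columns", path=path)
    first = df.iloc[0]
    if str(first[0]).lower() in ("sample", "sample_id", "cell", "cell_id", "barcode"):
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str).str.strip()
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate sample identifiers: {dupes[:10]}", path=path)
    return pd.Series(df.iloc[:, 1].astype(str).str.strip().to_numpy(), index=ids.to_numpy())


def attach_labels(
    values: pd.DataFrame,
    labels: pd.Series,
    reference_level: str | None = None,
) -> ExpressionMatrix:
    """Combine a matrix with per-sample labels and assign condition roles.

    Every matrix sample must appear in the labels; samples present in the
    labels but absent from the matrix are ignored with a warning.
    """
    missing = values.columns.difference(labels.index)
    if len(missing):
        raise DataError(f"samples missing from labels: {missing.tolist()[:10]}")
    extra = labels.index.difference(values.columns)
    if len(extra):
        warnings.warn(f"{len(extra)} labeled sample(s) absent from the matrix; ignored")
    labels = labels.reindex(values.columns)
    if reference_level is not None and reference_level not in set(labels):
        raise ConfigurationError(
            f"reference level {reference_level!r} not among label levels "
            f"{sorted(labels.unique().tolist())}"
        )
    return ExpressionMatrix(values, labels, reference_level)


def write_enrichment(em, path, sidecar_path=None) -> None:
    """Write an enrichment matrix as TSV plus a JSON metadata sidecar.

    The sidecar records the denominator mode, measured gene counts per set
    and any dropped sets.
    """
    em.scores.to_csv(path, sep="\t", index_label="gene_set", lineterminator="\n")
    if sidecar_path is not None:
        import json

        meta = {
            "denominator_mode": em.denominator_mode,
            "genes_measured": {k: int(v) for k, v in em.genes_measured.items()},
            "dropped_sets": list(em.dropped_sets),
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_enrichment(path) -> pd.DataFrame:
    """Read an enrichment TSV back into a sets x samples DataFrame."""
    return read_dense_expression(path, sep="\t")
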