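"""Containers and IO for Ct tables, count matrices and gene annotation.

Formats
-------
Ct tables (CSV):
    wide    one row per well, header row of gene symbols, optional ``batch``
            column; this is the canonical dialect.
    long    columns ``well,gene,ct`` plus optional ``batch``.

No-amplification reactions carry the sentinel Ct 999 (common Biomark export
practice); on read, empty fields and the string ``Undetermined`` are
normalised to the sentinel as well.

Count matrices:
    tsv     genes in rows, cells in columns, first column gene ids.
    mtx     MatrixMarket triplet with ``.genes`` / ``.cells`` sidecar files
            (one id per line) next to the ``.mtx``.

Gene annotation: TSV with columns ``gene_id``, ``is_mito`` (0/1) and
``length_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Sentinel Ct value meaning "no amplification detected".
SENTINEL = 999.0

#: Strings normalised to the sentinel on read.
_SENTINEL_STRINGS = {"999", "999.0", "", "NA", "Undetermined"}

DEFAULT_BATCH = "batch1"


@dataclass
class CtMatrix:
    """Cycle-threshold values for wells × genes with a per-well batch label.

    ``ct`` is a float DataFrame indexed by well id with gene-symbol columns;
    entries are either the sentinel 999 or a Ct in (0, 999).
    """

    ct: pd.DataFrame
    batch: pd.Series

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if not self.ct.index.is_unique:
            raise ValueError("well ids must be unique")
        if not self.ct.columns.is_unique:
            raise ValueError("gene ids must be unique")
        vals = self.ct.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size != vals.size:
            raise ValueError("Ct values must be finite (use the 999 sentinel)")
        bad = (vals != SENTINEL) & ((vals <= 0) | (vals >= SENTINEL))
        if bad.any():
            raise ValueError("Ct values must be 999 or in (0, 999)")
        self.batch = self.batch.reindex(self.ct.index)
        if self.batch.isna().any():
            raise ValueError("every well needs a batch label")
        self.batch = self.batch.astype(str)

    @property
    def well_ids(self) -> pd.Index:
        return self.ct.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.ct.columns

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.ct.copy(), self.batch.copy())

    def subset_wells(self, wells) -> "CtMatrix":
        wells = pd.Index(wells)
        return CtMatrix(self.ct.loc[wells], self.batch.loc[wells])

    def equals(self, other: "CtMatrix") -> bool:
        return self.ct.equals(other.ct) and self.batch.equals(other.batch)


@dataclass
class CountMatrix:
    """Integer fragment counts, genes × cells."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.round().astype(np.int64)
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("cell ids must be unique")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: mitochondrial flag and gene length in bases."""

    table: pd.DataFrame  # index gene_id, columns is_mito (bool), length_bp

    def __post_init__(self) -> None:
        required = {"is_mito", "length_bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("annotation gene ids must be unique")
        self.table = self.table.assign(
            is_mito=self.table["is_mito"].astype(bool),
            length_bp=self.table["length_bp"].astype(float),
        )
        if (self.table["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def is_mito(self) -> pd.Series:
        return self.table["is_mito"]

    @property
    def length_bp(self) -> pd.Series:
        return self.table["length_bp"]


def _normalise_ct(raw: object, where: str) -> float:
    if isinstance(raw, str):
        s = raw.strip()
        if s in _SENTINEL_STRINGS:
            return SENTINEL
        try:
            return float(s)
        except ValueError:
            raise ValueError(f"non-numeric Ct value {raw!r} at {where}") from None
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return SENTINEL
    return float(raw)


def read_ct_table(path, dialect: str = "wide") -> CtMatrix:
    """Read a Ct table from CSV in the ``wide`` or ``long`` dialect."""
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate well ids: {dups}")
        if "batch" in df.columns:
            batch = df["batch"].astype(str)
            df = df.drop(columns="batch")
        else:
            batch = pd.Series(DEFAULT_BATCH, index=df.index)
        ct = pd.DataFrame(
            [
                [_normalise_ct(v, f"row {i + 2}, gene {g}") for g, v in row.items()]
                for i, (_, row) in enumerate(df.iterrows())
            ],
            index=df.index.rename(None),
            columns=df.columns.rename(None),
        )
        return CtMatrix(ct, batch.rename_axis(None))
    if dialect == "long":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"well", "gene", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long dialect needs columns {sorted(required)}; missing {sorted(missing)}")
        dup = df.duplicated(subset=["well", "gene"], keep=False)
        if dup.any():
            pair = tuple(df.loc[dup, ["well", "gene"]].iloc[0])
            raise ValueError(f"duplicate (well, gene) pair: {pair}")
        df = df.assign(
            ct_value=[
                _normalise_ct(v, f"row {i + 2}") for i, v in enumerate(df["ct"])
            ]
        )
        ct = df.pivot(index="well", columns="gene", values="ct_value")
        if ct.isna().any().any():
            ct = ct.fillna(SENTINEL)
        if "batch" in df.columns:
            batch = df.drop_duplicates("well").set_index("well")["batch"]
            batch = batch.reindex(ct.index).astype(str)
        else:
            batch = pd.Series(DEFAULT_BATCH, index=ct.index)
        ct.index.name = None
        ct.columns.name = None
        return CtMatrix(ct, batch)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


def write_ct_table(matrix: CtMatrix, path, dialect: str = "wide") -> None:
    """Write a Ct table to CSV; lossless under :func:`read_ct_table`."""
    path = Path(path)

    def fmt(v: float) -> str:
        if v == SENTINEL:
            return "999"
        return repr(float(v))

    if dialect == "wide":
        out = matrix.ct.map(fmt)
        out.insert(0, "batch", matrix.batch)
        out.to_csv(path, index_label="well")
        return
    if dialect == "long":
        long = matrix.ct.stack().reset_index()
        long.columns = ["well", "gene", "ct"]
        long["ct"] = long["ct"].map(fmt)
        long["batch"] = matrix.batch.loc[long["well"]].to_numpy()
        long.to_csv(path, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


def _check_integral(values: np.ndarray, what: str) -> None:
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{what} contains fractional counts")


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV (genes × cells) or MatrixMarket triplet."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        df.columns.name = None
        _check_integral(df.to_numpy(dtype=float), str(path))
        return CountMatrix(df)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        genes = Path(str(path).removesuffix(".mtx") + ".genes").read_text().split()
        cells = Path(str(path).removesuffix(".mtx") + ".cells").read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        _check_integral(dense, str(path))
        df = pd.DataFrame(dense, index=genes, columns=cells)
        return CountMatrix(df)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'mtx')")


def write_counts(matrix: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = matrix.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        return
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        stem = str(path).removesuffix(".mtx")
        Path(stem + ".genes").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(stem + ".cells").write_text("\n".join(matrix.cell_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'mtx')")


def read_gene_annotation(path, matrix: CountMatrix | None = None) -> GeneAnnotation:
    """Read the annotation TSV; if ``matrix`` is given, require full coverage."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("annotation must have a gene_id column")
    ann = GeneAnnotation(df.set_index("gene_id"))
    if matrix is not None:
        missing = matrix.gene_ids.difference(ann.gene_ids)
        if len(missing):
            raise ValueError(f"annotation missing genes: {sorted(missing)}")
    return ann


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.table.copy()
    out["is_mito"] = out["is_mito"].astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
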