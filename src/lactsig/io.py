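"""Readers and writers for every external representation the pipeline touches.

Counts travel as the 10x Genomics triplet dialect (MatrixMarket coordinate
MTX + features TSV + barcodes TSV, optionally gzipped); per-barcode sample
metadata and DE result tables travel as headered CSV. In memory the package
uses a single convention everywhere: an :class:`anndata.AnnData` with cells
as observations and unique gene symbols as variables, integer counts in
``X``. The on-disk 10x orientation (genes x cells) is converted at this
boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import IO

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, JoinError
from .signatures import normalize_mouse_symbol

__all__ = [
    "read_10x_triplet",
    "write_10x_triplet",
    "read_metadata",
    "write_metadata",
    "attach_metadata",
    "read_de_table",
    "write_de_table",
    "GENOTYPES",
    "STATES",
]

GENOTYPES = ("C57", "NZB")
STATES = ("NL", "LacD21")

METADATA_COLUMNS = ("barcode", "sample_id", "genotype", "state", "mouse")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv_column(path: str | Path, column: int, what: str) -> list[str]:
    rows: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if column >= len(fields):
                # features files may carry a single symbol column
                if what == "feature" and len(fields) == 1:
                    rows.append(fields[0])
                    continue
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected at least {column + 1}"
                )
            rows.append(fields[column])
    return rows


def read_10x_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    *,
    genes_as_rows: bool = True,
) -> ad.AnnData:
    """Read a 10x triplet into a cells x genes AnnData of integer counts.

    Parameters
    ----------
    genes_as_rows
        On-disk orientation flag. ``True`` (the 10x convention) means the
        MTX rows are genes and columns are cells; ``False`` means the file
        is already cells x genes. Either way the returned matrix is
        cells x genes.

    Duplicate gene symbols in the features file are collapsed by summing
    their counts, so the gene axis is unique after loading. Symbols are
    normalized to the mouse convention (capitalized first letter).
    """
    with _open_maybe_gzip(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"{matrix_path}: not valid MatrixMarket: {exc}") from exc
    mat = sp.coo_matrix(mat)
    data = np.asarray(mat.data)
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise FormatError(f"{matrix_path}: entries must be nonnegative integers")

    symbols = _read_tsv_column(features_path, 1, "feature")
    barcodes = _read_tsv_column(barcodes_path, 0, "barcode")

    n_genes_disk, n_cells_disk = (
        (mat.shape[0], mat.shape[1]) if genes_as_rows else (mat.shape[1], mat.shape[0])
    )
    if len(symbols) != n_genes_disk:
        raise FormatError(
            f"{features_path}: {len(symbols)} features but matrix declares "
            f"{n_genes_disk} genes"
        )
    if len(barcodes) != n_cells_disk:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares "
            f"{n_cells_disk} cells"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: barcodes are not unique")

    X = sp.csr_matrix(mat.T if genes_as_rows else mat, dtype=np.int64)

    symbols = [normalize_mouse_symbol(s) for s in symbols]
    sym_arr = pd.Index(symbols)
    if sym_arr.has_duplicates:
        # collapse duplicate symbols by summing counts per symbol
        uniq, inverse = np.unique(sym_arr.to_numpy(), return_inverse=True)
        collapse = sp.csr_matrix(
            (np.ones(len(symbols)), (np.arange(len(symbols)), inverse)),
            shape=(len(symbols), len(uniq)),
        )
        X = sp.csr_matrix(X @ collapse, dtype=np.int64)
        symbols = list(uniq)

    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(symbols, name="gene")),
    )
    return adata


def write_10x_triplet(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write counts as matrix.mtx / features.tsv / barcodes.tsv (genes x cells)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(str(out / "matrix.mtx"), X, field="integer")
    with open(out / "features.tsv", "w", encoding="utf-8") as fh:
        for sym in adata.var_names:
            fh.write(f"{sym}\t{sym}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for bc in adata.obs_names:
            fh.write(f"{bc}\n")


def read_metadata(csv_path: str | Path) -> pd.DataFrame:
    """Read the per-barcode sample metadata CSV.

    Required columns: barcode, sample_id, genotype, state, mouse. Genotype
    and state must come from the closed vocabularies ``{C57, NZB}`` and
    ``{NL, LacD21}``; duplicate barcodes are rejected.
    """
    df = pd.read_csv(csv_path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    if df["barcode"].duplicated().any():
        dupes = sorted(df.loc[df["barcode"].duplicated(), "barcode"].unique()[:5])
        raise FormatError(f"{csv_path}: duplicate barcodes, e.g. {dupes}")
    bad_geno = sorted(set(df["genotype"]) - set(GENOTYPES))
    if bad_geno:
        raise FormatError(
            f"{csv_path}: genotype values {bad_geno} not in {list(GENOTYPES)}"
        )
    bad_state = sorted(set(df["state"]) - set(STATES))
    if bad_state:
        raise FormatError(
            f"{csv_path}: state values {bad_state} not in {list(STATES)}"
        )
    return df.loc[:, list(METADATA_COLUMNS)].reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, csv_path: str | Path) -> None:
    meta.loc[:, list(METADATA_COLUMNS)].to_csv(csv_path, index=False)


def attach_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    """Join metadata onto the matrix; every barcode must have exactly one row."""
    meta = meta.set_index("barcode")
    missing = [bc for bc in adata.obs_names if bc not in meta.index]
    if missing:
        raise JoinError(
            f"{len(missing)} matrix barcodes absent from metadata, "
            f"e.g. {missing[:5]}"
        )
    out = adata.copy()
    aligned = meta.reindex(adata.obs_names)
    for col in ("sample_id", "genotype", "state", "mouse"):
        out.obs[col] = aligned[col].to_numpy()
    return out


DE_COLUMNS = ("gene", "log2fc", "pvalue", "padj")


def _validate_de(df: pd.DataFrame, where: str) -> None:
    if df["gene"].duplicated().any():
        raise FormatError(f"{where}: duplicate gene rows")
    for col in ("pvalue", "padj"):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1) | ~np.isfinite(vals)):
            raise FormatError(f"{where}: {col} outside [0, 1]")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table (gene, log2fc, pvalue, padj) as CSV.

    Floats are serialized with 12 significant digits so a read/write
    round trip is an identity at that precision.
    """
    _validate_de(table, str(path))
    table.loc[:, list(DE_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table CSV; compute BH-adjusted p-values if absent.

    A table whose ``padj`` is smaller than ``pvalue`` somewhere (foreign
    adjustment) triggers a warning, not an error. When ``padj`` is missing
    it is filled in by Benjamini-Hochberg adjustment of ``pvalue`` and the
    result is flagged in ``df.attrs['padj_imputed']``.
    """
    df = pd.read_csv(path)
    required = [c for c in DE_COLUMNS if c != "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df.attrs["padj_imputed"] = False
    if "padj" not in df.columns:
        from .stats import bh_adjust

        df["padj"] = bh_adjust(df["pvalue"].to_numpy(dtype=float))
        df.attrs["padj_imputed"] = True
    _validate_de(df, str(path))
    if (df["padj"].to_numpy(dtype=float) < df["pvalue"].to_numpy(dtype=float) - 1e-12).any():
        warnings.warn(
            f"{path}: padj < pvalue for some rows; adjustment method is not BH",
            stacklevel=2,
        )
    return df.loc[:, list(DE_COLUMNS)]
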