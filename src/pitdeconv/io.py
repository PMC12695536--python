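"""Readers and writers for expression matrices, annotations and signatures.

Plain-text TSV/CSV is the canonical interchange for dense matrices; the
MatrixMarket triple (matrix.mtx + genes.tsv + barcodes.tsv) is supported
for sparse single-cell inputs. Duplicate gene ids are summed with a
logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .prep import SignatureMatrix
from .simulate import AnnotatedCounts

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_annotated_counts",
    "write_annotated_counts",
    "read_signature",
    "write_signature",
]


def _dedupe_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("summing %d duplicated gene id row(s)", n)
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_expression(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Load a genes x columns expression matrix.

    ``fmt`` is ``mtx_dir``, ``dense_tsv`` or ``dense_csv``; inferred from
    the path when omitted (a directory implies MTX, else the suffix).
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif path.suffix == ".csv":
            fmt = "dense_csv"
        else:
            fmt = "dense_tsv"
    if fmt == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(f"MTX directory is missing {f.name}")
        m = spio.mmread(mtx)
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(cells_f, sep="\t", header=None)[0].astype(str)
        arr = np.asarray(m.todense() if sparse.issparse(m) else m)
        if arr.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix.mtx shape {arr.shape} does not match "
                f"{len(genes)} genes x {len(cells)} barcodes"
            )
        df = pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=cells)
    elif fmt in ("dense_tsv", "dense_csv"):
        sep = "\t" if fmt == "dense_tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "gene"
    else:
        raise ValueError(f"read_expression: unknown format {fmt!r}")
    return _dedupe_genes(df)


def write_expression(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "mtx_dir" if path.suffix == "" else (
            "dense_csv" if path.suffix == ".csv" else "dense_tsv"
        )
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csc_matrix(df.to_numpy()))
        pd.Series(df.index).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(df.columns).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    else:
        sep = "," if fmt == "dense_csv" else "\t"
        df.to_csv(path, sep=sep)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="cell_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="cell_id")
    ann.index = ann.index.astype(str)
    return ann


def write_annotated_counts(data: AnnotatedCounts, outdir: str | Path, fmt: str = "mtx_dir") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx_dir":
        write_expression(data.matrix, outdir, fmt="mtx_dir")
    else:
        write_expression(data.matrix, outdir / "counts.tsv", fmt=fmt)
    write_annotation(data.annotation, outdir / "annotation.tsv")


def read_annotated_counts(path: str | Path) -> AnnotatedCounts:
    path = Path(path)
    if (path / "matrix.mtx").exists():
        matrix = read_expression(path, fmt="mtx_dir")
    else:
        matrix = read_expression(path / "counts.tsv", fmt="dense_tsv")
    ann = read_annotation(path / "annotation.tsv")
    return AnnotatedCounts(matrix, ann.loc[matrix.columns])


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    """Signature TSV (gene column + one column per type) with a sidecar
    JSON of per-type member sets."""
    path = Path(path)
    sig.values.to_csv(path, sep="\t", index_label="gene")
    sidecar = path.with_suffix(path.suffix + ".members.json")
    sidecar.write_text(json.dumps({"name": sig.name, "members": sig.members}, indent=1))


def read_signature(path: str | Path) -> SignatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene")
    sidecar = path.with_suffix(path.suffix + ".members.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        members = {t: list(g) for t, g in meta["members"].items()}
        name = meta.get("name", path.stem)
    else:
        members = {t: list(values.index) for t in values.columns}
        name = path.stem
    return SignatureMatrix(values=values, members=members, name=name)
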