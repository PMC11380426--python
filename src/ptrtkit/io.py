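"""Readers and writers for the standard formats the pipeline touches.

Expression input: 10x-convention MTX directory (matrix.mtx + features.tsv +
barcodes.tsv, optionally gzipped) or a dense genes-in-columns TSV. TCR input:
10x ``filtered_contig_annotations.csv`` or an AIRR rearrangement TSV (the
TRUST4 AIRR export for bulk repertoires goes through the same adapter). Gene
sets: GMT. Bulk expression: genes x samples TSV. All result tables are
written as TSV.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    BulkExpressionTable,
    CONTIG_COLUMNS,
    ContigTable,
    ExpressionDataset,
    GeneSetCollection,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def dedup_symbols(symbols) -> list[str]:
    """Make gene symbols unique by suffixing repeats with -1, -2, ... (10x convention)."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        s = str(s)
        if s in seen:
            seen[s] += 1
            new = f"{s}-{seen[s]}"
            log.warning("duplicate gene symbol %r renamed to %r", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


def _find_sidecar(d: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = d / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"missing sidecar file (looked for {stems}) in {d}")


def _open_maybe_gz(p: Path):
    return gzip.open(p, "rt") if p.suffix == ".gz" else open(p)


def load_counts(path, format: str = "mtx_dir") -> ExpressionDataset:
    """Load a cell x gene count matrix.

    ``mtx_dir``: directory with matrix.mtx(.gz), features.tsv(.gz) (or
    genes.tsv) and barcodes.tsv(.gz); the matrix is genes x cells on disk as
    CellRanger writes it and is transposed on load. ``dense_tsv``: cells in
    rows, genes in columns, first column = barcode.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format == "mtx_dir":
        mtx = _find_sidecar(path, ("matrix.mtx",))
        feat = _find_sidecar(path, ("features.tsv", "genes.tsv"))
        bc = _find_sidecar(path, ("barcodes.tsv",))
        try:
            with _open_maybe_gz(mtx) as fh:
                mat = scipy.io.mmread(fh)
        except Exception as e:  # noqa: BLE001 - rewrap any parse failure
            raise FormatError(f"cannot parse MatrixMarket file {mtx}: {e}") from e
        with _open_maybe_gz(feat) as fh:
            features = pd.read_csv(fh, sep="\t", header=None)
        with _open_maybe_gz(bc) as fh:
            barcodes = pd.read_csv(fh, sep="\t", header=None)[0].astype(str).tolist()
        # features.tsv carries (id, symbol, type); a 1-column file is symbols only
        sym_col = 1 if features.shape[1] > 1 else 0
        symbols = dedup_symbols(features[sym_col].astype(str))
        counts = sp.csr_matrix(mat).T.tocsr()  # stored genes x cells
        if counts.shape != (len(barcodes), len(symbols)):
            raise FormatError(
                f"matrix {mat.shape} does not match {len(symbols)} features x "
                f"{len(barcodes)} barcodes"
            )
    elif format == "dense_tsv":
        # parse the header ourselves: pandas would silently mangle duplicate
        # gene symbols instead of applying the -1/-2 dedup convention
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"empty matrix file: {path}")
        try:
            df = pd.read_csv(path, sep="\t", skiprows=1, header=None, index_col=0)
        except pd.errors.EmptyDataError as e:
            raise FormatError(f"empty matrix file: {path}") from e
        if df.empty or df.shape[1] != len(header) - 1:
            raise FormatError(f"empty or ragged matrix file: {path}")
        symbols = dedup_symbols(header[1:])
        barcodes = df.index.astype(str).tolist()
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
            raise FormatError("dense TSV counts must be integers")
        counts = sp.csr_matrix(vals.astype(np.int64))
    else:
        raise FormatError(f"unknown counts format: {format!r}")
    if counts.nnz == 0 and counts.shape[0] == 0:
        raise FormatError("empty matrix")
    return ExpressionDataset(counts=counts, gene_ids=pd.Index(symbols), cell_ids=pd.Index(barcodes))


def write_counts(ds: ExpressionDataset, path, format: str = "mtx_dir") -> None:
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", ds.counts.T.tocoo())
        pd.DataFrame({0: ds.gene_ids, 1: ds.gene_ids, 2: "Gene Expression"}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "dense_tsv":
        pd.DataFrame(
            np.asarray(ds.counts.todense()), index=ds.cell_ids, columns=ds.gene_ids
        ).to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown counts format: {format!r}")


# 10x truth strings observed in filtered_contig_annotations.csv
_TENX_TRUE = {"true"}
_TENX_COLS = {
    "barcode": "cell_id", "chain": "chain", "v_gene": "v_gene", "j_gene": "j_gene",
    "cdr3_nt": "cdr3_nt", "cdr3": "cdr3_aa", "productive": "productive", "umis": "umi_count",
}
_AIRR_COLS = {
    "cell_id": "cell_id", "locus": "chain", "v_call": "v_gene", "j_call": "j_gene",
    "junction": "cdr3_nt", "junction_aa": "cdr3_aa", "productive": "productive",
    "duplicate_count": "umi_count",
}


def load_contigs(path, dialect: str = "tenx_csv") -> ContigTable:
    """Load TCR contigs from 10x CSV or AIRR TSV; non-TRA/TRB loci are dropped
    and counted in ``ContigTable.n_dropped_loci``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if dialect == "tenx_csv":
        raw = pd.read_csv(path, dtype=str)
        colmap = _TENX_COLS
    elif dialect == "airr_tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        colmap = _AIRR_COLS
    else:
        raise FormatError(f"unknown contig dialect: {dialect!r}")
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise FormatError(f"{dialect} file missing required columns: {missing}")
    df = raw[list(colmap)].rename(columns=colmap)
    keep = df["chain"].isin(["TRA", "TRB"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d contigs on non-TRA/TRB loci", n_dropped)
    df = df[keep].copy()
    df["productive"] = df["productive"].fillna("false").str.lower().isin(_TENX_TRUE)
    df["umi_count"] = pd.to_numeric(df["umi_count"], errors="coerce").fillna(0).astype(int)
    for col in ("cdr3_nt", "cdr3_aa"):
        df[col] = df[col].fillna("")
    return ContigTable(df=df.reset_index(drop=True), n_dropped_loci=n_dropped)


def write_contigs(contigs: ContigTable, path) -> None:
    """Write contigs back out in the 10x CSV dialect."""
    inv = {v: k for k, v in _TENX_COLS.items()}
    out = contigs.df[CONTIG_COLUMNS].rename(columns=inv).copy()
    out["productive"] = np.where(out["productive"], "true", "false")
    out.to_csv(path, index=False)


def attach_metadata(ds: ExpressionDataset, meta: pd.DataFrame, *, strict: bool = False) -> ExpressionDataset:
    """Merge a per-cell metadata table (indexed or keyed by cell_id) into the dataset.

    With ``strict=True`` the metadata must cover every cell; otherwise missing
    cells get NA and extra metadata rows are ignored with a warning.
    """
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate cell_id in metadata: {dup[:5]}")
    meta.index = meta.index.astype(str)
    extra = meta.index.difference(ds.cell_ids)
    if len(extra):
        log.warning("%d metadata rows have no matching cell and are ignored", len(extra))
    absent = ds.cell_ids.difference(meta.index)
    if strict and len(absent):
        raise ValueError(f"metadata missing for cells: {absent.tolist()[:10]}")
    aligned = meta.reindex(ds.cell_ids)
    new_meta = ds.cell_meta.copy()
    for col in aligned.columns:
        new_meta[col] = aligned[col]
    return ExpressionDataset(
        counts=ds.counts, gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
        cell_meta=new_meta, normalized=ds.normalized,
    )


def load_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT (name <tab> description <tab> gene...)."""
    sets, prov = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = list(dict.fromkeys(genes))
            prov[name] = desc
    if not sets:
        raise FormatError(f"no gene sets parsed from {path}")
    return GeneSetCollection(sets=sets, provenance=prov)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, gsc.provenance.get(name, "")] + list(genes)) + "\n")


def load_bulk(path, sample_meta: pd.DataFrame | None = None) -> BulkExpressionTable:
    """Read a genes x samples bulk expression TSV (first column = gene symbol)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.empty:
        raise FormatError(f"empty bulk expression table: {path}")
    expr.index = dedup_symbols(expr.index)
    return BulkExpressionTable(expr=expr, sample_meta=sample_meta)
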