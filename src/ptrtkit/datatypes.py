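"""Core in-memory containers for the pipeline.

The pipeline revolves around four kinds of input:

* a cell-by-gene count matrix with per-cell annotations (:class:`ExpressionDataset`),
* a table of TCR contigs, one row per assembled chain (:class:`ContigTable`),
* named gene sets (:class:`GeneSetCollection`),
* a bulk genes-by-samples expression table (:class:`BulkExpressionTable`).

All containers validate their invariants on construction, so downstream code
can assume shapes and dtypes are consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

METADATA_COLUMNS = ("cluster", "condition", "donor", "compartment")

_DNA = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWY*X")


def _as_spmatrix(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


@dataclass
class ExpressionDataset:
    """Cell x gene counts plus per-cell metadata and an optional normalized layer.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.
    gene_ids
        Ordered, unique gene symbols (length = n_genes).
    cell_ids
        Ordered, unique cell barcodes (length = n_cells).
    cell_meta
        DataFrame indexed by cell id. Standard columns ``cluster``,
        ``condition``, ``donor`` and ``compartment`` are created (as NA)
        when absent.
    normalized
        Optional real-valued matrix of the same shape as ``counts``
        (see :func:`ptrtkit.scoring.normalize_log1p`).
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame = None
    normalized: sp.csr_matrix | None = None

    def __post_init__(self):
        self.counts = _as_spmatrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        if not self.gene_ids.is_unique:
            dup = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if not self.cell_ids.is_unique:
            dup = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dup[:5]}")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        if not self.cell_meta.index.equals(self.cell_ids):
            if set(self.cell_meta.index) != set(self.cell_ids):
                raise ValueError("cell_meta must cover every cell id exactly once")
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        for col in METADATA_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = pd.NA
        if self.normalized is not None:
            self.normalized = _as_spmatrix(self.normalized).astype(float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape mismatch")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str, *, case_insensitive: bool = False) -> int:
        """Column index of ``gene``; optional case-insensitive match for
        cross-species symbol lookups (e.g. human ADGRG1 vs mouse Adgrg1)."""
        if gene in self.gene_ids:
            return int(self.gene_ids.get_loc(gene))
        if case_insensitive:
            lowered = pd.Index([g.lower() for g in self.gene_ids])
            if gene.lower() in lowered:
                return int(lowered.get_loc(gene.lower()))
        raise KeyError(f"gene {gene!r} not in dataset")

    def counts_for(self, gene: str, **kw) -> np.ndarray:
        return np.asarray(
            self.counts[:, self.gene_index(gene, **kw)].todense()
        ).ravel()

    def normalized_dense(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer not computed; run normalize_log1p first")
        return np.asarray(self.normalized.todense())

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (counts in X, normalized as layer)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obs_names = self.cell_ids
        if self.normalized is not None:
            adata.layers["normalized"] = self.normalized.copy()
        return adata


CONTIG_COLUMNS = [
    "cell_id", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
    "productive", "umi_count",
]


@dataclass
class ContigTable:
    """One row per assembled TCR chain (TRA or TRB) per cell."""

    df: pd.DataFrame
    n_dropped_loci: int = 0

    def __post_init__(self):
        missing = [c for c in CONTIG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"contig table missing columns: {missing}")
        df = self.df.loc[:, CONTIG_COLUMNS].reset_index(drop=True).copy()
        bad_chain = ~df["chain"].isin(["TRA", "TRB"])
        if bad_chain.any():
            raise ValueError(
                f"chain must be TRA or TRB; got {sorted(df.loc[bad_chain, 'chain'].unique())}"
            )
        df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.upper()
        df["cdr3_aa"] = df["cdr3_aa"].astype(str).str.upper()
        for col, alphabet in (("cdr3_nt", _DNA), ("cdr3_aa", _AA)):
            vals = df[col][df[col] != ""]
            bad = vals[~vals.map(lambda s: set(s) <= alphabet)]
            if len(bad):
                raise ValueError(f"invalid {col} sequence: {bad.iloc[0]!r}")
        df["productive"] = df["productive"].astype(bool)
        df["umi_count"] = df["umi_count"].astype(int)
        if (df["umi_count"] < 0).any():
            raise ValueError("umi_count must be non-negative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance note per set."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate symbols")
        self.provenance = {name: self.provenance.get(name, "") for name in self.sets}

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class BulkExpressionTable:
    """Genes x samples expression matrix (TPM-like) with optional sample metadata."""

    expr: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.expr.columns.is_unique:
            raise ValueError("duplicate sample ids in bulk table")
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("bulk expression must be non-negative")
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.loc[self.expr.columns]

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns
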