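"""Identification of potentially tumor-reactive T cells (pTRTs).

A cluster is called pTRT when it simultaneously shows

* tumor enrichment        — Ro/e of the cluster in the tumor condition,
* clonal expansion        — 1 - normalized entropy of its tumor-condition clones,
* proliferation           — fraction of cells detecting a cycling marker set,
* TCR-signaling activation — z-scored mean gene-set scores across clusters.

Cells of pTRT clusters are labeled ``pTRT``; cells elsewhere that share a
clonotype with at least one pTRT cell are ``pTRT-relevant`` (TCR-based
tracing); everything else is ``pTRT-irrelevant`` (bystander). Tumor-reactive
= pTRT plus pTRT-relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSetCollection
from .repertoire import ClonotypeAssignment, entropy_stats
from .scoring import positive_any_fraction, roe_matrix, score_gene_set

PTRT = "pTRT"
RELEVANT = "pTRT-relevant"
IRRELEVANT = "pTRT-irrelevant"

DEFAULT_PROLIFERATION_GENES = ["MKI67", "TOP2A", "PCNA"]

#: minimum tumor-condition cells for a cluster to enter pTRT calling;
#: entropy estimates below this are too unstable to rank.
MIN_TUMOR_CELLS = 20


@dataclass
class PtrtThresholds:
    """Conjunction thresholds for pTRT calling (all config-exposed)."""

    tumor_enrichment: float = 1.2   # Ro/e, inclusive
    clonal_expansion: float = 0.2   # 1 - normalized entropy, inclusive
    proliferation: float = 0.05     # positive fraction, inclusive
    signaling_z: float = 0.0        # median z across sets, strict


@dataclass
class ReactivityLabels:
    labels: pd.Series  # cell_id -> {pTRT, pTRT-relevant, pTRT-irrelevant}

    @property
    def tumor_reactive(self) -> pd.Series:
        return self.labels != IRRELEVANT

    def cells(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def tally(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def compute_cluster_indices(
    ds: ExpressionDataset,
    assign: ClonotypeAssignment,
    signaling_sets: GeneSetCollection,
    proliferation_genes: list[str] | None = None,
    seed: int = 0,
    *,
    tumor_condition: str = "tumor",
    n_bins: int = 25,
    n_ctrl: int = 50,
    case_insensitive: bool = False,
    min_tumor_cells: int = MIN_TUMOR_CELLS,
) -> pd.DataFrame:
    """Per-cluster table of the four pTRT indices.

    Columns: ``tumor_enrichment``, ``clonal_expansion``, ``proliferation``,
    one z-scored column per signaling set (``z_<set>``), ``signaling_z_median``
    and ``insufficient`` (True for clusters with fewer than
    ``min_tumor_cells`` tumor-condition cells, which are excluded from
    calling). Expansion is computed on tumor-condition cells only, since
    pTRTs are defined by expansion in the tumor context.
    """
    meta = ds.cell_meta
    if meta["cluster"].isna().any() or meta["condition"].isna().any():
        raise ValueError("cluster and condition labels required for every cell")
    clusters = pd.Index(sorted(meta["cluster"].astype(str).unique()))
    cluster_s = meta["cluster"].astype(str)

    roe = roe_matrix(cluster_s.to_numpy(), meta["condition"].to_numpy())
    if tumor_condition not in roe.columns:
        raise ValueError(f"condition {tumor_condition!r} absent from dataset")
    enrichment = roe[tumor_condition].reindex(clusters)

    tumor_cells = meta.index[meta["condition"] == tumor_condition]
    expansion, n_tumor = {}, {}
    for cl in clusters:
        in_cl = tumor_cells[cluster_s.loc[tumor_cells] == cl]
        assigned = assign.cell_to_clonotype.index.intersection(in_cl)
        n_tumor[cl] = len(assigned)
        if len(assigned) == 0:
            expansion[cl] = np.nan
            continue
        sizes = assign.cell_to_clonotype.loc[assigned].value_counts()
        expansion[cl] = entropy_stats(sizes).expansion_index

    genes = proliferation_genes or DEFAULT_PROLIFERATION_GENES
    prolif = positive_any_fraction(ds, genes, cluster_s.to_numpy()).reindex(clusters)

    out = pd.DataFrame(
        {
            "tumor_enrichment": enrichment,
            "clonal_expansion": pd.Series(expansion).reindex(clusters),
            "proliferation": prolif,
            "n_tumor_cells": pd.Series(n_tumor).reindex(clusters).astype(int),
        },
        index=clusters,
    )

    rng = np.random.default_rng(seed)
    zcols = []
    for name in signaling_sets.names():
        scores = score_gene_set(
            ds, signaling_sets[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=rng,
            case_insensitive=case_insensitive,
        )
        per_cluster = pd.Series(scores).groupby(cluster_s.to_numpy()).mean().reindex(clusters)
        sd = per_cluster.std(ddof=0)
        z = (per_cluster - per_cluster.mean()) / (sd if sd > 0 else 1.0)
        col = f"z_{name}"
        out[col] = z
        zcols.append(col)
    out["signaling_z_median"] = out[zcols].median(axis=1)
    out["insufficient"] = out["n_tumor_cells"] < min_tumor_cells
    return out


def call_ptrt_clusters(
    indices: pd.DataFrame, thresholds: PtrtThresholds | None = None
) -> pd.DataFrame:
    """Flag pTRT clusters: all four criteria must hold simultaneously
    (enrichment, expansion and proliferation inclusive; signaling strict).
    Clusters marked insufficient never pass."""
    t = thresholds or PtrtThresholds()
    idx = indices.copy()
    callable_ = ~idx["insufficient"] & idx[
        ["tumor_enrichment", "clonal_expansion", "proliferation", "signaling_z_median"]
    ].notna().all(axis=1)
    idx["is_ptrt"] = (
        callable_
        & (idx["tumor_enrichment"] >= t.tumor_enrichment)
        & (idx["clonal_expansion"] >= t.clonal_expansion)
        & (idx["proliferation"] >= t.proliferation)
        & (idx["signaling_z_median"] > t.signaling_z)
    )
    n = int(idx["is_ptrt"].sum())
    if n == 0:
        import logging

        logging.getLogger(__name__).warning("no cluster passed the pTRT criteria")
    elif n == len(idx):
        import logging

        logging.getLogger(__name__).warning("every cluster passed the pTRT criteria")
    return idx


def label_reactivity(
    ds: ExpressionDataset, assign: ClonotypeAssignment, ptrt_clusters
) -> ReactivityLabels:
    """Three-way per-cell labels from pTRT clusters and clonotype sharing."""
    clusters = ds.cell_meta["cluster"].astype(str)
    ptrt_clusters = {str(c) for c in ptrt_clusters}
    in_ptrt = clusters.isin(ptrt_clusters)
    labels = pd.Series(IRRELEVANT, index=ds.cell_ids, dtype=object)
    labels[in_ptrt.to_numpy()] = PTRT

    ct = assign.cell_to_clonotype
    ptrt_cells = labels.index[labels == PTRT]
    shared_cts = set(ct.loc[ct.index.isin(ptrt_cells)])
    outside = ct.index[~ct.index.isin(ptrt_cells) & ct.isin(shared_cts)]
    outside = outside.intersection(labels.index)
    labels.loc[outside] = RELEVANT
    return ReactivityLabels(labels=labels)


def relevant_composition(labels: ReactivityLabels, cluster_labels: pd.Series) -> pd.Series:
    """Per-cluster fraction of pTRT-relevant cells (0 for pTRT clusters by
    construction, since their cells are labeled pTRT)."""
    clusters = pd.Series(cluster_labels).astype(str).reindex(labels.labels.index)
    rel = (labels.labels == RELEVANT).groupby(clusters.to_numpy()).mean()
    return rel.sort_index()
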