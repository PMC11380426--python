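"""Clonotype calling from paired chains and repertoire diversity statistics.

A clonotype is the strictest common identity class: V gene, J gene and
nucleotide CDR3 of both the alpha and the beta chain. Cells without at least
one productive TRA and one productive TRB are left unassigned with a reason
code. Diversity is summarized per group as Shannon entropy of clone-size
proportions, normalized by ln(number of clonotypes); the clonal expansion
index is 1 minus that (1 = monoclonal, 0 = perfectly even repertoire).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ContigTable


@dataclass
class ClonotypeAssignment:
    cell_to_clonotype: pd.Series          # cell_id -> clonotype_id
    clonotype_keys: pd.DataFrame          # clonotype_id -> TRA/TRB v, j, cdr3_nt (+aa)
    clone_size: pd.Series                 # clonotype_id -> cell count
    unassigned: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    # cell_id -> reason code

    @property
    def assigned_cells(self) -> pd.Index:
        return self.cell_to_clonotype.index


@dataclass
class DiversityStats:
    group: object
    n_cells: int
    n_clonotypes: int
    shannon_entropy: float        # nats
    normalized_entropy: float     # H / ln(k), 0 for k = 1
    expansion_index: float        # 1 - normalized entropy


_KEY_FIELDS = ["v_gene", "j_gene", "cdr3_nt"]


def _pick_chain(group: pd.DataFrame) -> pd.Series:
    """Among productive chains of one locus in one cell keep the highest-UMI
    contig; ties broken by lexicographically smallest cdr3_nt."""
    ordered = group.sort_values(
        ["umi_count", "cdr3_nt"], ascending=[False, True], kind="mergesort"
    )
    return ordered.iloc[0]


def call_clonotypes(contigs: ContigTable, *, aa_level: bool = False) -> ClonotypeAssignment:
    """Assign each cell a paired-chain clonotype.

    Requires >= 1 productive TRA and >= 1 productive TRB per cell; otherwise
    the cell is unassigned with reason ``no_productive_TRA`` /
    ``no_productive_TRB``. With ``aa_level=True`` the clonotype key uses the
    amino-acid CDR3 instead of the nucleotide one (for cross-donor
    comparisons).
    """
    df = contigs.df
    seq_col = "cdr3_aa" if aa_level else "cdr3_nt"
    prod = df[df["productive"]]
    cells = pd.Index(df["cell_id"].unique())
    best: dict[tuple, pd.Series] = {}
    for (cell, chain), grp in prod.groupby(["cell_id", "chain"], sort=False):
        best[(cell, chain)] = _pick_chain(grp)
    records, reasons = [], {}
    for cell in cells:
        tra = best.get((cell, "TRA"))
        trb = best.get((cell, "TRB"))
        if tra is None:
            reasons[cell] = "no_productive_TRA"
            continue
        if trb is None:
            reasons[cell] = "no_productive_TRB"
            continue
        records.append(
            {
                "cell_id": cell,
                "TRA_v": tra["v_gene"], "TRA_j": tra["j_gene"], "TRA_cdr3": tra[seq_col],
                "TRB_v": trb["v_gene"], "TRB_j": trb["j_gene"], "TRB_cdr3": trb[seq_col],
                "TRB_cdr3_aa": trb["cdr3_aa"],
            }
        )
    if not records:
        return ClonotypeAssignment(
            cell_to_clonotype=pd.Series(dtype=object),
            clonotype_keys=pd.DataFrame(),
            clone_size=pd.Series(dtype=int),
            unassigned=pd.Series(reasons, dtype=object),
        )
    tab = pd.DataFrame(records)
    key_cols = ["TRA_v", "TRA_j", "TRA_cdr3", "TRB_v", "TRB_j", "TRB_cdr3"]
    keys = tab[key_cols].apply(tuple, axis=1)
    uniq = sorted(keys.unique())
    key_to_id = {k: f"clonotype{n + 1}" for n, k in enumerate(uniq)}
    tab["clonotype_id"] = keys.map(key_to_id)
    cell_to_ct = tab.set_index("cell_id")["clonotype_id"]
    keys_df = (
        tab.drop_duplicates("clonotype_id")
        .set_index("clonotype_id")[key_cols + ["TRB_cdr3_aa"]]
        .sort_index()
    )
    sizes = cell_to_ct.value_counts().sort_index()
    return ClonotypeAssignment(
        cell_to_clonotype=cell_to_ct,
        clonotype_keys=keys_df,
        clone_size=sizes,
        unassigned=pd.Series(reasons, dtype=object),
    )


def clone_sizes(assign: ClonotypeAssignment, cells=None) -> pd.Series:
    """Clonotype -> cell count within the chosen cell universe.

    Clone size is deliberately relative to the universe passed in (e.g. the
    tumor compartment only), not to the full dataset.
    """
    mapping = assign.cell_to_clonotype
    if cells is not None:
        cells = pd.Index(cells)
        unknown = cells.difference(assign.assigned_cells)
        if len(unknown):
            raise ValueError(f"cells not in assignment: {unknown.tolist()[:5]}")
        mapping = mapping.loc[mapping.index.isin(cells)]
    return mapping.value_counts().sort_index()


def entropy_stats(sizes, group=None) -> DiversityStats:
    """Diversity summary from a vector of clone sizes."""
    sizes = np.asarray(list(sizes), dtype=float)
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        raise ValueError("no clones in group")
    total = sizes.sum()
    p = sizes / total
    h = float(-(p * np.log(p)).sum())
    k = sizes.size
    norm = 0.0 if k == 1 else h / np.log(k)
    return DiversityStats(
        group=group,
        n_cells=int(total),
        n_clonotypes=int(k),
        shannon_entropy=h,
        normalized_entropy=norm,
        expansion_index=1.0 - norm,
    )


def diversity(assign: ClonotypeAssignment, group_labels: pd.Series) -> pd.DataFrame:
    """Per-group clonal diversity (entropy / expansion) table.

    ``group_labels`` is indexed by cell id; cells without a clonotype are
    ignored. Every group must retain >= 1 assigned cell.
    """
    labels = pd.Series(group_labels)
    merged = pd.DataFrame(
        {"clonotype": assign.cell_to_clonotype}
    ).join(labels.rename("group"), how="left")
    rows = []
    for grp in pd.unique(labels.dropna()):
        sub = merged[merged["group"] == grp]
        if sub.empty:
            raise ValueError(f"group {grp!r} has no assigned cells")
        st = entropy_stats(sub["clonotype"].value_counts(), group=grp)
        rows.append(vars(st))
    return pd.DataFrame(rows).set_index("group")


def sharing_edges(assign: ClonotypeAssignment, cluster_labels: pd.Series) -> pd.DataFrame:
    """Pairwise cluster-sharing table: one row per (clonotype, cluster pair)
    for every clonotype spanning >= 2 clusters, with per-cluster cell counts."""
    labels = pd.Series(cluster_labels)
    merged = pd.DataFrame({"clonotype": assign.cell_to_clonotype}).join(
        labels.rename("cluster"), how="inner"
    )
    merged["cluster"] = merged["cluster"].astype(str)
    rows = []
    for ct, grp in merged.groupby("clonotype", sort=True):
        counts = grp["cluster"].value_counts()
        if len(counts) < 2:
            continue
        clusters = sorted(counts.index.astype(str))
        for i, j in ((a, b) for ai, a in enumerate(clusters) for b in clusters[ai + 1:]):
            rows.append(
                {
                    "clonotype": ct,
                    "cluster_i": i,
                    "cluster_j": j,
                    "cells_i": int(counts[i]),
                    "cells_j": int(counts[j]),
                }
            )
    return pd.DataFrame(rows, columns=["clonotype", "cluster_i", "cluster_j", "cells_i", "cells_j"])
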