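"""Marker-gene specificity ranking for tumor-reactive T cells.

The procedure that surfaces ADGRG1: restrict to genes lowly expressed in
bystander cells (mean log-normalized expression below a cutoff), rank the
survivors by the delta value (difference in expressing-cell fractions,
reactive minus bystander), keep the top K, and score each by reactive-cell
precision — the share of tumor-reactive cells among all cells expressing the
gene. Virus-specific clonotypes, matched against a CDR3 reference table,
serve as a negative control: they should not express the marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset
from .reactivity import IRRELEVANT, ReactivityLabels
from .repertoire import ClonotypeAssignment
from .scoring import positive_fraction

VIRAL_REFERENCE_COLUMNS = ["cdr3_aa_beta", "v_gene", "species"]


@dataclass
class ViralAnnotation:
    """Per-cell virus-specific-TCR flag plus the reference it was matched against."""

    viral_tcr: pd.Series          # cell_id -> bool
    reference: pd.DataFrame

    @property
    def flagged_cells(self) -> pd.Index:
        return self.viral_tcr.index[self.viral_tcr]


def rank_marker_candidates(
    ds: ExpressionDataset,
    labels: ReactivityLabels,
    bystander_mean_cutoff: float = 0.5,
    top_k: int = 100,
    *,
    delta_mode: str = "fraction",
) -> pd.DataFrame:
    """Rank genes by specificity for tumor-reactive cells.

    Returns a per-gene table with bystander/reactive mean normalized
    expression, expressing fractions, delta, candidate flag, precision and
    final rank (precision descending; ties broken by larger delta, then by
    symbol). ``delta_mode='mean'`` switches delta to the difference of mean
    normalized expression instead of expressing fractions.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if delta_mode not in ("fraction", "mean"):
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    reactive_mask = labels.tumor_reactive.reindex(ds.cell_ids).to_numpy()
    if reactive_mask.sum() == 0 or (~reactive_mask).sum() == 0:
        raise ValueError("need at least one reactive and one bystander cell")
    X = ds.normalized_dense()
    C = ds.counts
    expressing = np.asarray((C > 0).todense())

    mean_react = X[reactive_mask].mean(axis=0)
    mean_byst = X[~reactive_mask].mean(axis=0)
    frac_react = expressing[reactive_mask].mean(axis=0)
    frac_byst = expressing[~reactive_mask].mean(axis=0)
    delta = (
        frac_react - frac_byst if delta_mode == "fraction" else mean_react - mean_byst
    )

    n_expr = expressing.sum(axis=0)
    n_expr_react = expressing[reactive_mask].sum(axis=0)
    with np.errstate(invalid="ignore"):
        precision = np.where(n_expr > 0, n_expr_react / np.maximum(n_expr, 1), np.nan)

    out = pd.DataFrame(
        {
            "bystander_mean": mean_byst,
            "reactive_mean": mean_react,
            "bystander_frac": frac_byst,
            "reactive_frac": frac_react,
            "delta": delta,
            "n_expressing": n_expr,
            "precision": precision,
        },
        index=ds.gene_ids,
    )
    passes = out["bystander_mean"] < bystander_mean_cutoff
    by_delta = out[passes].sort_index().sort_values(
        ["delta"], ascending=False, kind="mergesort"
    )
    candidates = by_delta.index[:top_k]
    out["candidate"] = out.index.isin(candidates)

    cand = out[out["candidate"]].copy()
    cand = cand.sort_index().sort_values(
        ["precision", "delta"], ascending=[False, False], kind="mergesort"
    )
    out["rank"] = pd.Series(
        np.arange(1, len(cand) + 1), index=cand.index
    ).reindex(out.index)
    return out


def load_viral_reference(path) -> pd.DataFrame:
    """Read a viral-TCR reference TSV (columns cdr3_aa_beta, v_gene, species);
    empty v_gene means 'match on CDR3 alone'."""
    ref = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in VIRAL_REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise ValueError(f"viral reference missing columns: {missing}")
    bad = ref["cdr3_aa_beta"].str.len() == 0
    if bad.any():
        raise ValueError("viral reference rows with empty cdr3_aa_beta")
    return ref[VIRAL_REFERENCE_COLUMNS]


def flag_viral_clonotypes(assign: ClonotypeAssignment, reference: pd.DataFrame) -> ViralAnnotation:
    """Flag cells whose TRB CDR3 amino-acid sequence exactly matches a
    reference entry (and whose TRB V gene matches when the row specifies one).
    Unassigned cells are never flagged."""
    if reference.empty:
        raise ValueError("viral reference is empty")
    if (reference["cdr3_aa_beta"].astype(str).str.len() == 0).any():
        raise ValueError("viral reference rows with empty cdr3_aa_beta")
    keys = assign.clonotype_keys
    flagged_cts = set()
    for _, row in reference.iterrows():
        m = keys["TRB_cdr3_aa"] == row["cdr3_aa_beta"]
        v = str(row.get("v_gene", "") or "")
        if v:
            m &= keys["TRB_v"] == v
        flagged_cts.update(keys.index[m])
    viral = assign.cell_to_clonotype.isin(flagged_cts)
    return ViralAnnotation(viral_tcr=viral, reference=reference)


def marker_expression_in_viral(
    ds: ExpressionDataset, viral: ViralAnnotation, gene: str, **gene_kw
) -> float:
    """Expressing fraction of ``gene`` among viral-TCR-flagged cells."""
    flagged = viral.flagged_cells.intersection(ds.cell_ids)
    if len(flagged) == 0:
        raise ValueError("no viral-flagged cells in dataset")
    groups = pd.Series(
        np.where(ds.cell_ids.isin(flagged), "viral", "other"), index=ds.cell_ids
    )
    frac = positive_fraction(ds, gene, groups.to_numpy(), **gene_kw)
    return float(frac["viral"])
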