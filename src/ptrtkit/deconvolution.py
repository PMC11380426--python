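"""Signature-based deconvolution of bulk RNA-seq into cell-state fractions.

The signature matrix is built from the single-cell reference: for every cell
state, the top genes by rank-sum score against all other states (BH-adjusted
p < 0.05) define the signature gene list, and matrix entries are per-state
means of expm1(log-normalized expression). Bulk samples are then decomposed
by non-negative least squares over the signature genes and the coefficients
renormalized to fractions summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import BulkExpressionTable, ExpressionDataset
from .scoring import rank_sum_markers

MIN_CELLS_PER_STATE = 10


@dataclass
class SignatureMatrix:
    profiles: pd.DataFrame       # signature genes x states
    signature_genes: list[str]

    @property
    def states(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class FractionEstimates:
    fractions: pd.DataFrame      # samples x states, rows sum to 1
    residual: pd.Series          # per-sample residual norm (on the scaled vector)


def build_signature(
    ds: ExpressionDataset,
    state_labels: pd.Series,
    n_top: int = 50,
    *,
    padj_cutoff: float = 0.05,
    min_log2fc: float = 0.5,
) -> SignatureMatrix:
    """One-vs-rest rank-sum signature: per state, the ``n_top`` genes with the
    largest log2 fold change among BH-significant genes with log2FC above
    ``min_log2fc`` (weakly differential genes add collinearity, not signal)."""
    states = pd.Series(state_labels).astype(str).reindex(ds.cell_ids)
    if states.isna().any():
        raise ValueError("state label missing for some cells")
    levels = sorted(states.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 states")
    small = [s for s in levels if (states == s).sum() < MIN_CELLS_PER_STATE]
    if small:
        raise ValueError(f"states below {MIN_CELLS_PER_STATE} cells: {small}")
    X = np.expm1(ds.normalized_dense())
    sig_genes: list[str] = []
    for state in levels:
        in_state = ds.cell_ids[(states == state).to_numpy()]
        rest = ds.cell_ids[(states != state).to_numpy()]
        tab = rank_sum_markers(ds, in_state, rest)
        up = tab[(tab["padj"] < padj_cutoff) & (tab["log2fc"] > min_log2fc)]
        if up.empty:
            raise ValueError(f"no significant signature genes for state {state!r}")
        top = up.sort_index().sort_values("log2fc", ascending=False, kind="mergesort")
        sig_genes.extend(top.index[:n_top])
    sig_genes = sorted(set(sig_genes))
    gidx = [ds.gene_index(g) for g in sig_genes]
    profiles = pd.DataFrame(
        {
            state: X[(states == state).to_numpy()][:, gidx].mean(axis=0)
            for state in levels
        },
        index=sig_genes,
    )
    return SignatureMatrix(profiles=profiles, signature_genes=sig_genes)


def estimate_fractions(bulk: BulkExpressionTable, sig: SignatureMatrix) -> FractionEstimates:
    """Per-sample NNLS decomposition of bulk expression over the signature.

    Requires >= 50% of signature genes in the bulk table. Each sample vector
    is scaled to unit mean over the signature genes (so estimates are
    invariant to global rescaling of the sample); coefficients are then
    renormalized to sum to one.
    """
    present = [g for g in sig.signature_genes if g in bulk.expr.index]
    missing = [g for g in sig.signature_genes if g not in bulk.expr.index]
    if len(present) < 0.5 * len(sig.signature_genes):
        raise ValueError(
            f"only {len(present)}/{len(sig.signature_genes)} signature genes in bulk; "
            f"missing {missing[:10]}..."
        )
    A = sig.profiles.loc[present].to_numpy()
    fracs, resid = {}, {}
    for sample in bulk.samples:
        y = bulk.expr.loc[present, sample].to_numpy(dtype=float)
        if np.all(y == 0):
            raise ValueError(f"sample {sample!r} is all-zero over the signature genes")
        y = y / y.mean()
        coef, rnorm = nnls(A, y)
        total = coef.sum()
        if total == 0:
            frac = np.full(len(coef), np.nan)
        else:
            frac = coef / total
        fracs[sample] = frac
        resid[sample] = rnorm
    fractions = pd.DataFrame(fracs, index=sig.states).T
    return FractionEstimates(fractions=fractions, residual=pd.Series(resid))
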