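"""Expression-level statistics: normalization, gene-set scoring, rank-sum
marker tests, Ro/e enrichment, positive-cell fractions and the cytotoxicity
killing ratio.

Gene-set scoring follows the binned control-pool scheme standard in
single-cell analysis: genes are binned by dataset-mean expression, a seeded
control pool is drawn per set gene from the matching bin, and the score is
the per-cell mean over the set minus the mean over the control pool.
"""

from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset

log = logging.getLogger(__name__)

#: largest enumeration size for the exact tied-data rank-sum path
_MAX_EXACT_ENUM = 200_000


def normalize_log1p(ds: ExpressionDataset, scale_total: float = 1e4) -> ExpressionDataset:
    """Library-size normalize to ``scale_total`` counts per cell and log-transform.

    normalized[i, g] = ln(1 + scale_total * counts[i, g] / total_i).
    Cells with zero total counts get an all-zero row (with a warning).
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    counts = ds.counts.astype(float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("%d cells have zero total counts; normalized rows set to zero", n_zero)
    if ds.normalized is not None:
        log.info("overwriting existing normalized layer")
    safe = np.where(totals > 0, totals, 1.0)
    scaled = sp.diags(scale_total / safe) @ counts
    norm = scaled.copy()
    norm.data = np.log1p(norm.data)
    return ExpressionDataset(
        counts=ds.counts, gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
        cell_meta=ds.cell_meta, normalized=norm.tocsr(),
    )


def score_gene_set(
    ds: ExpressionDataset,
    genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int | np.random.Generator = 0,
    *,
    case_insensitive: bool = False,
) -> np.ndarray:
    """Per-cell control-adjusted gene-set score.

    Genes are ranked by dataset-mean normalized expression and cut into
    ``n_bins`` near-equal bins; for every set gene, ``n_ctrl`` control genes
    are drawn (seeded, without replacement, set genes excluded) from its
    bin. Score = mean normalized expression over the set minus the mean over
    the pooled control genes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = ds.normalized_dense()
    present = []
    for g in genes:
        try:
            present.append(ds.gene_index(g, case_insensitive=case_insensitive))
        except KeyError:
            pass
    if not present:
        raise ValueError(f"no gene of the set found in dataset: missing {sorted(genes)}")
    set_idx = np.array(sorted(set(present)))
    gene_means = X.mean(axis=0)
    order = pd.Series(gene_means).rank(method="first").to_numpy()
    bins = np.minimum((order - 1) * n_bins // len(order), n_bins - 1).astype(int)
    in_set = np.zeros(ds.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        # degenerate: set covers the whole expression space
        return X[:, set_idx].mean(axis=1) - X.mean(axis=1)
    ctrl_idx = np.array(sorted(ctrl))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


# -- rank-sum marker statistics -----------------------------------------------


def _mwu_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)


def _exact_enum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group-A index sets of the pooled
    sample; valid in the presence of ties (midrank U; the null distribution
    of U is symmetric about n_a*n_b/2)."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    mu = na * (n - na) / 2
    u_obs = _mwu_u(a, b)
    ranks = stats.rankdata(pooled)
    rank_a_base = na * (na + 1) / 2
    hits = total = 0
    dev = abs(u_obs - mu) - 1e-9
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - rank_a_base
        if abs(u - mu) >= dev:
            hits += 1
        total += 1
    return hits / total


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Mann–Whitney U for one gene.

    Returns (U statistic of group A, p value, untestable flag). Exact for
    min(n_a, n_b) <= 8 (full enumeration when ties make the standard exact
    distribution invalid and the enumeration is tractable), tie-corrected
    normal approximation otherwise. A gene whose pooled values are all
    identical is untestable and assigned p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = _mwu_u(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u, 1.0, True
    small = min(len(a), len(b)) <= 8
    has_ties = len(np.unique(pooled)) < len(pooled)
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return u, float(res.pvalue), False
    if small and comb(len(pooled), len(a)) <= _MAX_EXACT_ENUM:
        return u, _exact_enum_p(a, b), False
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue), False


def rank_sum_markers(
    ds: ExpressionDataset, cells_a, cells_b, *, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene two-sided Mann–Whitney on normalized expression, group A vs B.

    Returns a table with expressing fractions (raw count > 0), log2 fold
    change of expm1 mean normalized expression (pseudocount 1e-9), U, raw p
    and BH-adjusted p. Groups must be disjoint with >= 2 cells each.
    """
    ia = ds.cell_ids.get_indexer(pd.Index(cells_a))
    ib = ds.cell_ids.get_indexer(pd.Index(cells_b))
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("group contains unknown cell ids")
    if set(ia) & set(ib):
        raise ValueError("groups A and B overlap")
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs >= 2 cells")
    X = ds.normalized_dense()
    C = ds.counts
    gidx = (
        np.arange(ds.n_genes)
        if genes is None
        else np.array([ds.gene_index(g) for g in genes])
    )
    rows = []
    eps = 1e-9
    for gi in gidx:
        xa, xb = X[ia, gi], X[ib, gi]
        u, p, untestable = mann_whitney(xa, xb)
        ca = np.asarray(C[ia, gi].todense()).ravel()
        cb = np.asarray(C[ib, gi].todense()).ravel()
        log2fc = np.log2((np.expm1(xa).mean() + eps) / (np.expm1(xb).mean() + eps))
        rows.append(
            {
                "gene": ds.gene_ids[gi],
                "frac_a": float((ca > 0).mean()),
                "frac_b": float((cb > 0).mean()),
                "log2fc": float(log2fc),
                "u_stat": u,
                "pval": p,
                "untestable": untestable,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["padj"] = multipletests(out["pval"], method="fdr_bh")[1]
    return out


def roe_matrix(labels_a, labels_b) -> pd.DataFrame:
    """Observed/expected (Ro/e) enrichment of label A levels across label B levels.

    E_ij = (row_i total)(col_j total)/N, the chi-square expected count under
    independence; entries > 1 mean the (i, j) combination is over-represented.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    obs = pd.crosstab(a, b, dropna=False)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        empties = list(obs.index[obs.sum(axis=1) == 0]) + list(obs.columns[obs.sum(axis=0) == 0])
        raise ValueError(f"empty label level(s): {empties}")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.to_numpy().sum()
    return pd.DataFrame(obs.to_numpy() / expected, index=obs.index, columns=obs.columns)


def positive_fraction(ds: ExpressionDataset, gene: str, groups, **gene_kw) -> pd.Series:
    """Per-group fraction of cells with raw count > 0 for ``gene``."""
    pos = ds.counts_for(gene, **gene_kw) > 0
    return pd.Series(pos).groupby(pd.Series(groups).reset_index(drop=True), observed=False).mean()


def positive_any_fraction(ds: ExpressionDataset, genes: list[str], groups) -> pd.Series:
    """Per-group fraction of cells with raw count > 0 for any gene of a set
    (used for the proliferation index)."""
    idx = []
    for g in genes:
        try:
            idx.append(ds.gene_index(g))
        except KeyError:
            pass
    if not idx:
        raise ValueError(f"none of {genes} found in dataset")
    pos = np.asarray((ds.counts[:, idx] > 0).sum(axis=1)).ravel() > 0
    return pd.Series(pos).groupby(pd.Series(groups).reset_index(drop=True), observed=False).mean()


def killing_ratio(residual_24h: float, initial_0h: float) -> float:
    """Residual blast count after 24 h coculture over the initial blast count
    (lower = stronger killing)."""
    if initial_0h <= 0:
        raise ValueError("initial blast count must be > 0")
    if residual_24h < 0:
        raise ValueError("counts must be non-negative")
    return residual_24h / initial_0h
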