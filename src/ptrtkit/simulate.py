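"""Synthetic paired expression + TCR data with planted ground truth.

The generator emulates the statistical structure the pTRT analysis relies
on, without attempting transcriptome realism:

* multi-donor tumor/control cell populations split into clusters, counts
  drawn negative-binomial around cluster-specific mean profiles;
* planted pTRT clusters with elevated tumor proportion, a heavier power-law
  clone-size tail, and boosted TCR-signaling and proliferation genes;
* a configurable share of pTRT clonotypes re-seeded into designated source
  clusters, creating true pTRT-relevant cells;
* a near-specific marker gene (default ADGRG1) planted at exact expressing
  fractions in reactive vs bystander cells;
* viral clonotypes confined to bystander cells with the marker suppressed.

Everything is driven by one seed through one generator; identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ContigTable, ExpressionDataset
from .io import load_gmt, write_contigs, write_counts

_RESOURCES = Path(__file__).parent / "resources"

# fixed back-translation table: one codon per amino acid keeps CDR3 nt
# sequences in-frame and deterministic
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA_CHOICES = list(_CODON)

_TRAV = [f"TRAV{i}" for i in range(1, 11)]
_TRAJ = [f"TRAJ{i}" for i in range(1, 7)]
_TRBV = [f"TRBV{i}" for i in range(1, 11)]
_TRBJ = [f"TRBJ{i}" for i in range(1, 7)]

#: default planted viral TRB chains; mirrored in
#: resources/viral_tcr_reference_synthetic.tsv
DEFAULT_VIRAL_CHAINS = [
    ("CASSVIRALAEQFF", "TRBV9"),
    ("CASSEPSTEINYF", "TRBV5"),
    ("CASSFLVENAEQF", "TRBV7"),
]


@dataclass
class SimulationConfig:
    n_cells: int = 2000
    n_genes: int = 500
    n_clusters: int = 12
    planted_ptrt_clusters: int = 2
    relevant_source_clusters: int = 2
    tumor_prop_ptrt: float = 0.85     # per-cluster tumor proportion, planted clusters
    tumor_prop_other: float = 0.50
    n_tumor_donors: int = 3
    n_control_donors: int = 3
    nb_dispersion: float = 0.35       # var = mu + dispersion * mu^2
    base_mean_log: float = -1.2       # lognormal(meanlog, sdlog) baseline gene means
    base_mean_sdlog: float = 1.0
    cluster_effect_genes: int = 15    # genes upregulated per cluster
    cluster_effect_size: float = 3.0
    signaling_boost: float = 4.0      # fold boost of TCR-signaling genes in pTRT clusters
    proliferation_boost: float = 8.0
    proliferation_base_mean: float = 0.03
    clone_exponent_ptrt: float = 1.2  # power-law exponent, pTRT tumor blocks
    clone_exponent_other: float = 2.0
    max_clone_size: int = 50
    dominant_clone_frac: float = 0.3  # share of a pTRT tumor block held by its top clone
    min_expansion_plant: float = 0.3  # guaranteed expansion index of pTRT tumor blocks
    sharing_rate: float = 0.15        # share of pTRT clonotypes re-seeded into sources
    shared_cells_max: int = 3         # cells per shared clonotype in source clusters
    marker_gene: str = "ADGRG1"
    marker_frac_reactive: float = 0.9
    marker_frac_bystander: float = 0.02
    viral_n_clonotypes: int = 3
    viral_cells_per_clonotype: int = 8
    viral_marker_leak: float = 0.01
    pair_rate: float = 0.92           # fraction of cells with both productive chains
    seed: int = 0

    def validate(self) -> None:
        if self.planted_ptrt_clusters + self.relevant_source_clusters > self.n_clusters:
            raise ValueError("planted + source clusters exceed n_clusters")
        if self.sharing_rate > 0 and self.relevant_source_clusters == 0:
            raise ValueError("sharing_rate > 0 requires at least one source cluster")
        for name in ("tumor_prop_ptrt", "tumor_prop_other", "sharing_rate",
                     "marker_frac_reactive", "marker_frac_bystander",
                     "viral_marker_leak", "pair_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < self.n_clusters:
            raise ValueError("need at least one cell per cluster")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**d)

    @property
    def ptrt_cluster_ids(self) -> list[str]:
        return [f"cluster{i:02d}" for i in range(self.planted_ptrt_clusters)]

    @property
    def source_cluster_ids(self) -> list[str]:
        lo = self.planted_ptrt_clusters
        return [f"cluster{i:02d}" for i in range(lo, lo + self.relevant_source_clusters)]


@dataclass
class GroundTruth:
    reactivity: pd.Series            # cell_id -> pTRT / pTRT-relevant / pTRT-irrelevant
    ptrt_clusters: list[str]
    marker_gene: str
    marker_frac_reactive: float
    marker_frac_bystander: float
    viral_clonotypes: list[str]
    viral_cells: list[str]
    bulk_fractions: pd.DataFrame | None = None

    def expected_marker_precision(self) -> float:
        """Closed-form precision implied by the planted expressing fractions
        and realized group sizes (exact-count planting makes this exact up to
        the floor rounding)."""
        n_react = int((self.reactivity != "pTRT-irrelevant").sum())
        n_byst = int((self.reactivity == "pTRT-irrelevant").sum())
        n_viral = len(self.viral_cells)
        expr_react = int(round(self.marker_frac_reactive * n_react))
        expr_byst = int(round(self.marker_frac_bystander * (n_byst - n_viral)))
        expr_viral = 0  # leak is floored; below one cell at defaults
        denom = expr_react + expr_byst + expr_viral
        return expr_react / denom if denom else float("nan")

    def to_json_dict(self) -> dict:
        return {
            "reactivity": self.reactivity.to_dict(),
            "ptrt_clusters": self.ptrt_clusters,
            "marker_gene": self.marker_gene,
            "marker_frac_reactive": self.marker_frac_reactive,
            "marker_frac_bystander": self.marker_frac_bystander,
            "viral_clonotypes": self.viral_clonotypes,
            "viral_cells": self.viral_cells,
            "bulk_fractions": None
            if self.bulk_fractions is None
            else self.bulk_fractions.to_dict(),
        }


def _power_law_sizes(rng, exponent: float, smax: int, n_cells: int) -> list[int]:
    """Draw clone sizes s ~ s^-exponent on 1..smax until they cover n_cells;
    the last clone is truncated to fit exactly."""
    s = np.arange(1, smax + 1, dtype=float)
    p = s ** (-exponent)
    p /= p.sum()
    sizes: list[int] = []
    left = n_cells
    while left > 0:
        k = int(rng.choice(s, p=p))
        k = min(k, left)
        sizes.append(k)
        left -= k
    return sizes


def _expanded_block_sizes(rng, cfg: "SimulationConfig", n_cells: int) -> list[int]:
    """Clone sizes for a pTRT tumor block: one dominant clone holding
    ``dominant_clone_frac`` of the block over a heavy power-law background,
    redrawn until the block's expansion index reaches ``min_expansion_plant``
    (conditioned sampling — the elevated-clonality plant is a guarantee, not
    a tendency). Falls back to the best draw after 500 attempts (tiny blocks
    may not be able to reach the floor)."""
    from .repertoire import entropy_stats

    dom = max(1, int(round(cfg.dominant_clone_frac * n_cells)))
    best: list[int] = []
    best_exp = -1.0
    for _ in range(500):
        rest = n_cells - dom
        sizes = [dom] + (
            _power_law_sizes(rng, cfg.clone_exponent_ptrt, cfg.max_clone_size, rest)
            if rest > 0
            else []
        )
        exp = entropy_stats(sizes).expansion_index
        if exp >= cfg.min_expansion_plant:
            return sizes
        if exp > best_exp:
            best, best_exp = sizes, exp
    return best


def _random_cdr3(rng, lo: int = 8, hi: int = 15) -> tuple[str, str]:
    length = int(rng.integers(lo, hi + 1))
    aa = "C" + "".join(rng.choice(_AA_CHOICES, size=length - 2)) + "F"
    nt = "".join(_CODON[c] for c in aa)
    return aa, nt


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    signaling = load_gmt(_RESOURCES / "tcr_signaling.gmt")
    phenotype = load_gmt(_RESOURCES / "phenotype_scores.gmt")
    special: list[str] = [cfg.marker_gene, "MKI67", "TOP2A", "PCNA"]
    for name in signaling.names():
        special.extend(signaling[name])
    for name in phenotype.names():
        special.extend(phenotype[name])
    special = list(dict.fromkeys(special))
    if len(special) > cfg.n_genes:
        raise ValueError(f"n_genes={cfg.n_genes} too small for {len(special)} built-in genes")
    fillers = [f"GENE{i:04d}" for i in range(cfg.n_genes - len(special))]
    return special + fillers, dict(signaling.sets)


def generate_dataset(cfg: SimulationConfig) -> tuple[ExpressionDataset, ContigTable, GroundTruth]:
    """Generate one paired expression + TCR dataset with ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, signaling_sets = _gene_names(cfg)
    gene_idx = {g: i for i, g in enumerate(genes)}
    clusters = [f"cluster{i:02d}" for i in range(cfg.n_clusters)]
    ptrt_set = set(cfg.ptrt_cluster_ids)

    # -- cells: cluster, condition, donor -------------------------------------
    cell_ids = [f"CELL{i:05d}-1" for i in range(cfg.n_cells)]
    cell_cluster = np.array(clusters)[rng.integers(0, cfg.n_clusters, cfg.n_cells)]
    # guarantee every cluster is populated
    for i, cl in enumerate(clusters):
        if not (cell_cluster == cl).any():
            cell_cluster[i] = cl
    tumor_p = np.where(
        np.isin(cell_cluster, list(ptrt_set)), cfg.tumor_prop_ptrt, cfg.tumor_prop_other
    )
    is_tumor = rng.random(cfg.n_cells) < tumor_p
    condition = np.where(is_tumor, "tumor", "control")
    donor = np.where(
        is_tumor,
        [f"AML{d + 1}" for d in rng.integers(0, cfg.n_tumor_donors, cfg.n_cells)],
        [f"HD{d + 1}" for d in rng.integers(0, cfg.n_control_donors, cfg.n_cells)],
    )

    # -- cluster mean profiles -------------------------------------------------
    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sdlog, cfg.n_genes)
    prolif_idx = [gene_idx[g] for g in ("MKI67", "TOP2A", "PCNA")]
    base[prolif_idx] = cfg.proliferation_base_mean
    base[gene_idx[cfg.marker_gene]] = 0.0  # planted directly below
    signaling_idx = sorted(
        {gene_idx[g] for gs in signaling_sets.values() for g in gs if g in gene_idx}
    )
    profiles = {}
    for cl in clusters:
        mu = base.copy()
        up = rng.choice(cfg.n_genes, size=cfg.cluster_effect_genes, replace=False)
        mu[up] *= cfg.cluster_effect_size
        if cl in ptrt_set:
            mu[signaling_idx] *= cfg.signaling_boost
            mu[prolif_idx] *= cfg.proliferation_boost
        profiles[cl] = mu

    # -- negative binomial counts ---------------------------------------------
    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    d = cfg.nb_dispersion
    for cl in clusters:
        rows = np.flatnonzero(cell_cluster == cl)
        mu = profiles[cl]
        lam = rng.gamma(1.0 / d, d * np.broadcast_to(mu, (len(rows), cfg.n_genes)))
        counts[rows] = rng.poisson(lam)

    # -- clonotypes ------------------------------------------------------------
    paired = rng.random(cfg.n_cells) < cfg.pair_rate
    cell_clonotype = np.array([""] * cfg.n_cells, dtype=object)
    unpaired_reason = {}
    for i in np.flatnonzero(~paired):
        unpaired_reason[cell_ids[i]] = (
            "no_productive_TRA" if rng.random() < 0.5 else "no_productive_TRB"
        )
    clonotype_chains: dict[str, dict] = {}

    def new_clonotype(tag: str, trb_override: tuple[str, str] | None = None) -> str:
        ct = f"sim_ct_{tag}_{len(clonotype_chains):05d}"
        tra_aa, tra_nt = _random_cdr3(rng)
        trb_aa, trb_nt = _random_cdr3(rng)
        trb_v = rng.choice(_TRBV)
        if trb_override is not None:
            trb_aa, trb_v = trb_override
            trb_nt = "".join(_CODON[c] for c in trb_aa)
        clonotype_chains[ct] = {
            "TRA": (rng.choice(_TRAV), rng.choice(_TRAJ), tra_nt, tra_aa),
            "TRB": (trb_v, rng.choice(_TRBJ), trb_nt, trb_aa),
        }
        return ct

    ptrt_tumor_clonotypes: list[str] = []
    for cl in clusters:
        for cond in ("tumor", "control"):
            rows = np.flatnonzero((cell_cluster == cl) & (condition == cond) & paired)
            if rows.size == 0:
                continue
            heavy = cl in ptrt_set and cond == "tumor"
            if heavy:
                sizes = _expanded_block_sizes(rng, cfg, rows.size)
            else:
                sizes = _power_law_sizes(
                    rng, cfg.clone_exponent_other, cfg.max_clone_size, rows.size
                )
            rng.shuffle(rows)
            pos = 0
            for size in sizes:
                ct = new_clonotype(cl)
                if heavy:
                    ptrt_tumor_clonotypes.append(ct)
                for r in rows[pos : pos + size]:
                    cell_clonotype[r] = ct
                pos += size

    # -- clonotype sharing into source clusters (true pTRT-relevant cells) ----
    n_shared = int(round(cfg.sharing_rate * len(ptrt_tumor_clonotypes)))
    shared_cts = list(
        rng.choice(ptrt_tumor_clonotypes, size=n_shared, replace=False)
    ) if n_shared else []
    source_rows = np.flatnonzero(
        np.isin(cell_cluster, cfg.source_cluster_ids) & paired
    )
    rng.shuffle(source_rows)
    cursor = 0
    for ct in shared_cts:
        k = int(rng.integers(1, cfg.shared_cells_max + 1))
        for r in source_rows[cursor : cursor + k]:
            cell_clonotype[r] = ct
        cursor += k

    # -- viral clonotypes in bystander cells ----------------------------------
    in_ptrt = np.isin(cell_cluster, list(ptrt_set))
    shared_mask = np.isin(cell_clonotype, shared_cts)
    bystander_rows = np.flatnonzero(~in_ptrt & ~shared_mask & paired)
    rng.shuffle(bystander_rows)
    viral_cts, viral_rows = [], []
    cursor = 0
    for v in range(cfg.viral_n_clonotypes):
        aa, trbv = DEFAULT_VIRAL_CHAINS[v % len(DEFAULT_VIRAL_CHAINS)]
        ct = new_clonotype("viral", trb_override=(aa, trbv))
        viral_cts.append(ct)
        take = bystander_rows[cursor : cursor + cfg.viral_cells_per_clonotype]
        for r in take:
            cell_clonotype[r] = ct
            viral_rows.append(int(r))
        cursor += cfg.viral_cells_per_clonotype

    # -- ground-truth reactivity labels ----------------------------------------
    ptrt_cells = set(np.flatnonzero(in_ptrt))
    ptrt_cts_final = set(cell_clonotype[sorted(ptrt_cells)]) - {""}
    labels = np.where(in_ptrt, "pTRT", "pTRT-irrelevant").astype(object)
    relevant = ~in_ptrt & np.isin(cell_clonotype, sorted(ptrt_cts_final)) & (cell_clonotype != "")
    labels[relevant] = "pTRT-relevant"

    # -- marker gene planting (exact expressing-cell counts) -------------------
    mk = gene_idx[cfg.marker_gene]
    reactive_rows = np.flatnonzero(labels != "pTRT-irrelevant")
    byst_rows = np.flatnonzero(labels == "pTRT-irrelevant")
    viral_arr = np.array(sorted(set(viral_rows)), dtype=int)
    byst_nonviral = np.setdiff1d(byst_rows, viral_arr)

    def plant(rows: np.ndarray, frac: float) -> None:
        n_on = int(np.floor(frac * rows.size + 0.5))
        on = rng.choice(rows, size=min(n_on, rows.size), replace=False)
        counts[on, mk] = 1 + rng.poisson(1.5, size=on.size)

    plant(reactive_rows, cfg.marker_frac_reactive)
    plant(byst_nonviral, cfg.marker_frac_bystander)
    n_leak = int(np.floor(cfg.viral_marker_leak * viral_arr.size))
    if n_leak:
        on = rng.choice(viral_arr, size=n_leak, replace=False)
        counts[on, mk] = 1

    # -- contig table -----------------------------------------------------------
    contig_rows = []
    for i in range(cfg.n_cells):
        ct = cell_clonotype[i]
        chains = []
        if ct:
            chains = [("TRA", True), ("TRB", True)]
        elif cell_ids[i] in unpaired_reason:
            missing = unpaired_reason[cell_ids[i]]
            have = "TRB" if missing == "no_productive_TRA" else "TRA"
            chains = [(have, True)]
            ct_single = new_clonotype("orphan")
            ct = ct_single
        for chain, productive in chains:
            v, j, nt, aa = clonotype_chains[ct][chain]
            contig_rows.append(
                {
                    "cell_id": cell_ids[i],
                    "chain": chain,
                    "v_gene": v,
                    "j_gene": j,
                    "cdr3_nt": nt,
                    "cdr3_aa": aa,
                    "productive": productive,
                    "umi_count": int(rng.integers(2, 21)),
                }
            )
    contigs = ContigTable(df=pd.DataFrame(contig_rows))

    meta = pd.DataFrame(
        {
            "cluster": cell_cluster,
            "condition": condition,
            "donor": donor,
            "compartment": "CD8",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
    )
    truth = GroundTruth(
        reactivity=pd.Series(labels, index=ds.cell_ids),
        ptrt_clusters=cfg.ptrt_cluster_ids,
        marker_gene=cfg.marker_gene,
        marker_frac_reactive=cfg.marker_frac_reactive,
        marker_frac_bystander=cfg.marker_frac_bystander,
        viral_clonotypes=viral_cts,
        viral_cells=[cell_ids[r] for r in sorted(set(viral_rows))],
    )
    return ds, contigs, truth


def generate_bulk_mixtures(
    profiles: pd.DataFrame,
    n_samples: int = 20,
    dirichlet_alpha: float | np.ndarray = 1.0,
    noise_sigma: float = 0.2,
    depth: float = 1e6,
    seed: int = 0,
):
    """Mix per-state expression profiles into synthetic bulk samples.

    Per sample: fractions ~ Dirichlet(alpha); bulk = profiles @ fractions,
    multiplied by i.i.d. lognormal(0, noise_sigma) gene noise, scaled to
    ``depth`` total. Returns (BulkExpressionTable, true fraction DataFrame).
    """
    from .datatypes import BulkExpressionTable

    rng = np.random.default_rng(seed)
    states = list(profiles.columns)
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (len(states),))
    if (alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be positive")
    P = profiles.to_numpy(dtype=float)
    cols, truths = {}, {}
    for s in range(n_samples):
        frac = rng.dirichlet(alpha)
        y = P @ frac
        if noise_sigma > 0:
            y = y * rng.lognormal(0.0, noise_sigma, size=y.shape)
        if y.sum() > 0:
            y = y * (depth / y.sum())
        name = f"sample{s + 1:03d}"
        cols[name] = y
        truths[name] = frac
    bulk = BulkExpressionTable(expr=pd.DataFrame(cols, index=profiles.index))
    truth = pd.DataFrame(truths, index=states).T
    return bulk, truth


def write_simulation(
    ds: ExpressionDataset, contigs: ContigTable, truth: GroundTruth, cfg: SimulationConfig, outdir
) -> None:
    """Persist one simulated dataset: MTX dir + contig CSV + metadata TSV +
    truth JSON + config copy."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(ds, outdir / "counts_mtx", format="mtx_dir")
    write_contigs(contigs, outdir / "filtered_contig_annotations.csv")
    ds.cell_meta.rename_axis("cell_id").to_csv(outdir / "cell_metadata.tsv", sep="\t")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / "simulation_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
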