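"""End-to-end orchestration: one YAML config drives
load -> normalize -> clonotypes -> cluster indices -> pTRT call -> labels ->
marker ranking -> optional viral exclusion -> optional deconvolution,
with a machine-readable run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import GeneSetCollection
from .io import attach_metadata, load_bulk, load_contigs, load_counts, load_gmt
from .markers import (
    flag_viral_clonotypes,
    load_viral_reference,
    marker_expression_in_viral,
    rank_marker_candidates,
)
from .reactivity import (
    DEFAULT_PROLIFERATION_GENES,
    PtrtThresholds,
    call_ptrt_clusters,
    compute_cluster_indices,
    label_reactivity,
    relevant_composition,
)
from .repertoire import call_clonotypes, diversity
from .scoring import normalize_log1p
from .deconvolution import build_signature, estimate_fractions

log = logging.getLogger(__name__)

_RESOURCES = Path(__file__).parent / "resources"


class ConfigError(ValueError):
    """Raised when the pipeline config fails schema validation."""


@dataclass
class PipelineConfig:
    counts_path: str = ""
    counts_format: str = "mtx_dir"
    contigs_path: str = ""
    contigs_dialect: str = "tenx_csv"
    metadata_path: str = ""
    signaling_gmt: str = ""              # empty -> packaged default
    proliferation_genes: list[str] = field(default_factory=lambda: list(DEFAULT_PROLIFERATION_GENES))
    tumor_condition: str = "tumor"
    scale_total: float = 1e4
    n_bins: int = 25
    n_ctrl: int = 50
    tau_enrichment: float = 1.2
    tau_expansion: float = 0.2
    tau_proliferation: float = 0.05
    tau_signaling_z: float = 0.0
    min_tumor_cells: int = 20
    marker_gene: str = "ADGRG1"
    bystander_mean_cutoff: float = 0.5
    top_k: int = 100
    delta_mode: str = "fraction"
    viral_reference_path: str = ""       # optional stage
    bulk_path: str = ""                  # optional deconvolution stage
    deconv_n_top: int = 50
    seed: int = 0
    out_dir: str = "ptrt_run"

    REQUIRED = ("counts_path", "contigs_path", "metadata_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in cls.REQUIRED:
            if not getattr(cfg, name):
                raise ConfigError(f"missing required config field: {name}")
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    label_tally: dict = field(default_factory=dict)
    n_cells: int = 0
    n_contig_rows: int = 0
    n_dropped_loci: int = 0
    n_unassigned_cells: int = 0

    def add_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **counts})

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def run_pipeline(config: PipelineConfig | str | Path) -> RunReport:
    """Run the full analysis; all result tables and report.json are written
    to ``config.out_dir``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), seed=config.seed)
    current = {"name": "load"}

    def stage(name):
        current["name"] = name
        t0 = time.perf_counter()

        def done(**counts):
            report.add_stage(name, time.perf_counter() - t0, **counts)

        return done

    try:
        done = stage("load")
        ds = load_counts(config.counts_path, format=config.counts_format)
        meta = pd.read_csv(config.metadata_path, sep="\t", dtype=str)
        ds = attach_metadata(ds, meta)
        contigs = load_contigs(config.contigs_path, dialect=config.contigs_dialect)
        report.n_cells = ds.n_cells
        report.n_contig_rows = len(contigs)
        report.n_dropped_loci = contigs.n_dropped_loci
        done(cells=ds.n_cells, genes=ds.n_genes, contig_rows=len(contigs))

        done = stage("normalize")
        ds = normalize_log1p(ds, scale_total=config.scale_total)
        done(cells=ds.n_cells)

        done = stage("clonotypes")
        assign = call_clonotypes(contigs)
        report.n_unassigned_cells = len(assign.unassigned)
        done(assigned=len(assign.assigned_cells), unassigned=len(assign.unassigned))

        done = stage("cluster_indices")
        gmt_path = config.signaling_gmt or (_RESOURCES / "tcr_signaling.gmt")
        signaling: GeneSetCollection = load_gmt(gmt_path)
        indices = compute_cluster_indices(
            ds, assign, signaling,
            proliferation_genes=config.proliferation_genes,
            seed=config.seed,
            tumor_condition=config.tumor_condition,
            n_bins=config.n_bins, n_ctrl=config.n_ctrl,
            min_tumor_cells=config.min_tumor_cells,
        )
        done(clusters=len(indices))

        done = stage("ptrt_call")
        thresholds = PtrtThresholds(
            tumor_enrichment=config.tau_enrichment,
            clonal_expansion=config.tau_expansion,
            proliferation=config.tau_proliferation,
            signaling_z=config.tau_signaling_z,
        )
        indices = call_ptrt_clusters(indices, thresholds)
        indices.rename_axis("cluster").to_csv(out / "cluster_indices.tsv", sep="\t")
        ptrt_clusters = list(indices.index[indices["is_ptrt"]])
        done(ptrt_clusters=len(ptrt_clusters))

        done = stage("labels")
        labels = label_reactivity(ds, assign, ptrt_clusters)
        labels.labels.rename("label").rename_axis("cell_id").to_csv(
            out / "reactivity_labels.tsv", sep="\t"
        )
        comp = relevant_composition(labels, ds.cell_meta["cluster"])
        comp.rename("relevant_fraction").rename_axis("cluster").to_csv(
            out / "relevant_composition.tsv", sep="\t"
        )
        report.label_tally = {k: int(v) for k, v in labels.tally().items()}
        assert sum(report.label_tally.values()) == ds.n_cells
        done(**report.label_tally)

        done = stage("marker_ranking")
        ranking = rank_marker_candidates(
            ds, labels,
            bystander_mean_cutoff=config.bystander_mean_cutoff,
            top_k=config.top_k, delta_mode=config.delta_mode,
        )
        ranking.rename_axis("gene").to_csv(out / "marker_ranking.tsv", sep="\t")
        done(candidates=int(ranking["candidate"].sum()))

        done = stage("diversity")
        marker_pos = pd.Series(
            ds.counts_for(config.marker_gene) > 0, index=ds.cell_ids
        ).map({True: f"{config.marker_gene}+", False: f"{config.marker_gene}-"})
        div = diversity(assign, marker_pos)
        div.rename_axis("group").to_csv(out / "marker_diversity.tsv", sep="\t")
        done(groups=len(div))

        if config.viral_reference_path:
            done = stage("viral_exclusion")
            ref = load_viral_reference(config.viral_reference_path)
            viral = flag_viral_clonotypes(assign, ref)
            frac = (
                marker_expression_in_viral(ds, viral, config.marker_gene)
                if viral.viral_tcr.any()
                else float("nan")
            )
            pd.DataFrame(
                {
                    "n_viral_cells": [int(viral.viral_tcr.sum())],
                    "marker_expressing_fraction": [frac],
                }
            ).to_csv(out / "viral_exclusion.tsv", sep="\t", index=False)
            done(viral_cells=int(viral.viral_tcr.sum()))

        if config.bulk_path:
            done = stage("deconvolution")
            state = labels.labels.copy()
            marker_on = ds.counts_for(config.marker_gene) > 0
            state[:] = "other"
            state[marker_on & (ds.cell_meta["compartment"] == "CD8").to_numpy()] = (
                f"{config.marker_gene}+CD8"
            )
            sig = build_signature(ds, state, n_top=config.deconv_n_top)
            bulk = load_bulk(config.bulk_path)
            est = estimate_fractions(bulk, sig)
            est.fractions.rename_axis("sample").to_csv(out / "bulk_fractions.tsv", sep="\t")
            done(samples=len(est.fractions))
    except ConfigError:
        raise
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {current['name']!r}: {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    return report
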