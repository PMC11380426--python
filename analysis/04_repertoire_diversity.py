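#!/usr/bin/env python
"""Repertoire structure of marker-positive vs marker-negative cells:
normalized Shannon entropy, expansion index and mean clone size, plus the
viral-clonotype negative control (virus-specific cells should not express
the marker).

Writes results/04_marker_diversity.tsv.
"""

from pathlib import Path

import pandas as pd

from ptrtkit.markers import flag_viral_clonotypes, load_viral_reference, marker_expression_in_viral
from ptrtkit.repertoire import call_clonotypes, clone_sizes, diversity
from ptrtkit.scoring import normalize_log1p
from ptrtkit.simulate import SimulationConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]
RESOURCES = Path(__import__("ptrtkit").__file__).parent / "resources"

ds, contigs, truth = generate_dataset(SimulationConfig(seed=1))
ds = normalize_log1p(ds)
assign = call_clonotypes(contigs)

marker = truth.marker_gene
pos = pd.Series(ds.counts_for(marker) > 0, index=ds.cell_ids)
groups = pos.map({True: f"{marker}+", False: f"{marker}-"})
div = diversity(assign, groups)

mean_size = {}
for name, cells in groups.groupby(groups):
    sizes = clone_sizes(assign, assign.assigned_cells.intersection(cells.index))
    percell = assign.cell_to_clonotype.loc[
        assign.assigned_cells.intersection(cells.index)
    ].map(sizes)
    mean_size[name] = percell.mean()
div["mean_clone_size"] = pd.Series(mean_size)

(ROOT / "results").mkdir(exist_ok=True)
div.rename_axis("group").to_csv(ROOT / "results" / "04_marker_diversity.tsv", sep="\t")
print(div.round(4))

ref = load_viral_reference(RESOURCES / "viral_tcr_reference_synthetic.tsv")
viral = flag_viral_clonotypes(assign, ref)
frac = marker_expression_in_viral(ds, viral, marker)
print(
    f"\nviral-TCR cells: {int(viral.viral_tcr.sum())}; "
    f"{marker} expressing fraction among them: {frac:.4f}"
)
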