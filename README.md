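# ptrtkit

Identification of **potentially tumor-reactive T cells (pTRTs)** from paired
single-cell RNA-seq + single-cell TCR-seq, TCR-based tracing of their
relatives, specificity ranking of candidate marker genes (the analysis that
surfaces *ADGRG1*/GPR56 in AML bone marrow), and signature-based
deconvolution of the marker⁺CD8⁺ fraction from bulk RNA-seq.

The package is aimed at computational immunologists working with 10x-style
expression matrices and `filtered_contig_annotations.csv` / AIRR
rearrangement tables. Clustering, QC and embedding are assumed done
upstream; `ptrtkit` consumes cluster labels and produces reactivity calls,
marker rankings and bulk fraction estimates. A synthetic-data generator with
planted ground truth makes every stage testable without access to patient
data.

## The method

A cluster *c* is called pTRT when four criteria hold simultaneously:

* **Tumor enrichment** — Ro/e(c, tumor) = O/E ≥ τ_e, where
  E = (row total × column total)/N is the chi-square expected count of the
  cluster × condition table;
* **Clonal expansion** — 1 − H/ln k ≥ τ_x on the cluster's tumor-condition
  cells, with H = −Σ pᵢ ln pᵢ the Shannon entropy of clone-size
  proportions and k the number of clonotypes;
* **Proliferation** — fraction of cells detecting a cycling marker set
  (MKI67/TOP2A/PCNA) ≥ τ_p;
* **TCR-signaling activation** — median z-scored gene-set score across six
  TCR-signaling sets > τ_s.

Clonotypes are paired-chain identities (V, J, CDR3nt of both TRA and TRB;
highest-UMI chain per locus). Cells outside pTRT clusters sharing a
clonotype with any pTRT cell are **pTRT-relevant**; tumor-reactive =
pTRT ∪ pTRT-relevant, everything else is bystander. Marker candidates are
genes with bystander mean log-normalized expression < 0.5, ranked by the
delta value (expressing fraction in reactive − bystander cells), truncated
to the top 100, and scored by **reactive-cell precision**: the share of
tumor-reactive cells among all cells expressing the gene. Bulk fractions
are non-negative least squares against a rank-sum signature matrix,
renormalized to sum to one.

## Worked example

```bash
python analysis/01_simulate.py        # synthetic cohort with planted truth
python analysis/02_identify_ptrt.py   # four indices + pTRT call + tracing
python analysis/03_rank_markers.py    # bystander filter, delta, precision
python analysis/04_repertoire_diversity.py
python analysis/05_deconvolve_bulk.py
```

`02` prints the per-cluster index table and the call, e.g.

```
called pTRT clusters: ['cluster00', 'cluster01'] (planted: ['cluster00', 'cluster01'])
label tally: {'pTRT-irrelevant': 1665, 'pTRT': 325, 'pTRT-relevant': 10}
```

meaning both planted clusters are recovered and 335 of 2,000 cells are
called tumor-reactive. `03` prints the marker ranking:

```
          delta  precision  rank
ADGRG1   0.8817     0.9015   1.0
PCNA     0.2220     0.6833   2.0
...
ADGRG1: rank 1, precision 90.15% (closed-form planted value 90.15%), delta 0.882
```

the planted marker tops the precision ranking and its estimated precision
equals the value implied by the planted expressing fractions. `04` shows
marker⁺ cells with lower normalized entropy (expansion index 0.249 vs
0.077) and larger clones (24.4 vs 7.2 cells), and zero marker expression
among the planted virus-specific clonotypes. `05` recovers planted bulk
mixture fractions with mean absolute error ≈ 0.08 under 20% lognormal
noise.

The same pipeline runs from a shell via the `ptrtkit` CLI
(`simulate`, `run`, `markers`, `deconvolve`, `report`) driven by one YAML
config; see `ptrtkit run --help`.

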