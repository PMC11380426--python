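import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ptrtkit.datatypes import ContigTable, ExpressionDataset
from ptrtkit.io import load_gmt
from ptrtkit.repertoire import call_clonotypes
from ptrtkit.scoring import normalize_log1p
from ptrtkit.simulate import SimulationConfig, generate_dataset

RESOURCES = __import__("pathlib").Path(__import__("ptrtkit").__file__).parent / "resources"


def make_dataset(counts, genes=None, cells=None, meta=None, normalized=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i+1}" for i in range(counts.shape[1])]
    cells = cells or [f"c{i+1}" for i in range(counts.shape[0])]
    if meta is not None:
        meta = pd.DataFrame(meta, index=pd.Index(cells, name="cell_id"))
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(cells),
        cell_meta=meta,
        normalized=None if normalized is None else sp.csr_matrix(np.asarray(normalized, dtype=float)),
    )


def make_contigs(rows):
    """rows: list of (cell, chain, v, j, cdr3_nt, cdr3_aa, productive, umis)."""
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
                 "productive", "umi_count"],
    )
    return ContigTable(df=df)


@pytest.fixture(scope="session")
def signaling_sets():
    return load_gmt(RESOURCES / "tcr_signaling.gmt")


@pytest.fixture(scope="session")
def sim_default():
    """One default-config simulation shared across tests (seed 1)."""
    ds, contigs, truth = generate_dataset(SimulationConfig(seed=1))
    ds = normalize_log1p(ds)
    assign = call_clonotypes(contigs)
    return ds, contigs, truth, assign
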