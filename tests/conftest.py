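import numpy as np
import pandas as pd
import pytest

import stemindex as si
from stemindex import signatures as sg
from stemindex import single_cell as sc
from stemindex import synthetic as syn


@pytest.fixture(scope="session")
def sc_default():
    """Default synthetic single-cell cohort (5 patients x 400 cells + low-quality)."""
    return syn.simulate_single_cell(syn.ScSimConfig(seed=0))


@pytest.fixture(scope="session")
def sc_classified(sc_default):
    """QC-passed cells scored and classified with unrounded 95th-pct cutoffs."""
    adata, cell_truth, gene_truth = sc_default
    metrics = sc.qc_filter(sc.qc_metrics(adata))
    passed = adata[metrics["qc_pass"].to_numpy()].copy()
    sc.logcounts(passed)
    cbc = si.GeneSignature("CBC", tuple(g for g in adata.var_names if g.startswith("CBCM")))
    rsc = si.GeneSignature("RSC", tuple(g for g in adata.var_names if g.startswith("RSCM")))
    tab = metrics.loc[metrics["qc_pass"]].copy()
    tab["cbc_value"] = sc.cell_signature_value(passed, cbc)
    tab["rsc_value"] = sc.cell_signature_value(passed, rsc)
    cutoffs = sc.ClassificationCutoffs(
        cbc_cutoff=sc.derive_cutoffs(tab["cbc_value"], rounding_step=0),
        rsc_cutoff=sc.derive_cutoffs(tab["rsc_value"], rounding_step=0),
    )
    tab = sc.classify_cells(tab, cutoffs)
    tab["population"] = passed.obs["population"].to_numpy()
    return tab, cutoffs


@pytest.fixture(scope="session")
def sc_pseudobulk(sc_default):
    adata, _, _ = sc_default
    return sg.pseudobulk_aggregate(adata, adata.obs["cell_type"], adata.obs["patient"])


@pytest.fixture
def toy_pseudobulk():
    """Hand-built pseudobulk: 3 cell types x 5 patients, planted specific genes.

    EPI_HI: ~100 raw counts in every epithelial patient vs 1 in all rivals
    (clearly specific). FLAT_EQ/BASE*: identical in stroma and myeloid (margin
    0, never specific). EPI_MOSTLY: high in epithelium for 4/5 patients but
    collapsed in one, so the patient-replicate test cannot reach p < 0.01.
    """
    cell_types = ["epithelial", "stroma", "myeloid"]
    patients = [f"P{i}" for i in range(5)]
    cols = pd.MultiIndex.from_product([cell_types, patients], names=["cell_type", "patient"])
    genes = ["EPI_HI", "FLAT_EQ", "EPI_MOSTLY", "BASE1", "BASE2"]
    data = np.zeros((len(genes), len(cols)), dtype=int)
    for ci, (ct, pat) in enumerate(cols):
        pi = int(pat[1])
        data[0, ci] = 100 + pi if ct == "epithelial" else 1
        data[1, ci] = 50
        if ct == "epithelial":
            data[2, ci] = 5 if pi == 4 else 90
        else:
            data[2, ci] = 30
        data[3, ci] = 20
        data[4, ci] = 30
    counts = pd.DataFrame(data, index=genes, columns=cols)
    n_cells = pd.Series(10, index=cols)
    return sg.PseudobulkMatrix(counts=counts, n_cells=n_cells)
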