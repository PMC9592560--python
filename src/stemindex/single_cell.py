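"""Single-cell QC, signature scoring and CBC/RSC/mixed classification.

Cells are filtered on UMI depth, mitochondrial fraction and detected-gene
count; the per-cell signature value is the mean logcounts over signature
genes; positivity cutoffs are percentile-derived from the cell population
(default: 95th percentile, rounded to the nearest 0.05 logcounts) and cells
are classed CBC, RSC, mixed (double-positive) or negative by strict
comparison against the cutoffs.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .signatures import GeneSignature

__all__ = [
    "QcThresholds",
    "ClassificationCutoffs",
    "load_mtx",
    "qc_metrics",
    "qc_filter",
    "logcounts",
    "cell_signature_value",
    "derive_cutoffs",
    "classify_cells",
]

MITO_REGEX_HUMAN = r"^MT-"
MITO_REGEX_MOUSE = r"^mt-"


@dataclass(frozen=True)
class QcThresholds:
    """Cell QC gates.

    ``min_umi`` is strict (> 1000 UMI passes at 1001, not 1000) and
    ``max_mito`` strict (< 30%), while the detected-gene bounds are inclusive.
    """

    min_umi: int = 1000
    max_mito: float = 0.30
    min_genes: int = 2000
    max_genes: int = 6000

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not 0 < self.max_mito < 1:
            raise ValueError("max_mito must be in (0, 1)")


@dataclass(frozen=True)
class ClassificationCutoffs:
    """Positivity cutoffs on the logcounts scale."""

    cbc_cutoff: float
    rsc_cutoff: float
    percentile: float = 95.0
    rounding_step: float = 0.05

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cbc_cutoff) and np.isfinite(self.rsc_cutoff)):
            raise ValueError("cutoffs must be finite")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


def load_mtx(mtx_path, features_path, barcodes_path, metadata_path=None):
    """Load an MTX triplet (genes x cells on disk) into AnnData (cells x genes).

    ``metadata_path`` is an optional TSV with a ``barcode`` column and
    per-cell annotations (e.g. ``patient``) merged into ``.obs``.
    """
    import anndata as ad
    from scipy.io import mmread

    X = sp.csr_matrix(mmread(mtx_path).T)
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"barcode": str}).set_index("barcode")
        adata.obs = adata.obs.join(meta, how="left")
    return adata


def qc_metrics(adata, mito_regex: str = MITO_REGEX_HUMAN) -> pd.DataFrame:
    """Per-cell umi_count, genes_detected and mito_fraction from raw counts."""
    X = adata.X
    if sp.issparse(X):
        umi = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        umi = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
    mito_mask = np.array([bool(re.search(mito_regex, g)) for g in adata.var_names])
    if mito_mask.any():
        sub = X[:, mito_mask]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
    return pd.DataFrame(
        {
            "umi_count": umi.astype(int),
            "genes_detected": detected.astype(int),
            "mito_fraction": frac,
        },
        index=adata.obs_names,
    )


def qc_filter(cells: pd.DataFrame, thr: QcThresholds | None = None) -> pd.DataFrame:
    """Apply QC gates; returns the table with ``qc_pass`` and ``qc_reason``.

    A cell passes iff umi_count > min_umi, mito_fraction < max_mito and
    min_genes <= genes_detected <= max_genes. Failing cells get a
    comma-joined reason code (low_umi, high_mito, low_genes, high_genes).
    """
    thr = thr or QcThresholds()
    for col in ("umi_count", "genes_detected", "mito_fraction"):
        if col not in cells.columns:
            raise KeyError(f"cells table missing QC metric {col!r}")
    out = cells.copy()
    reasons = []
    for _, row in out.iterrows():
        r = []
        if not row["umi_count"] > thr.min_umi:
            r.append("low_umi")
        if not row["mito_fraction"] < thr.max_mito:
            r.append("high_mito")
        if row["genes_detected"] < thr.min_genes:
            r.append("low_genes")
        if row["genes_detected"] > thr.max_genes:
            r.append("high_genes")
        reasons.append(",".join(r))
    out["qc_reason"] = reasons
    out["qc_pass"] = [r == "" for r in reasons]
    if not out["qc_pass"].any():
        warnings.warn("no cell passed QC")
    return out


def logcounts(adata, target_sum: float = 1e4, inplace: bool = True):
    """Depth-normalize to ``target_sum`` counts per cell and log1p.

    Stored in ``adata.layers['logcounts']``. The scale matches the common
    single-cell convention (natural log of 1 + counts scaled to 10,000 per
    cell).
    """
    import scanpy as sc

    if not inplace:
        adata = adata.copy()
    norm = sc.pp.normalize_total(adata, target_sum=target_sum, inplace=False)["X"]
    adata.layers["logcounts"] = norm.log1p() if sp.issparse(norm) else np.log1p(norm)
    return adata


def cell_signature_value(adata, sig: GeneSignature, layer: str = "logcounts") -> pd.Series:
    """Mean logcounts over signature genes, per cell.

    Signature genes absent from the matrix are excluded from the denominator
    (reported once in a warning); zero overlap is an error.
    """
    present = [g for g in sig.genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} found in the matrix")
    if len(present) < len(sig.genes):
        warnings.warn(
            f"signature {sig.name!r}: {len(sig.genes) - len(present)} gene(s) absent "
            f"from the matrix; mean taken over {len(present)} genes"
        )
    X = adata[:, present].layers[layer] if layer else adata[:, present].X
    if sp.issparse(X):
        vals = np.asarray(X.mean(axis=1)).ravel()
    else:
        vals = np.asarray(X).mean(axis=1)
    return pd.Series(vals, index=adata.obs_names, name=f"{sig.name.lower()}_value")


def derive_cutoffs(
    values, percentile: float = 95.0, rounding_step: float = 0.05
) -> float:
    """Population-percentile positivity cutoff, rounded to a grid.

    Linear-interpolation percentile of the values, then rounded to the nearest
    multiple of ``rounding_step`` with ties rounding half up; a step of 0
    disables rounding. Requires >= 20 cells and finite values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20:
        raise ValueError(f"need >= 20 cells to place a percentile cutoff (got {v.size})")
    if not np.isfinite(v).all():
        raise ValueError("non-finite signature values")
    q = float(np.percentile(v, percentile, method="linear"))
    if rounding_step == 0:
        return q
    return round_half_up(q, rounding_step)


def round_half_up(x: float, step: float) -> float:
    """Round to the nearest multiple of ``step``; exact halves round up."""
    # guard the quotient against binary representation error (0.425/0.05
    # evaluates just below 8.5) so ties genuinely round up
    q = np.round(x / step, 9)
    k = math.floor(q + 0.5)
    return float(np.round(k * step, 10))


def classify_cells(
    cells: pd.DataFrame,
    cutoffs: ClassificationCutoffs,
    cbc_col: str = "cbc_value",
    rsc_col: str = "rsc_value",
) -> pd.DataFrame:
    """Assign CBC / RSC / mixed / negative classes by strict cutoff excess.

    mixed: both signature values strictly above their cutoffs; CBC or RSC:
    only that value above; negative otherwise. Assumes QC-passed cells.
    """
    for col in (cbc_col, rsc_col):
        if col not in cells.columns:
            raise KeyError(f"cells table missing {col!r}")
    out = cells.copy()
    cbc_pos = out[cbc_col].to_numpy() > cutoffs.cbc_cutoff
    rsc_pos = out[rsc_col].to_numpy() > cutoffs.rsc_cutoff
    cls = np.where(
        cbc_pos & rsc_pos, "mixed", np.where(cbc_pos, "CBC", np.where(rsc_pos, "RSC", "negative"))
    )
    out["cell_class"] = cls
    return out
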