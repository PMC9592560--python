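"""Gene signatures: GMT IO, pseudobulk aggregation, cell-type specificity and
signature refinement.

The regenerative stem cell (RSC) and crypt-base columnar (CBC) signatures used
for the stem cell index are ordinary gene lists; this module houses the
container, the GMT parser/writer, and the refinement procedure that restricts a
signature to genes of predominantly epithelial origin using single-cell
pseudobulk profiles:

1. raw counts are summed per (cell type, patient) group ("pseudobulk");
2. a gene is *specific* to a cell type when its depth-adjusted pseudobulk
   expression exceeds every rival cell type by at least a raw-count margin and
   every pairwise patient-replicate test is significant (default p < 0.01);
3. signature genes are hierarchically clustered on z-scored cell-type mean
   log-CPM profiles, and clusters that are stromal-dominant, epithelial with
   high stromal expression, or flat are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "GeneSignature",
    "PseudobulkMatrix",
    "SpecificityParams",
    "SpecificityCall",
    "ClusterParams",
    "read_gmt",
    "write_gmt",
    "pseudobulk_aggregate",
    "classify_specificity",
    "refine_signature",
    "map_orthologs",
]


class GmtParseError(ValueError):
    """Raised for a malformed GMT line."""


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered set of gene identifiers.

    Parameters
    ----------
    name
        Short label, e.g. ``"RSC"`` or ``"CBC"``. Must be non-empty.
    genes
        Ordered, unique gene identifiers.
    species
        ``"human"`` or ``"mouse"``.
    provenance
        Free-text origin note.
    """

    name: str
    genes: tuple[str, ...]
    species: str = "human"
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        if any(not g for g in genes):
            raise ValueError(f"signature {self.name!r} contains empty gene ids")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def subset(self, keep, provenance_suffix: str = "") -> "GeneSignature":
        """Return a new signature restricted to ``keep``, preserving order."""
        keep = set(keep)
        return replace(
            self,
            genes=tuple(g for g in self.genes if g in keep),
            provenance=(self.provenance + provenance_suffix).strip(),
        )


def read_gmt(path) -> list[GeneSignature]:
    """Parse a tab-separated GMT file into a list of signatures.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``. Duplicate
    genes within a line are collapsed (with a warning); lines with fewer than
    three fields raise :class:`GmtParseError` naming the line number.
    """
    sigs: list[GeneSignature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # tolerate trailing empty fields
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                warnings.warn(
                    f"{path}: line {lineno} ({name}): collapsed {dups} duplicate gene(s)"
                )
            sigs.append(GeneSignature(name=name, genes=tuple(genes), provenance=desc))
    return sigs


def write_gmt(sigs, path) -> None:
    """Write signatures as GMT (description = provenance, or 'na')."""
    with open(path, "w", encoding="utf-8") as fh:
        for sig in sigs:
            desc = sig.provenance.replace("\t", " ") or "na"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# Pseudobulk


@dataclass
class PseudobulkMatrix:
    """Gene x (cell type, patient) matrix of summed raw counts.

    ``counts`` has a two-level column MultiIndex ``(cell_type, patient)``;
    ``n_cells`` records how many cells were aggregated into each column.
    """

    counts: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.nlevels != 2:
            raise ValueError("counts columns must be a (cell_type, patient) MultiIndex")
        if (self.n_cells < 1).any():
            raise ValueError("every pseudobulk column must aggregate >= 1 cell")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("pseudobulk counts must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns.get_level_values(0).unique())

    @property
    def patients(self) -> list[str]:
        return list(self.counts.columns.get_level_values(1).unique())


def pseudobulk_aggregate(counts, cell_type, patient) -> PseudobulkMatrix:
    """Sum raw counts of cells sharing (cell type, patient) into pseudobulk.

    Parameters
    ----------
    counts
        Gene x cell DataFrame of non-negative integer counts, or an AnnData
        (cells x genes; its ``X`` is transposed internally).
    cell_type, patient
        Per-cell labels, aligned with the columns of ``counts``. Missing
        (NaN/empty) labels raise a ``ValueError`` naming the offending cells.
    """
    if hasattr(counts, "X"):  # AnnData
        import scipy.sparse as sp

        X = counts.X
        mat = X.toarray() if sp.issparse(X) else np.asarray(X)
        counts = pd.DataFrame(mat.T, index=counts.var_names, columns=counts.obs_names)
    cell_type = pd.Series(np.asarray(cell_type, dtype=object), index=counts.columns)
    patient = pd.Series(np.asarray(patient, dtype=object), index=counts.columns)

    bad = [
        str(c)
        for c, ct, p in zip(counts.columns, cell_type, patient)
        if ct is None or p is None or pd.isna(ct) or pd.isna(p) or ct == "" or p == ""
    ]
    if bad:
        raise ValueError(f"cells with missing cell_type/patient labels: {bad[:10]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    groups = counts.T.groupby([cell_type, patient], sort=True)
    agg = groups.sum().T
    agg.columns = pd.MultiIndex.from_tuples(agg.columns, names=["cell_type", "patient"])
    n_cells = groups.size()
    n_cells.index = agg.columns
    return PseudobulkMatrix(counts=agg, n_cells=n_cells)


# ---------------------------------------------------------------------------
# Specificity


@dataclass(frozen=True)
class SpecificityParams:
    """Parameters of the cell-type specificity rule.

    ``alpha`` is the per-pair significance level (default 0.01) and ``margin``
    the raw-count excess (default 1) a gene must show over every rival cell
    type on depth-adjusted total pseudobulk.
    """

    alpha: float = 0.01
    margin: float = 1.0
    test: str = "welch-t"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.test != "welch-t":
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    cls: str  # "specific-to:<cell_type>" or "non-specific"
    margin: float  # min depth-adjusted count difference over rivals
    max_p: float  # largest pairwise p-value for the winning cell type

    @property
    def cell_type(self) -> str | None:
        if self.cls.startswith("specific-to:"):
            return self.cls.split(":", 1)[1]
        return None


def _depth_adjusted_totals(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Total pseudobulk per cell type, rescaled to a common library size.

    Cell-type totals are summed over patients and each total column is scaled
    to the mean total library size, so the raw-count margin compares counts at
    matched depth rather than raw cell-number imbalance.
    """
    totals = pb.counts.T.groupby(level="cell_type", sort=True).sum().T
    lib = totals.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("cell type with zero total counts")
    return totals * (lib.mean() / lib)


def classify_specificity(
    pb: PseudobulkMatrix, params: SpecificityParams | None = None
) -> list[SpecificityCall]:
    """Call each gene specific to one cell type, or non-specific.

    A gene is specific to cell type ``c`` iff its depth-adjusted total
    pseudobulk expression exceeds every rival cell type by at least
    ``params.margin`` raw counts (strictly greater when the margin is 0), and
    each Welch t-test of log1p-CPM patient replicates (``c`` vs rival) has
    p < ``params.alpha``. Deterministic; at most one cell type can win.
    """
    params = params or SpecificityParams()
    cell_types = pb.cell_types
    if len(cell_types) < 2:
        raise ValueError("need >= 2 cell types")
    reps: dict[str, np.ndarray] = {}
    for ct in cell_types:
        cols = pb.counts.xs(ct, axis=1, level="cell_type")
        if cols.shape[1] < 2:
            raise ValueError(
                f"cell type {ct!r} has a single patient replicate; the pairwise "
                "significance test is undefined — aggregate more patients or relax "
                "the rule"
            )
        lib = cols.sum(axis=0).to_numpy()
        if (lib <= 0).any():
            raise ValueError(f"zero-depth pseudobulk column in cell type {ct!r}")
        reps[ct] = np.log1p(cols.to_numpy() / lib * 1e6)  # gene x patient log1p-CPM

    adj = _depth_adjusted_totals(pb)  # gene x cell type
    adj_np = adj.to_numpy()

    calls: list[SpecificityCall] = []
    for gi, gene in enumerate(adj.index):
        row = adj_np[gi]
        winner = int(np.argmax(row))
        rivals = [j for j in range(len(adj.columns)) if j != winner]
        diffs = row[winner] - row[rivals]
        margin = float(diffs.min())
        ok_margin = margin >= params.margin and (row[winner] > row[rivals]).all()
        if not ok_margin:
            calls.append(SpecificityCall(str(gene), "non-specific", margin, np.nan))
            continue
        ct = adj.columns[winner]
        x = reps[ct][gi]
        max_p = 0.0
        for j in rivals:
            y = reps[adj.columns[j]][gi]
            if np.allclose(x.var(), 0) and np.allclose(y.var(), 0):
                p = 0.0 if x.mean() != y.mean() else 1.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            max_p = max(max_p, p)
        if max_p < params.alpha:
            calls.append(SpecificityCall(str(gene), f"specific-to:{ct}", margin, max_p))
        else:
            calls.append(SpecificityCall(str(gene), "non-specific", margin, max_p))
    # uniqueness is structural: only the argmax cell type can win, and it must
    # be strictly above every rival
    return calls


def specificity_table(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (gene, class, margin, max_p)."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "class": [c.cls for c in calls],
            "margin": [c.margin for c in calls],
            "max_p": [c.max_p for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Refinement


@dataclass(frozen=True)
class ClusterParams:
    """Hierarchical-clustering refinement parameters.

    Distance is 1 - Pearson correlation of z-scored cell-type mean log-CPM
    profiles, average linkage, cut into ``n_clusters`` flat clusters (default
    ``min(8, n_genes // 5)``). A cluster is dropped when its centroid is
    stromal-dominant, epithelial but with stromal z above
    ``stromal_z_threshold``, flat (max z below ``flat_z_threshold``), or — when
    ``keep_epithelial_only`` — dominated by any non-epithelial cell type.
    """

    n_clusters: int | None = None
    stromal_z_threshold: float = 0.5
    flat_z_threshold: float = 0.5
    epithelial_label: str = "epithelial"
    stromal_label: str = "stroma"
    keep_epithelial_only: bool = True
    linkage: str = "average"


def _celltype_log_cpm(pb: PseudobulkMatrix) -> pd.DataFrame:
    totals = pb.counts.T.groupby(level="cell_type", sort=True).sum().T
    lib = totals.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("cell type with zero total counts")
    return np.log2(totals / lib * 1e6 + 1.0)


def refine_signature(
    sig: GeneSignature,
    pb: PseudobulkMatrix,
    calls: list[SpecificityCall] | None = None,
    params: ClusterParams | None = None,
) -> GeneSignature:
    """Restrict a signature to genes of predominantly epithelial origin.

    Signature genes absent from the pseudobulk are dropped with a warning.
    When ``calls`` is given, genes called specific to a non-epithelial cell
    type are excluded up front. The remaining genes are clustered on z-scored
    cell-type mean log-CPM profiles and clusters failing the epithelial rule
    (see :class:`ClusterParams`) are removed. Gene order is preserved; the
    result is a subset of the input and the procedure is idempotent on its own
    output for a fixed pseudobulk.
    """
    params = params or ClusterParams()
    present = [g for g in sig.genes if g in pb.counts.index]
    missing = len(sig.genes) - len(present)
    if missing:
        warnings.warn(
            f"{missing}/{len(sig.genes)} signature genes absent from pseudobulk; dropped"
        )
    if calls is not None:
        by_gene = {c.gene: c for c in calls}
        drop = {
            g
            for g in present
            if (c := by_gene.get(g)) is not None
            and c.cell_type is not None
            and c.cell_type != params.epithelial_label
        }
        present = [g for g in present if g not in drop]
    if len(present) < 3:
        raise ValueError(
            f"only {len(present)} signature genes found in pseudobulk; "
            "clustering is degenerate (need >= 3)"
        )

    prof = _celltype_log_cpm(pb).loc[present]  # gene x cell type
    mu = prof.mean(axis=1).to_numpy()[:, None]
    sd = prof.std(axis=1, ddof=0).to_numpy()[:, None]
    z = (prof.to_numpy() - mu) / np.where(sd > 0, sd, 1.0)
    z[np.repeat(sd == 0, z.shape[1], axis=1)] = 0.0

    n = len(present)
    k = params.n_clusters if params.n_clusters is not None else min(8, n // 5)
    k = max(k, 1)
    # correlation distance; constant (all-zero z) rows are uncorrelated with everything
    zc = z - z.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(zc, axis=1)
    safe = np.where(norm > 0, norm, 1.0)
    corr = (zc / safe[:, None]) @ (zc / safe[:, None]).T
    corr[norm == 0, :] = 0.0
    corr[:, norm == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=params.linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    cell_types = list(prof.columns)
    stromal_i = cell_types.index(params.stromal_label) if params.stromal_label in cell_types else None
    keep_genes: set[str] = set()
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        centroid = z[members].mean(axis=0)
        dominant = cell_types[int(np.argmax(centroid))]
        max_z = float(centroid.max())
        stromal_z = float(centroid[stromal_i]) if stromal_i is not None else -np.inf
        if max_z < params.flat_z_threshold:
            continue  # no clear cell-type-specific expression
        if dominant == params.stromal_label:
            continue  # stromal-dominant
        if dominant == params.epithelial_label and stromal_z > params.stromal_z_threshold:
            continue  # epithelial with high stromal expression
        if params.keep_epithelial_only and dominant != params.epithelial_label:
            continue
        keep_genes.update(present[i] for i in members)

    if not keep_genes:
        warnings.warn(f"signature {sig.name!r}: refinement removed every gene")
    return sig.subset(keep_genes, provenance_suffix=" | refined by cell-type specificity")


# ---------------------------------------------------------------------------
# Orthologs


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a TSV ortholog table with columns mouse_gene, human_gene[, confidence]."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mouse_gene", "human_gene"}
    if not required.issubset(tab.columns):
        raise ValueError(f"ortholog table must have columns {sorted(required)}")
    if tab[list(required)].isna().any().any() or (tab[list(required)] == "").any().any():
        raise ValueError("ortholog table contains empty identifiers")
    return tab


def map_orthologs(
    sig: GeneSignature, table: pd.DataFrame, target_species: str = "human"
) -> GeneSignature:
    """Map a signature across species via an ortholog table.

    Unmapped genes are dropped (count reported in a warning); the output is
    deduplicated, preserving first occurrence. When a gene has several
    candidate orthologs and the table carries a ``confidence`` column, only
    the highest-confidence ("high" over anything else) row is used.
    """
    if target_species == sig.species:
        raise ValueError("signature is already in the target species")
    src, dst = ("mouse_gene", "human_gene") if target_species == "human" else ("human_gene", "mouse_gene")
    tab = table
    if "confidence" in tab.columns:
        tab = tab.sort_values(
            by="confidence", key=lambda s: (s != "high").astype(int), kind="stable"
        )
    mapping: dict[str, str] = {}
    for _, row in tab.iterrows():
        mapping.setdefault(row[src], row[dst])

    mapped: list[str] = []
    seen: set[str] = set()
    unmapped = 0
    for g in sig.genes:
        h = mapping.get(g)
        if h is None:
            unmapped += 1
            continue
        if h not in seen:
            seen.add(h)
            mapped.append(h)
    if unmapped:
        warnings.warn(f"{unmapped}/{len(sig.genes)} genes had no ortholog and were dropped")
    if not mapped:
        raise ValueError(f"no gene of signature {sig.name!r} could be mapped")
    return GeneSignature(
        name=sig.name,
        genes=tuple(mapped),
        species=target_species,
        provenance=(sig.provenance + " | ortholog-mapped").strip(),
    )
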