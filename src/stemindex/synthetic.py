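"""Synthetic cohorts with known ground truth.

Every pipeline stage is testable without external accessions: bulk cohorts
are negative-binomial mixtures of a CBC archetype and an RSC archetype plus a
non-epithelial (stromal) contamination profile; single-cell cohorts draw
multinomial counts per cell from population-specific expression programs
(CBC, RSC, double-positive, other epithelial, stromal, myeloid, lymphoid)
with per-patient structure, variable UMI depth and a planted low-quality
fraction; paired pre/post cohorts plant static/plastic labels and per-group
responder rates; biopsy tables plant a design intraclass correlation.

All generators are deterministic under a seed: the top-level seed expands to
per-component streams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import ExpressionMatrix
from .signatures import GeneSignature

__all__ = [
    "BulkSimConfig",
    "ScSimConfig",
    "PairedSimConfig",
    "simulate_bulk",
    "simulate_single_cell",
    "simulate_paired",
    "simulate_biopsies",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# Bulk mixtures


@dataclass(frozen=True)
class BulkSimConfig:
    """Bulk cohort as a CBC/RSC archetype mixture with stromal contamination.

    Per sample, the expected expression profile is
    ``(1 - c) * [(1 - f) * CBC + f * RSC] + c * stromal`` where ``f`` is the
    planted RSC mixing fraction and ``c`` the contamination fraction; counts
    are negative binomial around the profile scaled to the library size.
    Archetype marker blocks are elevated ``2**effect_lfc``-fold over baseline.
    """

    n_samples: int = 100
    n_genes: int = 2000
    n_cbc_genes: int = 100
    n_rsc_genes: int = 100
    n_stromal_genes: int = 100
    effect_lfc: float = 2.0
    dispersion: float = 0.2
    contamination: float = 0.0
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    rsc_fractions: tuple[float, ...] | None = None  # default: uniform grid on [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cbc_genes + self.n_rsc_genes + self.n_stromal_genes > self.n_genes:
            raise ValueError("marker blocks exceed n_genes")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")


def simulate_bulk(cfg: BulkSimConfig):
    """Simulate a bulk RNA-seq cohort.

    Returns ``(ExpressionMatrix[rnaseq-counts], truth, signatures)`` where
    ``truth`` holds the planted per-sample rsc_fraction, contamination and
    library size, and ``signatures`` the planted CBC and RSC marker gene
    lists (usable directly for enrichment scoring).
    """
    rng = _rng(cfg.seed, 0)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    cbc_idx = np.arange(cfg.n_cbc_genes)
    rsc_idx = np.arange(cfg.n_cbc_genes, cfg.n_cbc_genes + cfg.n_rsc_genes)
    str_idx = np.arange(
        cfg.n_cbc_genes + cfg.n_rsc_genes,
        cfg.n_cbc_genes + cfg.n_rsc_genes + cfg.n_stromal_genes,
    )

    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    up = 2.0**cfg.effect_lfc
    cbc_prof = base.copy()
    cbc_prof[cbc_idx] *= up
    rsc_prof = base.copy()
    rsc_prof[rsc_idx] *= up
    stromal_prof = base.copy()
    stromal_prof[str_idx] *= up
    # markers of the opposite compartment are depleted in the stromal profile
    stromal_prof[cbc_idx] /= up
    stromal_prof[rsc_idx] /= up
    for prof in (cbc_prof, rsc_prof, stromal_prof):
        prof /= prof.sum()

    if cfg.rsc_fractions is not None:
        f = np.asarray(cfg.rsc_fractions, dtype=float)
        if f.size != cfg.n_samples:
            raise ValueError("rsc_fractions length must equal n_samples")
    else:
        f = np.linspace(0.0, 1.0, cfg.n_samples)
    lib = rng.uniform(*cfg.lib_size_range, size=cfg.n_samples)

    counts = np.empty((cfg.n_genes, cfg.n_samples), dtype=np.int64)
    for j in range(cfg.n_samples):
        mix = (1 - cfg.contamination) * ((1 - f[j]) * cbc_prof + f[j] * rsc_prof)
        mix = mix + cfg.contamination * stromal_prof
        mu = mix / mix.sum() * lib[j]
        counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)

    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples), platform="rnaseq-counts"
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "rsc_fraction": f,
            "contamination": cfg.contamination,
            "lib_size": lib,
        }
    ).set_index("sample")
    sigs = {
        "CBC": GeneSignature("CBC", tuple(genes[cbc_idx]), provenance="planted CBC block"),
        "RSC": GeneSignature("RSC", tuple(genes[rsc_idx]), provenance="planted RSC block"),
    }
    return expr, truth, sigs


# ---------------------------------------------------------------------------
# Single-cell populations


DEFAULT_PROPORTIONS: dict[str, float] = {
    "CBC": 0.05,
    "RSC": 0.05,
    "mixed": 0.01,
    "other-epithelial": 0.59,
    "stromal": 0.15,
    "myeloid": 0.10,
    "lymphoid": 0.05,
}

# population -> coarse cell-type compartment used for pseudobulk
COMPARTMENT: dict[str, str] = {
    "CBC": "epithelial",
    "RSC": "epithelial",
    "mixed": "epithelial",
    "other-epithelial": "epithelial",
    "stromal": "stroma",
    "myeloid": "myeloid",
    "lymphoid": "lymphocytes",
}


@dataclass(frozen=True)
class ScSimConfig:
    """Single-cell cohort with planted populations and marker programs.

    Population proportions default to a tumor-epithelium-like composition
    with 5% CBC, 5% RSC and 1% double-positive cells. Cells are allocated to
    populations by exact largest-remainder counts per patient (so the planted
    class balance is exact), and counts are multinomial draws from the
    population's expression program at a lognormal UMI depth. A planted
    ``lowq_fraction`` of extra cells has low depth and high mitochondrial
    fraction and must fail QC.
    """

    n_patients: int = 5
    cells_per_patient: int = 400
    proportions: tuple[tuple[str, float], ...] = tuple(DEFAULT_PROPORTIONS.items())
    n_genes: int = 8000
    n_markers_per_pop: int = 30
    n_epithelial_common: int = 50
    n_stromal_markers: int = 50
    n_mito_genes: int = 10
    marker_lfc: float = 3.0
    depth_log_mean: float = np.log(7000.0)
    depth_log_sd: float = 0.2
    lowq_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions must sum to 1 (got {total})")
        need = (
            self.n_markers_per_pop * len(self.proportions)
            + self.n_epithelial_common
            + self.n_stromal_markers
            + self.n_mito_genes
        )
        if need > self.n_genes:
            raise ValueError("marker blocks exceed n_genes")


def _exact_allocation(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n cells to populations."""
    names = list(proportions)
    raw = np.array([proportions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts))


def simulate_single_cell(cfg: ScSimConfig):
    """Simulate a single-cell cohort.

    Returns ``(AnnData, cell_truth, gene_truth)``. ``AnnData.X`` holds raw
    counts (cells x genes, CSR); ``obs`` carries patient, population,
    cell_type (coarse compartment) and planted_lowq. ``gene_truth`` labels
    each gene with its planted role (population marker, epithelial-common,
    stromal marker, mito, or flat).
    """
    import anndata as ad

    rng = _rng(cfg.seed, 1)
    props = dict(cfg.proportions)
    pops = list(props)

    gene_names = []
    gene_role = []
    cursor = 0
    blocks: dict[str, np.ndarray] = {}
    for pop in pops:
        idx = np.arange(cursor, cursor + cfg.n_markers_per_pop)
        blocks[pop] = idx
        gene_names += [f"{pop.upper().replace('-', '')}M{i:03d}" for i in range(idx.size)]
        gene_role += [f"{pop}_marker"] * idx.size
        cursor += idx.size
    epi_common = np.arange(cursor, cursor + cfg.n_epithelial_common)
    gene_names += [f"EPI{i:03d}" for i in range(epi_common.size)]
    gene_role += ["epithelial_common"] * epi_common.size
    cursor += epi_common.size
    stromal_extra = np.arange(cursor, cursor + cfg.n_stromal_markers)
    gene_names += [f"STR{i:03d}" for i in range(stromal_extra.size)]
    gene_role += ["stromal_marker"] * stromal_extra.size
    cursor += stromal_extra.size
    mito_idx = np.arange(cursor, cursor + cfg.n_mito_genes)
    gene_names += [f"MT-SIM{i}" for i in range(mito_idx.size)]
    gene_role += ["mito"] * mito_idx.size
    cursor += mito_idx.size
    n_flat = cfg.n_genes - cursor
    gene_names += [f"FLAT{i:05d}" for i in range(n_flat)]
    gene_role += ["flat"] * n_flat

    base = rng.lognormal(mean=0.0, sigma=0.8, size=cfg.n_genes)
    base[mito_idx] = base.mean() * 40  # mito genes carry ~5% of a healthy cell's counts
    up = 2.0**cfg.marker_lfc

    prog: dict[str, np.ndarray] = {}
    for pop in pops:
        prof = base.copy()
        prof[blocks[pop]] *= up
        if pop == "mixed":
            prof[blocks["CBC"]] *= up
            prof[blocks["RSC"]] *= up
        if COMPARTMENT[pop] == "epithelial":
            prof[epi_common] *= up
        if pop == "stromal":
            prof[stromal_extra] *= up
        prog[pop] = prof / prof.sum()

    rows, cell_meta = [], []
    for pat in range(cfg.n_patients):
        patient = f"P{pat:02d}"
        alloc = _exact_allocation(cfg.cells_per_patient, props)
        for pop in pops:
            k = alloc[pop]
            if k == 0:
                continue
            depths = np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sd, size=k)).astype(int)
            rows.append(rng.multinomial(depths, prog[pop]))
            cell_meta += [(patient, pop, COMPARTMENT[pop], False)] * k
        n_lowq = int(round(cfg.lowq_fraction * cfg.cells_per_patient))
        for _ in range(n_lowq):
            pop = pops[rng.integers(len(pops))]
            depth = int(rng.uniform(100, 800))  # below the >1000 UMI gate
            prof = prog[pop].copy()
            prof[mito_idx] *= 20  # dying cell: mito-dominated transcriptome
            prof /= prof.sum()
            rows.append(rng.multinomial(depth, prof)[None, :])
            cell_meta.append((patient, pop, COMPARTMENT[pop], True))

    X = sp.csr_matrix(np.vstack(rows))
    obs = pd.DataFrame(
        cell_meta, columns=["patient", "population", "cell_type", "planted_lowq"]
    )
    obs.index = pd.Index([f"CELL{i:05d}" for i in range(len(obs))], name="barcode")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_names, name="gene")))
    gene_truth = pd.DataFrame({"gene": gene_names, "role": gene_role}).set_index("gene")
    return adata, obs.copy(), gene_truth


# ---------------------------------------------------------------------------
# Paired pre/post cohorts


@dataclass(frozen=True)
class PairedSimConfig:
    """Paired pre/post-treatment cohort with planted plasticity labels.

    Static tumors keep the sign of their index across treatment; plastic
    tumors flip it. Index magnitudes are drawn around ``index_magnitude``
    with ``noise_sd`` Gaussian noise (defaults keep the separation far above
    the noise so the sign rule recovers labels exactly). Responder labels are
    Bernoulli per group.
    """

    n_patients: int = 75
    fraction_plastic: float = 0.4
    index_magnitude: float = 0.3
    noise_sd: float = 0.05
    responder_rate_static: float = 0.6
    responder_rate_plastic: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_plastic <= 1:
            raise ValueError("fraction_plastic must be in [0, 1]")


def simulate_paired(cfg: PairedSimConfig):
    """Simulate paired pre/post stem cell indices.

    Returns ``(pairs, labels, truth)``: pairs has patient/pre_index/
    post_index; labels has patient/grade/responder; truth has the planted
    group and responder flag.
    """
    rng = _rng(cfg.seed, 2)
    n_plastic = int(round(cfg.fraction_plastic * cfg.n_patients))
    groups = np.array(["plastic"] * n_plastic + ["static"] * (cfg.n_patients - n_plastic))
    rng.shuffle(groups)

    patients = [f"PT{i:03d}" for i in range(cfg.n_patients)]
    pre_sign = rng.choice([-1.0, 1.0], size=cfg.n_patients)
    post_sign = np.where(groups == "plastic", -pre_sign, pre_sign)
    pre = pre_sign * cfg.index_magnitude + rng.normal(0, cfg.noise_sd, cfg.n_patients)
    post = post_sign * cfg.index_magnitude + rng.normal(0, cfg.noise_sd, cfg.n_patients)

    rate = np.where(groups == "plastic", cfg.responder_rate_plastic, cfg.responder_rate_static)
    responder = rng.random(cfg.n_patients) < rate
    grades = np.where(
        responder,
        rng.choice(["moderate", "marked"], size=cfg.n_patients),
        rng.choice(["none", "mild"], size=cfg.n_patients),
    )

    pairs = pd.DataFrame({"patient": patients, "pre_index": pre, "post_index": post})
    labels = pd.DataFrame({"patient": patients, "grade": grades, "responder": responder})
    truth = pd.DataFrame({"patient": patients, "group": groups, "responder": responder})
    return pairs, labels, truth


# ---------------------------------------------------------------------------
# Multiregional biopsies


def simulate_biopsies(
    n_tumors: int = 30,
    biopsies_per_tumor: int = 5,
    icc_design: float = 0.821,
    grand_mean: float = 1.0,
    total_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate multiregional-biopsy index values with a design ICC.

    Tumor effects ~ N(0, rho * sigma^2) and biopsy noise ~ N(0,
    (1 - rho) * sigma^2), so the population intraclass correlation equals
    ``icc_design``. Defaults emulate a reproducibility level with
    between-subject variation roughly double the within-subject variation.
    """
    if not 0 <= icc_design < 1:
        raise ValueError("icc_design must be in [0, 1)")
    rng = _rng(seed, 3)
    s2 = total_sd**2
    tumor_eff = rng.normal(0.0, np.sqrt(icc_design * s2), size=n_tumors)
    rows = []
    for t in range(n_tumors):
        noise = rng.normal(0.0, np.sqrt((1 - icc_design) * s2), size=biopsies_per_tumor)
        for b in range(biopsies_per_tumor):
            rows.append(
                {
                    "tumor": f"T{t:02d}",
                    "biopsy": f"B{b}",
                    "index": grand_mean + tumor_eff[t] + noise[b],
                }
            )
    return pd.DataFrame(rows)
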