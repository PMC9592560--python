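"""Cohort-level analytics on the stem cell index.

Covers the polarized-decile contrast (the 10% most CBC-skewed vs 10% most
RSC-skewed tumors), gain/loss categorization of copy-number segment means,
pathway mutation prevalence per decile, static/plastic classification of
paired pre-/post-treatment tumors with a Fisher exact association against
histological response, and one-way random-effects reproducibility statistics
(ICC and within-/between-subject coefficients of variation) for multiregional
biopsies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecileAssignment",
    "PlasticityCall",
    "ReproStats",
    "polarized_deciles",
    "categorize_cnv",
    "pathway_prevalence",
    "classify_plasticity",
    "fisher_association",
    "repro_stats",
]


@dataclass
class DecileAssignment:
    """Per-sample membership in the polarized deciles.

    ``table`` columns: stem_cell_index, cbc_score (tie-break), decile in
    {CBC-enriched, RSC-enriched, middle}, plus the predominance report
    (above-median RSC / CBC score flags).
    """

    table: pd.DataFrame
    n_per_decile: int


def polarized_deciles(result) -> DecileAssignment:
    """Segregate the 10% most polarized samples at each end of the index.

    Samples are ranked by stem cell index; the lowest decile is CBC-enriched,
    the highest RSC-enriched. Ties are broken by cbc_score (descending), then
    sample id. Requires n >= 10.
    """
    table = result.table if hasattr(result, "table") else result
    n = len(table)
    if n < 10:
        raise ValueError(f"polarized deciles need >= 10 samples (got {n})")
    k = int(round(0.10 * n))
    df = table.copy()
    if "cbc_score" not in df.columns:
        df["cbc_score"] = 0.0
    order = df.assign(_sid=df.index.astype(str)).sort_values(
        by=["stem_cell_index", "cbc_score", "_sid"],
        ascending=[True, False, True],
        kind="stable",
    )
    decile = pd.Series("middle", index=df.index, dtype=object)
    decile[order.index[:k]] = "CBC-enriched"
    decile[order.index[-k:]] = "RSC-enriched"
    df["decile"] = decile
    # predominance report: which signature is above its cohort median
    if "rsc_score" in df.columns:
        df["rsc_above_median"] = df["rsc_score"] > df["rsc_score"].median()
        df["cbc_above_median"] = df["cbc_score"] > df["cbc_score"].median()
    return DecileAssignment(table=df, n_per_decile=k)


def categorize_cnv(
    segments: pd.DataFrame,
    loss_threshold: float = -0.3,
    gain_threshold: float = 0.3,
    value_col: str = "value",
) -> pd.DataFrame:
    """Categorize copy-number segment means as loss (-1) / neutral (0) / gain (+1).

    Strict inequalities on both sides: a value of exactly +/-0.3 is neutral.
    """
    vals = segments[value_col].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite CNV values")
    out = segments.copy()
    out["category"] = np.where(vals < loss_threshold, -1, np.where(vals > gain_threshold, 1, 0))
    return out


def cnv_decile_frequency(calls: pd.DataFrame, deciles: DecileAssignment) -> pd.DataFrame:
    """Gain/loss frequency per segment id within each polarized decile."""
    dec = deciles.table["decile"]
    merged = calls.merge(
        dec.rename("decile"), left_on="sample", right_index=True, how="inner"
    )
    rows = []
    for (seg, d), grp in merged.groupby(["id", "decile"], sort=True):
        n = len(grp)
        rows.append(
            {
                "id": seg,
                "decile": d,
                "n": n,
                "gain_freq": float((grp["category"] == 1).mean()),
                "loss_freq": float((grp["category"] == -1).mean()),
            }
        )
    return pd.DataFrame(rows)


def pathway_prevalence(
    mutations: pd.DataFrame,
    pathways: dict[str, list[str]],
    deciles: DecileAssignment,
) -> pd.DataFrame:
    """Fraction of decile samples with >= 1 pathogenic mutation per pathway.

    ``mutations`` columns: sample, gene, pathogenic (bool); the table is
    assumed pre-filtered/flagged for pathogenicity upstream. Counts are
    reported alongside the fraction.
    """
    dec = deciles.table["decile"]
    muts = mutations[mutations["pathogenic"].astype(bool)]
    rows = []
    for pw_name, genes in pathways.items():
        gene_set = set(genes)
        hits = muts[muts["gene"].isin(gene_set)]
        if not gene_set or not mutations["gene"].isin(gene_set).any():
            warnings.warn(f"pathway {pw_name!r}: no gene found in the mutation table")
        carriers = set(hits["sample"])
        for d in ("CBC-enriched", "RSC-enriched", "middle"):
            samples = dec.index[dec == d]
            n = len(samples)
            if n == 0:
                continue
            k = sum(s in carriers for s in samples)
            rows.append(
                {
                    "pathway": pw_name,
                    "decile": d,
                    "n_samples": n,
                    "n_mutated": k,
                    "prevalence": k / n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plasticity


@dataclass(frozen=True)
class PlasticityCall:
    patient: str
    pre_index: float
    post_index: float
    pre_class: str  # RSC-positive / CBC-positive
    post_class: str
    group: str  # static / plastic


def _sign_class(index: float) -> str:
    # index > 0 -> RSC-positive; index <= 0 -> CBC-positive (strict reading of
    # "positive Index score"; an exact zero is a measure-zero case)
    return "RSC-positive" if index > 0 else "CBC-positive"


def classify_plasticity(pairs: pd.DataFrame) -> list[PlasticityCall]:
    """Classify paired pre/post tumors as static or plastic.

    ``pairs`` columns: patient, pre_index, post_index (one row per patient).
    A tumor is plastic when the sign class of the index flips between the
    pre-treatment and post-treatment sample.
    """
    required = {"patient", "pre_index", "post_index"}
    if not required.issubset(pairs.columns):
        raise KeyError(f"pairs table needs columns {sorted(required)}")
    incomplete = pairs[pairs[["pre_index", "post_index"]].isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"patients missing a pair member: {list(incomplete['patient'])}"
        )
    if pairs["patient"].duplicated().any():
        raise ValueError("duplicate patient rows in pairs table")
    calls = []
    for _, row in pairs.iterrows():
        pre_c = _sign_class(float(row["pre_index"]))
        post_c = _sign_class(float(row["post_index"]))
        calls.append(
            PlasticityCall(
                patient=str(row["patient"]),
                pre_index=float(row["pre_index"]),
                post_index=float(row["post_index"]),
                pre_class=pre_c,
                post_class=post_c,
                group="plastic" if pre_c != post_c else "static",
            )
        )
    return calls


RESPONDER_GRADES = frozenset({"moderate", "marked"})


def responder_flag(grade: str) -> bool:
    """Histological regression grade -> responder flag.

    Marked or moderate regression = responder; mild or none = non-responder.
    """
    grade = grade.lower()
    if grade not in {"none", "mild", "moderate", "marked"}:
        raise ValueError(f"unknown regression grade {grade!r}")
    return grade in RESPONDER_GRADES


def fisher_association(
    calls: list[PlasticityCall], labels: pd.DataFrame
) -> tuple[np.ndarray, float, float]:
    """2x2 static/plastic x responder/non-responder table with Fisher exact p.

    ``labels`` columns: patient and either ``responder`` (bool) or ``grade``.
    Returns (table, two-sided p, odds ratio). The two-sided p sums
    hypergeometric probabilities of tables (at fixed margins) no more likely
    than the observed one. The odds ratio is the sample OR with a Haldane 0.5
    correction when any cell is zero. A degenerate margin yields p = 1 with a
    warning.
    """
    lab = labels.copy()
    if "responder" not in lab.columns:
        if "grade" not in lab.columns:
            raise KeyError("labels need a 'responder' or 'grade' column")
        lab["responder"] = lab["grade"].map(responder_flag)
    resp = dict(zip(lab["patient"].astype(str), lab["responder"].astype(bool)))
    missing = [c.patient for c in calls if c.patient not in resp]
    if missing:
        raise ValueError(f"patients without a response label: {missing}")

    table = np.zeros((2, 2), dtype=int)  # rows: static, plastic; cols: responder, non
    for c in calls:
        i = 0 if c.group == "static" else 1
        j = 0 if resp[c.patient] else 1
        table[i, j] += 1

    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate margin in 2x2 table; association undefined (p = 1)")
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    a, b, c2, d = table.ravel().astype(float)
    if min(a, b, c2, d) == 0:
        a, b, c2, d = a + 0.5, b + 0.5, c2 + 0.5, d + 0.5
    odds = (a * d) / (b * c2)
    return table, p, float(odds)


# ---------------------------------------------------------------------------
# Multiregional-biopsy reproducibility


@dataclass
class ReproStats:
    """One-way random-effects reproducibility statistics.

    ``icc`` is ICC(1,1) = sigma2_between / (sigma2_between + sigma2_within);
    CVs are 100 * sigma / |grand mean| and are NaN when the grand mean is
    near zero (signed index scores can straddle zero).
    """

    icc: float
    within_cv: float
    between_cv: float
    sigma2_between: float
    sigma2_within: float
    grand_mean: float
    n_groups: int
    n_obs: int


def repro_stats(
    biopsies: pd.DataFrame,
    value_col: str = "index",
    group_col: str = "tumor",
    mean_tol: float = 1e-8,
) -> ReproStats:
    """Variance components, ICC and CVs from multiregional biopsies.

    One-way random-effects ANOVA with the unbalanced-design group size
    k0 = (N - sum(n_i^2)/N) / (a - 1): sigma2_between = (MSB - MSW)/k0
    (truncated at 0), sigma2_within = MSW, ICC = between/(between + within).
    All values identical -> ICC 0 with a warning.
    """
    df = biopsies[[group_col, value_col]].dropna()
    groups = [g[value_col].to_numpy(dtype=float) for _, g in df.groupby(group_col, sort=True)]
    a = len(groups)
    if a < 2:
        raise ValueError("need >= 2 tumors")
    sizes = np.array([len(g) for g in groups])
    if (sizes >= 2).sum() == 0:
        raise ValueError("need >= 2 biopsies for at least one tumor")
    N = int(sizes.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    k0 = (N - float(np.sum(sizes**2)) / N) / (a - 1)
    s2b = max((msb - msw) / k0, 0.0)
    s2w = msw
    total = s2b + s2w
    if total <= 0:
        warnings.warn("zero total variance; ICC undefined, returning 0")
        icc = 0.0
    else:
        icc = s2b / total
    if abs(grand) < mean_tol:
        warnings.warn("grand mean ~ 0; coefficients of variation undefined (NaN)")
        wcv = bcv = float("nan")
    else:
        wcv = 100.0 * np.sqrt(s2w) / abs(grand)
        bcv = 100.0 * np.sqrt(s2b) / abs(grand)
    return ReproStats(
        icc=float(icc),
        within_cv=float(wcv),
        between_cv=float(bcv),
        sigma2_between=float(s2b),
        sigma2_within=float(s2w),
        grand_mean=grand,
        n_groups=a,
        n_obs=N,
    )
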