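"""Isoform-specificity (τAS) and tissue-specificity (τ) indices.

τAS adapts the tissue-specificity index τ to isoform usage: for one gene
and one sex, each retained splice site contributes two isoforms with read
support x_i (inclusion) and y_i (exclusion), summed across that sex's
individuals. All supports are normalized by the gene-and-sex maximum, and

    τAS = Σ_i [(1 − x̂_i) + (1 − ŷ_i)] / (n − 1),   n = 2 · n_sites,

so an even representation of isoforms scores 0 and a single always-
expressed isoform scores 1.

Because detection power scales with expression, read counts of the more
highly expressed sex are scaled down to the lower-expressed sex per gene
before the index is computed; an optional library-size normalization
divides each sample's counts by its total library size first.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import JunctionCounts

log = logging.getLogger("sexsplice")


def tau_as_index(x: Sequence[float], y: Sequence[float]) -> float:
    """Evaluate τAS from per-site inclusion/exclusion supports of one
    gene and sex. Returns NaN when no site has any support."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equal-length 1-D site vectors")
    m = max(x.max(), y.max())
    if m <= 0:
        return float("nan")
    xh = x / m
    yh = y / m
    n = 2 * len(x)
    return float(((1 - xh) + (1 - yh)).sum() / (n - 1))


def tau_index(profile: Sequence[float]) -> float:
    """Tissue-specificity τ = Σ(1 − x̂_i)/(T − 1) with x̂ = x/max(x);
    0 for uniform profiles, 1 for single-tissue expression."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m <= 0:
        return float("nan")
    return float((1 - x / m).sum() / (len(x) - 1))


def normalize_by_library_size(counts: JunctionCounts,
                              library_sizes: Mapping[str, float]) -> JunctionCounts:
    """Divide every sample's junction counts by its total library size
    (sensitivity variant of τAS; outputs are real-valued)."""
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.samples)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("library sizes must be positive and cover all samples")
    return JunctionCounts(counts.ijc / sizes, counts.sjc / sizes)


def site_sex_counts(counts: JunctionCounts, events: pd.DataFrame,
                    meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, event) inclusion/exclusion supports summed within sex.

    Returns columns x_male, y_male, x_female, y_female indexed by
    (gene_id, event_id).
    """
    males = meta.loc[meta["sex"] == "male", "sample_id"].tolist()
    females = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
    out = pd.DataFrame(
        {
            "gene_id": events["gene_id"],
            "x_male": counts.ijc[males].sum(axis=1),
            "y_male": counts.sjc[males].sum(axis=1),
            "x_female": counts.ijc[females].sum(axis=1),
            "y_female": counts.sjc[females].sum(axis=1),
        }
    )
    out.index.name = "event_id"
    return out.reset_index().set_index(["gene_id", "event_id"])


def scale_counts_to_lower_sex(site_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's counts in the higher-expressed sex down to the
    lower-expressed sex's total (exact real ratio, no rounding).

    Genes with zero total in both sexes are dropped (logged).
    """
    out = site_counts.copy().astype(
        {c: float for c in ("x_male", "y_male", "x_female", "y_female")}
    )
    tot_m = out.groupby("gene_id")[["x_male", "y_male"]].transform("sum").sum(axis=1)
    tot_f = out.groupby("gene_id")[["x_female", "y_female"]].transform("sum").sum(axis=1)
    dead = (tot_m == 0) & (tot_f == 0)
    if dead.any():
        log.info("scale_counts_to_lower_sex: dropping %d genes with zero counts",
                 out.index[dead].get_level_values("gene_id").nunique())
        out = out[~dead]
        tot_m, tot_f = tot_m[~dead], tot_f[~dead]
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_m = np.where(tot_m > tot_f, tot_f / tot_m, 1.0)
        scale_f = np.where(tot_f > tot_m, tot_m / tot_f, 1.0)
    out[["x_male", "y_male"]] = out[["x_male", "y_male"]].mul(scale_m, axis=0)
    out[["x_female", "y_female"]] = out[["x_female", "y_female"]].mul(scale_f, axis=0)
    return out


def tau_as_site_filter(counts: JunctionCounts, meta: pd.DataFrame,
                       min_reads: int = 20, min_fraction: float = 0.5) -> pd.Index:
    """Splice sites with junction coverage of at least ``min_reads`` for
    both inclusion and exclusion in at least ``min_fraction`` of
    individuals, within either sex or across all individuals."""
    males = meta.loc[meta["sex"] == "male", "sample_id"].tolist()
    females = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
    ok = (counts.ijc >= min_reads) & (counts.sjc >= min_reads)
    passing = np.zeros(len(counts.ijc), dtype=bool)
    for group in (males, females, males + females):
        if group:
            passing |= (ok[group].mean(axis=1) >= min_fraction).to_numpy()
    return counts.ijc.index[passing]


def compute_tau_as(counts: JunctionCounts, events: pd.DataFrame,
                   meta: pd.DataFrame, min_reads: int = 20,
                   min_fraction: float = 0.5,
                   library_sizes: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-gene male and female τAS.

    Sites failing the coverage rule are excluded; the remaining per-sex
    sums are scaled to the lower-expressed sex per gene, then the index is
    evaluated per sex. Genes with no retained site are absent from the
    output.
    """
    kept = tau_as_site_filter(counts, meta, min_reads, min_fraction)
    if len(kept) == 0:
        return pd.DataFrame(
            columns=["gene_id", "tau_as_male", "tau_as_female", "n_isoforms", "n_sites_used"]
        )
    sub = counts.subset_events(kept)
    if library_sizes is not None:
        sub = normalize_by_library_size(sub, library_sizes)
    sites = site_sex_counts(sub, events.loc[kept], meta)
    sites = scale_counts_to_lower_sex(sites)
    rows = []
    for gid, grp in sites.groupby(level="gene_id"):
        n_sites = len(grp)
        rows.append(
            (
                gid,
                tau_as_index(grp["x_male"].to_numpy(), grp["y_male"].to_numpy()),
                tau_as_index(grp["x_female"].to_numpy(), grp["y_female"].to_numpy()),
                2 * n_sites,
                n_sites,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "tau_as_male", "tau_as_female", "n_isoforms", "n_sites_used"]
    )


def compute_tissue_tau(expression: pd.DataFrame) -> pd.DataFrame:
    """τ per gene from a genes × tissues expression matrix; all-zero
    profiles yield a missing τ."""
    if expression.shape[1] < 2:
        raise ValueError("need expression over at least 2 tissues")
    taus = [tau_index(row) if row.max() > 0 else np.nan
            for row in expression.to_numpy(dtype=float)]
    return pd.DataFrame(
        {"gene_id": expression.index, "tau": taus, "n_tissues": expression.shape[1]}
    )


def compare_tau_by_bias(tau_records: pd.DataFrame, bias: pd.DataFrame,
                        min_genes: int = 5) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank of male vs female τAS within each
    expression-bias class.

    ``bias`` carries gene_id and a ``bias`` column in
    {male, female, unbiased}. Classes with fewer than ``min_genes`` genes
    report a missing p.
    """
    merged = tau_records.merge(bias[["gene_id", "bias"]], on="gene_id")
    merged = merged.dropna(subset=["tau_as_male", "tau_as_female"])
    rows = []
    for cls in ("male", "female", "unbiased"):
        grp = merged[merged["bias"] == cls]
        med_m = grp["tau_as_male"].median()
        med_f = grp["tau_as_female"].median()
        diff = grp["tau_as_male"] - grp["tau_as_female"]
        if len(grp) < min_genes:
            stat, p = np.nan, np.nan
        elif np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(grp["tau_as_male"], grp["tau_as_female"])
        rows.append((cls, len(grp), med_m, med_f, med_m - med_f, stat, p))
    return pd.DataFrame(
        rows,
        columns=["bias_class", "n_genes", "median_tau_male", "median_tau_female",
                 "median_diff", "statistic", "p"],
    )
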