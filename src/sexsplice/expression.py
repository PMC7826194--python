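"""Gene-expression filtering, TMM normalization, and sex-differential
expression.

Counting uses constitutive exons only, so that splicing changes cannot
masquerade as expression changes. Normalization is the trimmed mean of
M-values (TMM): per-sample scaling factors from precision-weighted mean
log-ratios against a reference sample, after trimming extreme M and A
values, rescaled to geometric mean one.

The sex-differential test is a negative-binomial likelihood-ratio test
with a moment-estimated common dispersion shared across genes; the
decision rule for a sex-biased call is |log2FC| >= 1 and BH-FDR < 0.05.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("sexsplice")


def constitutive_gene_counts(exon_counts: pd.DataFrame,
                             excluded_exons: set[str]) -> pd.DataFrame:
    """Sum exon counts to genes using only constitutive exons.

    ``exon_counts`` has columns gene_id, exon_id plus one column per
    sample. Exons in ``excluded_exons`` (alternatively or differentially
    spliced) are dropped; genes losing all their exons are dropped with a
    log note. Unknown exon ids in the exclusion set raise a warning only.
    """
    known = set(exon_counts["exon_id"])
    unknown = excluded_exons - known
    if unknown:
        log.warning("constitutive_gene_counts: %d excluded exon ids not in the "
                    "count table", len(unknown))
    keep = ~exon_counts["exon_id"].isin(excluded_exons)
    kept = exon_counts[keep]
    before = exon_counts["gene_id"].nunique()
    out = kept.drop(columns=["exon_id"]).groupby("gene_id").sum()
    dropped = before - len(out)
    if dropped:
        log.info("constitutive_gene_counts: %d genes lost all exons", dropped)
    return out


def log_cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None,
            offset: float = 0.25) -> pd.DataFrame:
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    cpm = counts / library_sizes * 1e6
    return np.log2(cpm + offset)


def filter_low_expression(counts: pd.DataFrame, sexes: Mapping[str, str],
                          min_logcpm: float = 1.0, min_fraction: float = 0.5,
                          offset: float = 0.25) -> pd.DataFrame:
    """Keep genes at or above ``min_logcpm`` log2-CPM in at least
    ``min_fraction`` of the samples of each sex separately."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    lcpm = log_cpm(counts, lib, offset)
    keep = np.ones(len(counts), dtype=bool)
    for sex in ("male", "female"):
        cols = [s for s, sx in sexes.items() if sx == sex and s in counts.columns]
        if not cols:
            raise ValueError(f"no {sex} samples in count matrix")
        frac = (lcpm[cols] >= min_logcpm).mean(axis=1)
        keep &= (frac >= min_fraction).to_numpy()
    removed = int((~keep).sum())
    if removed:
        log.info("filter_low_expression: removed %d genes", removed)
    return counts[keep]


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference is the sample whose 75th-percentile CPM is closest to
    the mean of those quantiles. For every other sample, the factor is the
    precision-weighted mean of gene-wise log2 ratios (M) after discarding
    the most extreme ``trim_m`` of M-values and ``trim_a`` of average
    abundances (A), computed over genes expressed in both samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    q75 = (counts / lib).quantile(0.75)
    ref = (q75 - q75.mean()).abs().idxmin()

    factors = {}
    yr = counts[ref].to_numpy(dtype=float)
    nr = lib[ref]
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        ys = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        both = (ys > 0) & (yr > 0)
        if not both.any():
            log.warning("tmm_factors: sample %s shares no expressed genes with "
                        "reference; factor set to 1", s)
            factors[s] = 1.0
            continue
        ps, pr = ys[both] / ns, yr[both] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # inverse asymptotic variance of M as precision weight
        v = (ns - ys[both]) / (ns * ys[both]) + (nr - yr[both]) / (nr * yr[both])
        n = len(m)
        # rank-based double trim: trim_m / trim_a of genes from EACH tail
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[s] = float(2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Row sums of the NB log likelihood, var = mu + alpha mu^2."""
    mu = np.maximum(mu, 1e-10)
    if alpha <= 0:
        return (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=1)
    r = 1.0 / alpha
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=1)


def _fit_nb_mean(y: np.ndarray, depth: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """MLE of a shared per-gene base mean with per-sample depth offsets,
    by vectorized golden section on the log mean."""
    from .splicing import _golden_max

    start = np.log(np.maximum((y / depth).mean(axis=1), 1e-8))

    def obj(log_m: np.ndarray) -> np.ndarray:
        mu = np.exp(log_m)[:, None] * depth[None, :]
        return _nb_loglik(y, mu, alpha)

    # search centered windows around the moment start
    lo, hi = -30.0, 30.0
    x, ll = _golden_max(lambda t: obj(start + t), lo, hi, y.shape[0], iters=90)
    return np.exp(start + x), ll


def estimate_common_dispersion(counts: pd.DataFrame, groups: list[list[str]],
                               norm_factors: pd.Series | None = None,
                               min_mean: float = 5.0) -> float:
    """Method-of-moments common NB dispersion pooled over genes.

    For depth-normalized counts z = y/d, Var(z) = mu·E[1/d] + alpha·mu²
    within a group, so (s² - mu·mean(1/d))/mu² estimates alpha per gene;
    the pooled estimate is the 1%-trimmed mean over well-expressed genes
    and groups.
    """
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    depth = lib / np.exp(np.log(lib).mean())
    ests = []
    for cols in groups:
        d = depth[cols].to_numpy()
        z = counts[cols].to_numpy(dtype=float) / d
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        ok = m > min_mean
        if ok.sum() >= 10:
            u = (v[ok] - np.mean(1.0 / d) * m[ok]) / m[ok] ** 2
            lo, hi = np.quantile(u, [0.01, 0.99])
            ests.append(u[(u >= lo) & (u <= hi)].mean())
        elif ok.any():
            ests.append(np.mean((v[ok] - np.mean(1.0 / d) * m[ok]) / m[ok] ** 2))
    if not ests:
        return 0.0
    return float(max(0.0, np.mean(ests)))


def diff_expression(counts: pd.DataFrame, sexes: Mapping[str, str],
                    norm_factors: pd.Series | None = None,
                    fdr: float = 0.05, min_log2fc: float = 1.0,
                    pseudo_cpm: float = 0.25,
                    dispersion: float | None = None) -> pd.DataFrame:
    """Per-gene male-vs-female NB likelihood-ratio test and bias call.

    log2FC is male over female from normalized CPM means with a
    pseudo-count. Genes with zero counts in both sexes are skipped.
    """
    males = [s for s in counts.columns if sexes.get(s) == "male"]
    females = [s for s in counts.columns if sexes.get(s) == "female"]
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least 2 samples per sex")
    expressed = counts[males + females].sum(axis=1) > 0
    counts = counts[expressed]

    lib = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns)
    depth = (lib / np.exp(np.log(lib).mean()))

    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, [males, females],
                                                norm_factors)

    y_all = counts[males + females].to_numpy(dtype=float)
    d_all = depth[males + females].to_numpy()
    y_m = counts[males].to_numpy(dtype=float)
    d_m = depth[males].to_numpy()
    y_f = counts[females].to_numpy(dtype=float)
    d_f = depth[females].to_numpy()

    _, ll0 = _fit_nb_mean(y_all, d_all, dispersion)
    mu_m, ll_m = _fit_nb_mean(y_m, d_m, dispersion)
    mu_f, ll_f = _fit_nb_mean(y_f, d_f, dispersion)
    lrt = np.maximum(2.0 * (ll_m + ll_f - ll0), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    cpm_m = (counts[males] / lib[males] * 1e6).mean(axis=1)
    cpm_f = (counts[females] / lib[females] * 1e6).mean(axis=1)
    log2fc = np.log2((cpm_m + pseudo_cpm) / (cpm_f + pseudo_cpm))

    res = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc.to_numpy(),
            "p": p,
        }
    )
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    sig = (res["fdr"] < fdr) & (res["log2fc"].abs() >= min_log2fc)
    res["bias"] = np.select(
        [sig & (res["log2fc"] > 0), sig & (res["log2fc"] < 0)],
        ["male", "female"], default="unbiased",
    )
    res.attrs["dispersion"] = dispersion
    return res
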