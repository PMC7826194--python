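"""Percent-spliced-in quantification and sex-differential splicing.

PSI is the proportion of transcripts carrying the inclusion isoform at a
splice site, estimated from junction-spanning reads only. Because a skipped
exon contributes two inclusion junctions but one exclusion junction, raw
junction counts are normalized by these effective lengths before forming
the proportion (SE: 2 vs 1; MXE: 2 vs 2).

Differential splicing between two sample groups is tested per event with a
beta-binomial likelihood-ratio test on the junction-read proportion: the
null shares one proportion across both groups, the alternative fits one per
group, and twice the log-likelihood gap is referred to chi-square with one
degree of freedom. Overdispersion is a per-event method-of-moments
intraclass correlation shared by both groups.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from .io import JunctionCounts

log = logging.getLogger("sexsplice")

#: effective lengths (number of junctions supporting each form)
EFFECTIVE_LENGTHS = {"SE": (2, 1), "MXE": (2, 2)}

TESTABLE_TYPES = tuple(EFFECTIVE_LENGTHS)


def effective_lengths(event_types: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    l_inc = np.array([EFFECTIVE_LENGTHS[t][0] for t in event_types], dtype=float)
    l_exc = np.array([EFFECTIVE_LENGTHS[t][1] for t in event_types], dtype=float)
    return l_inc, l_exc


def compute_psi(counts: JunctionCounts, events: pd.DataFrame) -> pd.DataFrame:
    """Per-event, per-sample PSI with effective-length normalization.

    Events other than SE/MXE are dropped (logged). Samples with zero total
    junction reads for an event get a missing PSI, never a 0/0 error.

    Returns an event × sample float frame in [0, 1] with NaN for missing.
    """
    keep = events["event_type"].isin(TESTABLE_TYPES)
    if not keep.all():
        log.info("compute_psi: dropping %d non-SE/MXE events", (~keep).sum())
    ids = events.index[keep]
    ijc = counts.ijc.loc[ids].to_numpy(dtype=float)
    sjc = counts.sjc.loc[ids].to_numpy(dtype=float)
    l_inc, l_exc = effective_lengths(events.loc[ids, "event_type"])
    inc = ijc / l_inc[:, None]
    exc = sjc / l_exc[:, None]
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / total, np.nan)
    psi = np.clip(psi, 0.0, 1.0)
    return pd.DataFrame(psi, index=ids, columns=counts.samples)


def filter_events(counts: JunctionCounts, group_a: Sequence[str],
                  group_b: Sequence[str], min_reads: int = 20,
                  min_fraction: float = 0.5) -> pd.Index:
    """Events covered in both groups.

    An event is retained iff ijc >= min_reads AND sjc >= min_reads in at
    least ``min_fraction`` of the samples of *each* group.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both sample groups must be non-empty")
    ok = (counts.ijc >= min_reads) & (counts.sjc >= min_reads)
    keep = np.ones(len(counts.ijc), dtype=bool)
    for group in (group_a, group_b):
        frac = ok[list(group)].mean(axis=1)
        keep &= (frac >= min_fraction).to_numpy()
    return counts.ijc.index[keep]


def flag_alternative(psi: pd.DataFrame, group: Sequence[str],
                     min_fraction: float = 0.5) -> pd.Series:
    """True for events with 0 < PSI < 1 in more than ``min_fraction`` of the
    group's samples (strict interior, strict majority)."""
    sub = psi[list(group)]
    interior = (sub > 0) & (sub < 1)
    return interior.sum(axis=1) > min_fraction * len(group)


# ---------------------------------------------------------------------------
# beta-binomial likelihood machinery (vectorized over events)
# ---------------------------------------------------------------------------

def _bb_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray,
               rho: np.ndarray) -> np.ndarray:
    """Sum over samples (axis 1) of the beta-binomial log likelihood.

    ``p`` has shape (events,), ``rho`` shape (events,); rho == 0 falls back
    to the binomial. Samples with n == 0 contribute zero.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(p, 1e-12, 1 - 1e-12)[:, None]
    rho = np.asarray(rho, dtype=float)[:, None]
    choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = np.empty_like(k)
    bb = np.broadcast_to(rho > 0, k.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        binom_ll = choose + k * np.log(p) + (n - k) * np.log1p(-p)
        a = p * (1 - rho) / np.maximum(rho, 1e-12)
        b = (1 - p) * (1 - rho) / np.maximum(rho, 1e-12)
        bb_ll = choose + betaln(k + a, n - k + b) - betaln(a, b)
    out = np.where(bb, bb_ll, binom_ll)
    out = np.where(n > 0, out, 0.0)
    return out.sum(axis=1)


def _golden_max(f, lo: float, hi: float, n_events: int, iters: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of ``f`` (unimodal) over a
    shared scalar interval, independently for each event."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a = np.full(n_events, lo)
    b = np.full(n_events, hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = f(c)
    fd = f(d)
    for _ in range(iters):
        left = fc > fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        # one of the two probes is inherited; recompute both for simplicity
        c, d = c_new, d_new
        fc = f(c)
        fd = f(d)
    x = (a + b) / 2
    return x, f(x)


def _fit_bb_p(k: np.ndarray, n: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood junction-read proportion per event (logit scale
    golden section), returning (p_hat, loglik)."""
    n_events = k.shape[0]

    def obj(logit_p: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-logit_p))
        return _bb_loglik(k, n, p, rho)

    x, ll = _golden_max(obj, -14.0, 14.0, n_events)
    return 1.0 / (1.0 + np.exp(-x)), ll


def _mom_rho(k: np.ndarray, n: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-event method-of-moments intraclass correlation, pooled over the
    groups' residuals around their own (weighted) means.

    Within a group with G informative samples of sizes n_i (N = Σ n_i),

        E[Σ n_i (p_i - p̂)²] = p(1-p)[(G - 1) + ρ (Σ(n_i - 1) - Σ n_i(n_i - 1)/N)],

    so pooling the scaled sums of squares over groups and subtracting the
    degrees of freedom yields an unbiased-to-first-order ρ estimate.
    """
    ss = np.zeros(k.shape[0])
    df = np.zeros(k.shape[0])
    coef = np.zeros(k.shape[0])
    for idx in groups:
        kg = k[:, idx]
        ng = n[:, idx]
        tot = ng.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pbar = np.where(tot > 0, kg.sum(axis=1) / np.maximum(tot, 1), 0.5)
            var = pbar * (1 - pbar)
            prop = np.where(ng > 0, kg / np.maximum(ng, 1), 0.0)
            sq = ng * (prop - pbar[:, None]) ** 2
        informative = (ng > 0) & (var[:, None] > 1e-12)
        g_inf = informative.sum(axis=1)
        n_inf = np.where(informative, ng, 0.0)
        n_tot = n_inf.sum(axis=1)
        ss += np.where(var > 1e-12,
                       np.where(informative, sq, 0.0).sum(axis=1) / np.maximum(var, 1e-12),
                       0.0)
        df += np.where(var > 1e-12, np.maximum(g_inf - 1, 0), 0.0)
        c = (np.where(informative, n_inf - 1.0, 0.0).sum(axis=1)
             - (n_inf * (n_inf - 1.0)).sum(axis=1) / np.maximum(n_tot, 1))
        coef += np.where(var > 1e-12, c, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ss - df) / np.maximum(coef, 1e-12)
    rho = np.where(coef > 0, rho, 0.0)
    return np.clip(rho, 0.0, 0.95)


def diff_splice(counts: JunctionCounts, events: pd.DataFrame,
                group_a: Sequence[str], group_b: Sequence[str],
                fdr: float = 0.05, min_delta: float = 0.1,
                min_reads: int = 20, min_fraction: float = 0.5,
                prefilter: bool = True) -> pd.DataFrame:
    """Differential splicing between two groups (e.g. males vs females).

    Returns one row per tested event: group means, delta_psi (group A minus
    group B), LRT statistic, p, BH-FDR, significance under the joint
    FDR/|ΔPSI| rule, and the inclusion-bias direction.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    testable = events.index[events["event_type"].isin(TESTABLE_TYPES)]
    if prefilter:
        kept = filter_events(counts.subset_events(testable), group_a, group_b,
                             min_reads=min_reads, min_fraction=min_fraction)
    else:
        kept = testable
    psi = compute_psi(counts.subset_events(kept), events.loc[kept])

    # require >= 2 informative samples per group
    inf_a = psi[list(group_a)].notna().sum(axis=1)
    inf_b = psi[list(group_b)].notna().sum(axis=1)
    kept = kept[(inf_a >= 2).to_numpy() & (inf_b >= 2).to_numpy()]
    if len(kept) == 0:
        return _empty_result()
    psi = psi.loc[kept]

    samples = list(group_a) + list(group_b)
    k = counts.ijc.loc[kept, samples].to_numpy(dtype=float)
    n = k + counts.sjc.loc[kept, samples].to_numpy(dtype=float)
    idx_a = np.arange(len(group_a))
    idx_b = np.arange(len(group_a), len(samples))

    # Symmetrized dispersion: residuals around group means underestimate the
    # intraclass correlation's effective noise (anticonservative LRT), while
    # residuals around the pooled mean absorb the tested contrast
    # (conservative). Their average calibrates the chi-square reference.
    rho_within = _mom_rho(k, n, [idx_a, idx_b])
    rho_pooled = _mom_rho(k, n, [np.concatenate([idx_a, idx_b])])
    rho = 0.5 * (rho_within + rho_pooled)
    _, ll_null = _fit_bb_p(k, n, rho)
    _, ll_a = _fit_bb_p(k[:, idx_a], n[:, idx_a], rho)
    _, ll_b = _fit_bb_p(k[:, idx_b], n[:, idx_b], rho)
    lrt = np.maximum(2.0 * (ll_a + ll_b - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    mean_a = psi[list(group_a)].mean(axis=1).to_numpy()
    mean_b = psi[list(group_b)].mean(axis=1).to_numpy()
    delta = mean_a - mean_b

    res = pd.DataFrame(
        {
            "event_id": kept,
            "gene_id": events.loc[kept, "gene_id"].to_numpy(),
            "mean_psi_g1": mean_a,
            "mean_psi_g2": mean_b,
            "delta_psi": delta,
            "lrt_stat": lrt,
            "p": p,
        }
    )
    ok = res["p"].notna()
    res["fdr"] = np.nan
    if ok.any():
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["significant"] = (res["fdr"] < fdr) & (res["delta_psi"].abs() >= min_delta)
    res["inclusion_bias"] = np.select(
        [res["significant"] & (res["delta_psi"] > 0),
         res["significant"] & (res["delta_psi"] < 0)],
        ["group1", "group2"], default="none",
    )
    return res


def _empty_result() -> pd.DataFrame:
    cols = ["event_id", "gene_id", "mean_psi_g1", "mean_psi_g2", "delta_psi",
            "lrt_stat", "p", "fdr", "significant", "inclusion_bias"]
    return pd.DataFrame(columns=cols)


def psi_log2fc_significance(records: pd.DataFrame, fdr: float = 0.05,
                            min_log2fc: float = 1.0,
                            pseudo: float = 0.01) -> pd.DataFrame:
    """Alternative significance rule for comparisons against differential
    expression: FDR < ``fdr`` and |log2(male PSI / female PSI)| >=
    ``min_log2fc``, mirroring the fold-change threshold used for
    expression so the two gene sets are defined at equivalent stringency.

    Returns a copy of ``records`` with ``psi_log2fc`` added and
    ``significant`` recomputed. A small pseudo-count keeps zero PSI finite.
    """
    out = records.copy()
    out["psi_log2fc"] = np.log2(
        (out["mean_psi_g1"] + pseudo) / (out["mean_psi_g2"] + pseudo)
    )
    out["significant"] = (out["fdr"] < fdr) & (out["psi_log2fc"].abs() >= min_log2fc)
    return out


def gene_level_summary(records: pd.DataFrame, psi: pd.DataFrame,
                       events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene roll-up: differential-splicing flag and mean PSI per sample.

    A gene is flagged differentially spliced when at least one of its events
    is significant; gene-level PSI is the unweighted mean over its events.
    """
    flags = records.groupby("gene_id")["significant"].any()
    gene_psi = psi.join(events["gene_id"]).groupby("gene_id").mean()
    summary = pd.DataFrame({"diff_spliced": flags}).reset_index()
    return summary, gene_psi


def classify_isoform_bias(records: pd.DataFrame) -> pd.DataFrame:
    """Label each significant event's isoforms by sex bias.

    With group1 = males, a positive delta_psi means the inclusion isoform is
    male-biased (and the exclusion isoform female-biased); negative means
    the reverse.
    """
    sig = records[records["significant"]].copy()
    sig["inclusion_label"] = np.where(sig["delta_psi"] > 0, "male_biased", "female_biased")
    sig["exclusion_label"] = np.where(sig["delta_psi"] > 0, "female_biased", "male_biased")
    return sig[["event_id", "gene_id", "delta_psi", "inclusion_label", "exclusion_label"]]
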