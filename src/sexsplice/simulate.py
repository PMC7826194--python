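"""Synthetic data generators with known ground truth.

The generators emulate the structure of a three-species avian RNA-seq
study: roughly five individuals per sex per species, a minority of splice
events with sex-biased PSI, a "turkey-like" species whose subordinate
males are planted exactly intermediate between dominant males and females,
and gene classes differing in expression bias, population differentiation
and rates of coding-sequence evolution.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import JunctionCounts
from .splicing import EFFECTIVE_LENGTHS

log = logging.getLogger("sexsplice")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Beta-binomial draws; exact binomial when rho == 0."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if rho <= 0:
        return rng.binomial(n, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return rng.binomial(n, rng.beta(a, b))


def adjusted_junction_proportion(psi: np.ndarray, l_inc: float, l_exc: float) -> np.ndarray:
    """Probability that a junction-spanning read supports inclusion, given
    the transcript-level PSI — the inverse of the effective-length PSI
    transform (for SE, 2ψ/(1+ψ))."""
    return psi * l_inc / (psi * l_inc + (1 - psi) * l_exc)


def simulate_splicing(n_events: int = 1000,
                      n_per_group: tuple[int, int, int] = (5, 5, 2),
                      coverage_mean: float = 100.0,
                      frac_biased: float = 0.1,
                      delta: float = 0.3,
                      lambda_mix: float = 0.5,
                      rho: float = 0.05,
                      frac_mxe: float = 0.2,
                      events_per_gene: int = 2,
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, JunctionCounts, pd.DataFrame, pd.DataFrame]:
    """Splice-junction counts for one turkey-like gonad panel.

    ``n_per_group`` is (dominant males, females, subordinate males).
    Baseline male PSI is Beta(2, 2); for sex-biased events the female PSI is
    the male PSI plus a random-sign offset of magnitude ``delta``, clipped
    to [0.05, 0.95]; subordinate-male PSI is exactly
    ``lambda_mix * psi_male + (1 - lambda_mix) * psi_female``.

    Per sample, total junction reads are Poisson(``coverage_mean``) and the
    inclusion count is beta-binomial with intraclass correlation ``rho`` on
    the effective-length-adjusted proportion.

    Returns (events, counts, metadata, truth).
    """
    rng = _rng(seed)
    n_dom, n_fem, n_sub = n_per_group
    n_biased = int(round(frac_biased * n_events))
    if frac_biased > 0 and n_biased < 1:
        log.warning("simulate_splicing: frac_biased*n_events < 1; no biased events")

    event_ids = [f"ev{i:05d}" for i in range(n_events)]
    n_genes = max(1, int(np.ceil(n_events / events_per_gene)))
    gene_ids = [f"g{i:05d}" for i in rng.integers(0, n_genes, n_events)]
    types = np.where(rng.random(n_events) < frac_mxe, "MXE", "SE")

    psi_m = rng.beta(2.0, 2.0, n_events)
    biased = np.zeros(n_events, dtype=bool)
    biased[:n_biased] = True
    sign = rng.choice([-1.0, 1.0], n_events)
    psi_f = np.where(biased, np.clip(psi_m + sign * delta, 0.05, 0.95), psi_m)
    psi_s = lambda_mix * psi_m + (1 - lambda_mix) * psi_f

    meta_rows = []
    sample_psi: dict[str, np.ndarray] = {}
    for prefix, sex, morph, psi_vec, count in (
        ("dom", "male", "dominant", psi_m, n_dom),
        ("fem", "female", "none", psi_f, n_fem),
        ("sub", "male", "subordinate", psi_s, n_sub),
    ):
        for i in range(count):
            sid = f"{prefix}{i + 1}"
            meta_rows.append((sid, "turkeylike", "gonad", sex, morph))
            sample_psi[sid] = psi_vec
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "species", "tissue", "sex", "morph"])

    l_inc = np.array([EFFECTIVE_LENGTHS[t][0] for t in types], dtype=float)
    l_exc = np.array([EFFECTIVE_LENGTHS[t][1] for t in types], dtype=float)

    ijc = {}
    sjc = {}
    for sid, psi_vec in sample_psi.items():
        total = rng.poisson(coverage_mean, n_events)
        q = adjusted_junction_proportion(psi_vec, l_inc, l_exc)
        inc = _beta_binomial(rng, total, q, rho)
        ijc[sid] = inc
        sjc[sid] = total - inc

    start = rng.integers(1000, 1_000_000, n_events)
    coords = [f"{s}-{s + 150},{s + 300}-{s + 450}" for s in start]
    events = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "event_type": types,
            "chrom": "chr1",
            "strand": "+",
            "coords": coords,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    counts = JunctionCounts(
        pd.DataFrame(ijc, index=events.index), pd.DataFrame(sjc, index=events.index)
    )
    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "gene_id": gene_ids,
            "true_psi_male": psi_m,
            "true_psi_female": psi_f,
            "true_psi_subordinate": psi_s,
            "sex_biased": biased,
            "delta": psi_m - psi_f,
            "lambda_mix": lambda_mix,
            "rho": rho,
        }
    )
    return events, counts, meta, truth


def simulate_expression(n_genes: int = 1000, n_per_sex: int = 5,
                        frac_biased: float = 0.1, log2fc: float = 2.0,
                        dispersion: float = 0.1, n_tissues: int = 1,
                        base_mean: float = 200.0, libsize_sigma: float = 0.3,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-level negative-binomial counts for a two-sex design.

    Sex-biased genes (half male-, half female-biased) have their means split
    symmetrically by ``log2fc``; unbiased genes have exactly equal means.
    Library sizes are log-normal to exercise normalization. When
    ``n_tissues > 1`` each gene also carries a Dirichlet tissue profile and
    samples are replicated per tissue.

    Returns (counts, metadata, truth); counts is genes × samples.
    """
    rng = _rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    base = base_mean * np.exp(rng.normal(0.0, 1.0, n_genes))

    n_biased = int(round(frac_biased * n_genes))
    bias = np.array(["unbiased"] * n_genes, dtype=object)
    bias[: n_biased // 2] = "male"
    bias[n_biased // 2: n_biased] = "female"
    shift = np.where(bias == "male", log2fc / 2, np.where(bias == "female", -log2fc / 2, 0.0))
    mean_m = base * 2.0 ** shift
    mean_f = base * 2.0 ** (-shift)

    if n_tissues > 1:
        profile = rng.dirichlet(np.full(n_tissues, 0.8), n_genes) * n_tissues
    else:
        profile = np.ones((n_genes, 1))

    cols = {}
    meta_rows = []
    for t in range(n_tissues):
        tissue = "gonad" if t == 0 else "spleen" if t == 1 else f"tissue{t}"
        for sex, mean_vec in (("male", mean_m), ("female", mean_f)):
            for i in range(n_per_sex):
                sid = f"{sex[0]}{i + 1}" + (f"_t{t}" if n_tissues > 1 else "")
                meta_rows.append((sid, "simspecies", tissue, sex, "none"))
                lib = np.exp(rng.normal(0.0, libsize_sigma))
                mu = mean_vec * profile[:, t] * lib
                if dispersion > 0:
                    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
                else:
                    lam = mu
                cols[sid] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "species", "tissue", "sex", "morph"])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_male": mean_m,
            "mean_female": mean_f,
            "dispersion": dispersion,
            "bias": bias,
        }
    )
    for t in range(n_tissues):
        truth[f"tissue_profile_{t}"] = profile[:, t]
    return counts, meta, truth


def simulate_allele_counts(n_genes: int = 200, n_sites: int = 20,
                           n_males: int = 5, n_females: int = 5,
                           frac_differentiated: float = 0.1, d: float = 0.0,
                           theta: float = 1.0, pop_size: int = 100,
                           sfs_skew: float = 0.0,
                           frac_offset_sites: float = 1.0,
                           classify_exons: bool = False,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene site allele counts for intersexual FST and Tajima's D.

    Population allele frequencies follow the neutral site-frequency
    spectrum (weight ∝ 1/i over i/2N); sex-differentiated genes get a ±d/2
    offset between male and female frequencies on a ``frac_offset_sites``
    fraction of their sites, with those sites' frequencies restricted to
    the interior of the spectrum so the offset stays valid. Their
    remaining sites follow a spectrum skewed toward rare variants
    (weight ∝ 1/i^(1+``sfs_skew``)), which controls the sign of the
    differentiated genes' Tajima's D; 0 leaves it neutral. Per-sex
    alternate-allele counts are binomial over 2·n diploid chromosomes.
    With ``classify_exons`` half of each gene's sites are labeled
    sex_biased, and for differentiated genes exactly those carry the
    offset.

    Returns (allele count table, truth).
    """
    rng = _rng(seed)
    two_n = 2 * pop_size
    grid = np.arange(1, two_n) / two_n
    weights = 1.0 / np.arange(1, two_n)
    if d > 0:
        interior = (grid > d / 2) & (grid < 1 - d / 2)
    else:
        interior = np.ones_like(grid, dtype=bool)
    w_all = weights / weights.sum()
    w_int = np.where(interior, weights, 0.0)
    w_int = w_int / w_int.sum()
    w_skew = 1.0 / np.arange(1, two_n) ** (1.0 + sfs_skew)
    w_skew = w_skew / w_skew.sum()

    n_diff = int(round(frac_differentiated * n_genes))
    rows = []
    truth_rows = []
    for g in range(n_genes):
        gid = f"g{g:05d}"
        differentiated = g < n_diff
        n_poly = rng.binomial(n_sites, min(1.0, theta))
        n_off = int(round(n_poly * frac_offset_sites))
        for s in range(n_poly):
            if classify_exons:
                exon_class = "sex_biased" if s % 2 == 0 else "unbiased"
                offset_site = differentiated and exon_class == "sex_biased"
            else:
                exon_class = "NA"
                offset_site = differentiated and s < n_off
            if offset_site:
                p = rng.choice(grid, p=w_int)
            elif differentiated:
                p = rng.choice(grid, p=w_skew)
            else:
                p = rng.choice(grid, p=w_all)
            offset = d / 2 if offset_site else 0.0
            p_m = np.clip(p + offset, 0.0, 1.0)
            p_f = np.clip(p - offset, 0.0, 1.0)
            m_alt = rng.binomial(2 * n_males, p_m)
            f_alt = rng.binomial(2 * n_females, p_f)
            rows.append((gid, s, 2 * n_males - m_alt, m_alt,
                         2 * n_females - f_alt, f_alt, exon_class))
        truth_rows.append((gid, differentiated, d if differentiated else 0.0,
                           sfs_skew if differentiated else 0.0, n_poly))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "site", "male_ref", "male_alt",
                 "female_ref", "female_alt", "exon_class"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "sex_differentiated", "d", "sfs_skew", "n_sites"],
    )
    return table, truth


def simulate_dnds_table(n_genes_per_class: int = 100,
                        omega_by_class: dict[str, float] | None = None,
                        ds_mean: float = 0.1, frac_saturated: float = 0.02,
                        length_mean: float = 1500.0,
                        seed: int = 0) -> pd.DataFrame:
    """Per-gene dN/dS components for class contrasts.

    Nonsynonymous and synonymous site counts follow the simulated CDS
    length at the canonical ~3:1 ratio; substitution counts are Poisson
    with per-gene synonymous rate Gamma-distributed around ``ds_mean`` and
    dN = omega · dS. A small fraction of genes is given dS > 2 to exercise
    the saturation filter.
    """
    rng = _rng(seed)
    if omega_by_class is None:
        omega_by_class = {"spliced": 0.1, "expressed": 0.2, "unbiased": 0.15}
    rows = []
    idx = 0
    for cls, omega in omega_by_class.items():
        for _ in range(n_genes_per_class):
            gid = f"g{idx:05d}"
            idx += 1
            length = length_mean * np.exp(rng.normal(0.0, 0.5))
            n_sites = 0.75 * length
            s_sites = 0.25 * length
            if rng.random() < frac_saturated:
                ds_true = 2.5
            else:
                ds_true = rng.gamma(2.0, ds_mean / 2.0)
            dn_true = omega * ds_true
            sds = rng.poisson(s_sites * ds_true)
            ndn = rng.poisson(n_sites * dn_true)
            rows.append((gid, n_sites, s_sites, ndn, sds, sds / s_sites, cls, length))
    return pd.DataFrame(
        rows, columns=["gene_id", "N", "S", "NdN", "SdS", "dS", "class", "cds_length"]
    )


def simulate_gene_table(gene_ids: list[str], frac_sex_chrom: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Gene annotation with autosome flags and exon counts."""
    rng = _rng(seed)
    n = len(gene_ids)
    autosomal = rng.random(n) >= frac_sex_chrom
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": np.where(autosomal, "chr1", "chrZ"),
            "autosomal": autosomal,
            "n_exons": rng.integers(2, 20, n),
            "cds_length": rng.integers(300, 6000, n),
        }
    )
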