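"""Population-genomic and molecular-evolution contrasts.

Per-gene intersexual differentiation uses Hudson's FST with the
small-sample-corrected site numerator

    (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)

and denominator p1(1-p2) + p2(1-p1); the gene-level estimate is the ratio
of summed numerators to summed denominators (never a mean of per-site
ratios). Tajima's D follows the standard constants from the number of
chromosomes sampled. Class-level dN/dS is length-weighted —
(ΣNdN/ΣN)/(ΣSdS/ΣS) — with percentile bootstrap confidence intervals and
label-permutation tests between classes, after dropping genes with dS
above the mutational-saturation cutoff.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("sexsplice")


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_fst_components(p1: np.ndarray, n1: np.ndarray,
                          p2: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator arrays."""
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_per_gene(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene intersexual Hudson FST (ratio of sums over sites).

    ``table`` carries gene_id, site, male_ref, male_alt, female_ref,
    female_alt. Sites with fewer than 2 alleles in either sex or zero
    denominator are skipped; genes with no usable site get a missing FST.
    """
    n1 = (table["male_ref"] + table["male_alt"]).to_numpy(dtype=float)
    n2 = (table["female_ref"] + table["female_alt"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = table["male_alt"].to_numpy() / n1
        p2 = table["female_alt"].to_numpy() / n2
        num, den = hudson_fst_components(p1, np.maximum(n1, 2), p2, np.maximum(n2, 2))
    usable = (n1 >= 2) & (n2 >= 2) & (den > 0)
    df = pd.DataFrame(
        {"gene_id": table["gene_id"], "num": np.where(usable, num, 0.0),
         "den": np.where(usable, den, 0.0), "used": usable}
    )
    agg = df.groupby("gene_id").agg(num=("num", "sum"), den=("den", "sum"),
                                    n_sites_used=("used", "sum"))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(agg["den"] > 0, agg["num"] / agg["den"], np.nan)
    return pd.DataFrame(
        {"gene_id": agg.index, "fst": fst, "n_sites_used": agg["n_sites_used"].to_numpy()}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The standard normalization constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("need at least 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(alt_counts: Sequence[int], n_chromosomes: int) -> dict:
    """Tajima's D for one gene from per-site alternate-allele counts.

    Only segregating sites (0 < count < n) contribute; S = 0 yields a
    missing D. π is the total pairwise diversity summed over sites.
    """
    n = n_chromosomes
    c = tajima_constants(n)
    j = np.asarray(alt_counts, dtype=float)
    seg = (j > 0) & (j < n)
    S = int(seg.sum())
    if S == 0:
        return {"n_chromosomes": n, "S": 0, "pi": 0.0, "D": np.nan}
    jj = j[seg]
    pi = float(np.sum(jj * (n - jj)) / (n * (n - 1) / 2.0))
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    D = (pi - S / c["a1"]) / np.sqrt(var) if var > 0 else np.nan
    return {"n_chromosomes": n, "S": S, "pi": pi, "D": float(D)}


def tajimas_d(table: pd.DataFrame, n_chromosomes: int | None = None,
              sexes_pooled: bool = True) -> pd.DataFrame:
    """Per-gene Tajima's D from an allele-count table, pooling sexes."""
    rows = []
    for gid, grp in table.groupby("gene_id"):
        alt = (grp["male_alt"] + grp["female_alt"]).to_numpy()
        tot = (grp["male_alt"] + grp["male_ref"]
               + grp["female_alt"] + grp["female_ref"]).to_numpy()
        n = int(n_chromosomes or tot.max())
        res = tajimas_d_from_counts(alt, n)
        rows.append((gid, res["n_chromosomes"], res["S"], res["pi"], res["D"]))
    return pd.DataFrame(rows, columns=["gene_id", "n_chromosomes", "S", "pi", "D"])


# ---------------------------------------------------------------------------
# architecture enrichment and exon-class FST
# ---------------------------------------------------------------------------

def architecture_enrichment(ds_flags: pd.DataFrame, fst: pd.DataFrame,
                            tajima: pd.DataFrame,
                            de_genes: Iterable = (),
                            immune_genes: Iterable = (),
                            fst_quantile: float = 0.75,
                            d_quantile: float = 0.50) -> dict:
    """Chi-square test of differential splicing against the
    sex-differential-architecture candidate class.

    Candidates are genes with FST above the ``fst_quantile`` quantile AND
    Tajima's D below the ``d_quantile`` quantile, computed after removing
    differentially expressed genes and immune/MHC-annotated genes.
    ``ds_flags`` carries gene_id and a boolean ``diff_spliced``.
    """
    df = ds_flags.merge(fst[["gene_id", "fst"]], on="gene_id")
    df = df.merge(tajima[["gene_id", "D"]], on="gene_id")
    df = df[~df["gene_id"].isin(set(de_genes))]
    df = df[~df["gene_id"].isin(set(immune_genes))]
    df = df.dropna(subset=["fst", "D"])
    if len(df) == 0:
        return {"n_genes": 0, "chi2": np.nan, "p": np.nan,
                "table": np.zeros((2, 2), dtype=int)}
    fst_cut = df["fst"].quantile(fst_quantile)
    d_cut = df["D"].quantile(d_quantile)
    df["candidate"] = (df["fst"] > fst_cut) & (df["D"] < d_cut)
    tab = pd.crosstab(df["diff_spliced"], df["candidate"]) \
        .reindex(index=[False, True], columns=[False, True], fill_value=0)
    out = {"n_genes": len(df), "fst_cut": float(fst_cut), "d_cut": float(d_cut),
           "table": tab.to_numpy()}
    if (tab.to_numpy().sum(axis=0) == 0).any() or (tab.to_numpy().sum(axis=1) == 0).any():
        log.warning("architecture_enrichment: zero margin; p not computable")
        out.update({"chi2": np.nan, "p": np.nan})
        return out
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
    out.update({"chi2": float(chi2), "p": float(p)})
    return out


def immune_gene_filter(annotations: pd.DataFrame,
                       keywords: Sequence[str] = ("immune", "MHC"),
                       text_col: str = "annotation") -> set[str]:
    """Gene ids whose annotation text mentions any of the keywords
    (case-insensitive)."""
    pattern = "|".join(keywords)
    hit = annotations[text_col].fillna("").str.contains(pattern, case=False)
    return set(annotations.loc[hit, "gene_id"])


def exon_class_fst(table: pd.DataFrame, min_pairs: int = 5) -> dict:
    """Paired comparison of per-gene FST between sex-biased and unbiased
    exon classes (genes contributing both classes only)."""
    if "exon_class" not in table.columns:
        raise ValueError("allele table lacks exon_class")
    parts = {}
    for cls in ("sex_biased", "unbiased"):
        sub = table[table["exon_class"] == cls]
        parts[cls] = hudson_fst_per_gene(sub).set_index("gene_id")["fst"]
    paired = pd.DataFrame({"fst_sex_biased": parts["sex_biased"],
                           "fst_unbiased": parts["unbiased"]}).dropna()
    med_diff = float((paired["fst_sex_biased"] - paired["fst_unbiased"]).median())
    out = {
        "n_pairs": len(paired),
        "median_sex_biased": float(paired["fst_sex_biased"].median()) if len(paired) else np.nan,
        "median_unbiased": float(paired["fst_unbiased"].median()) if len(paired) else np.nan,
        "median_diff": med_diff if len(paired) else np.nan,
    }
    diff = paired["fst_sex_biased"] - paired["fst_unbiased"]
    if len(paired) < min_pairs or np.allclose(diff, 0):
        out.update({"statistic": np.nan if len(paired) < min_pairs else 0.0,
                    "p": np.nan if len(paired) < min_pairs else 1.0})
    else:
        s, p = stats.wilcoxon(paired["fst_sex_biased"], paired["fst_unbiased"])
        out.update({"statistic": float(s), "p": float(p)})
    return out


# ---------------------------------------------------------------------------
# weighted dN/dS
# ---------------------------------------------------------------------------

def weighted_dnds_estimate(records: pd.DataFrame) -> float:
    """Length-weighted class dN/dS = (ΣNdN/ΣN)/(ΣSdS/ΣS)."""
    dn = records["NdN"].sum() / records["N"].sum()
    ds = records["SdS"].sum() / records["S"].sum()
    if ds == 0:
        return np.nan
    return float(dn / ds)


def weighted_dnds(records: pd.DataFrame, ds_max: float = 2.0,
                  n_boot: int = 1000, n_perm: int = 1000,
                  seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
    """Per-class weighted dN/dS with bootstrap CIs and pairwise
    permutation p-values.

    Genes with dS > ``ds_max`` are excluded before aggregation. The CI is
    a percentile bootstrap over genes; the pairwise test permutes class
    labels between the two classes and compares |Δ dN/dS|.
    """
    rng = np.random.default_rng(seed)
    recs = records[records["dS"] <= ds_max]
    classes = sorted(recs["class"].unique())
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for cls in classes:
        sub = recs[recs["class"] == cls]
        if len(sub) < 2:
            raise ValueError(f"class {cls!r} has < 2 genes after dS filter")
        est = weighted_dnds_estimate(sub)
        boots = np.empty(n_boot)
        arr = sub[["NdN", "N", "SdS", "S"]].to_numpy(dtype=float)
        for b in range(n_boot):
            pick = rng.integers(0, len(arr), len(arr))
            a = arr[pick]
            ds = a[:, 2].sum() / a[:, 3].sum()
            boots[b] = (a[:, 0].sum() / a[:, 1].sum()) / ds if ds > 0 else np.nan
        rows.append((cls, len(sub), est,
                     float(np.nanquantile(boots, lo_q)),
                     float(np.nanquantile(boots, hi_q))))
    result = pd.DataFrame(rows, columns=["class", "n_genes", "dnds", "ci_lo", "ci_hi"])

    perm_rows = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            sub = recs[recs["class"].isin([c1, c2])].reset_index(drop=True)
            labels = (sub["class"] == c1).to_numpy()
            arr = sub[["NdN", "N", "SdS", "S"]].to_numpy(dtype=float)

            def contrast(lab: np.ndarray) -> float:
                a, b = arr[lab], arr[~lab]
                da = (a[:, 0].sum() / a[:, 1].sum()) / (a[:, 2].sum() / a[:, 3].sum())
                db = (b[:, 0].sum() / b[:, 1].sum()) / (b[:, 2].sum() / b[:, 3].sum())
                return da - db

            obs = contrast(labels)
            hits = 0
            for _ in range(n_perm):
                hits += abs(contrast(rng.permutation(labels))) >= abs(obs)
            perm_rows.append((c1, c2, obs, (hits + 1) / (n_perm + 1)))
    perms = pd.DataFrame(perm_rows, columns=["class1", "class2", "diff", "p_perm"])
    result.attrs["pairwise"] = perms
    return result


def dnds_covariate_control(records: pd.DataFrame, ds_max: float = 2.0) -> dict:
    """Linear model of per-gene dN/dS on class plus log length and log
    expression; F-test for the class term.

    ``records`` must carry cds_length and expression columns. Zero-variance
    covariates are dropped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    recs = records[(records["dS"] <= ds_max) & (records["SdS"] > 0)].copy()
    recs["dnds"] = (recs["NdN"] / recs["N"]) / (recs["SdS"] / recs["S"])
    recs["log_length"] = np.log(recs["cds_length"])
    recs["log_expr"] = np.log1p(recs["expression"]) if "expression" in recs else 0.0

    covars = []
    for cov in ("log_length", "log_expr"):
        if cov in recs and np.ptp(recs[cov].to_numpy()) > 1e-12:
            covars.append(cov)
        else:
            log.warning("dnds_covariate_control: dropping zero-variance covariate %s", cov)
    formula = "dnds ~ C(Q('class'))" + "".join(f" + {c}" for c in covars)
    model = smf.ols(formula, data=recs).fit()
    if covars:
        X = recs[covars].to_numpy()
        cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
        if cond > 1e8:
            log.warning("dnds_covariate_control: covariates nearly collinear "
                        "(condition number %.2g)", cond)
    aov = anova_lm(model, typ=2)
    class_row = [i for i in aov.index if "class" in i][0]
    return {
        "coefficients": model.params.to_dict(),
        "class_F": float(aov.loc[class_row, "F"]),
        "class_p": float(aov.loc[class_row, "PR(>F)"]),
        "covariates": covars,
        "n_genes": len(recs),
    }
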