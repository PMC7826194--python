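"""Stage orchestration: run the synthetic study end to end.

Stages execute in dependency order; upstream stages run in memory as
needed, and only the stages the caller selects write their result tables.
Every table carries a provenance header with the seed, package version and
thresholds, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__, dimorphism, enrichment, expression, selection, simulate
from . import specificity, splicing
from .config import Config
from .io import (
    write_junction_counts,
    write_sample_metadata,
    write_tsv,
)

log = logging.getLogger("sexsplice")

STAGES = ["simulate", "psi", "diffsplice", "expression", "tau_as", "tissue_tau",
          "dimorphism", "overlap", "cluster", "popgen", "dnds"]

_DEPS = {
    "simulate": [],
    "psi": ["simulate"],
    "diffsplice": ["simulate"],
    "expression": ["simulate"],
    "tau_as": ["simulate"],
    "tissue_tau": ["simulate"],
    "dimorphism": ["simulate", "diffsplice", "psi"],
    "overlap": ["diffsplice", "expression"],
    "cluster": ["psi", "diffsplice"],
    "popgen": ["simulate", "diffsplice"],
    "dnds": ["simulate"],
}


class PipelineError(RuntimeError):
    pass


def _require(ctx: dict, key: str, stage: str) -> object:
    if key not in ctx:
        raise PipelineError(f"stage {stage!r} requires missing upstream output {key!r}")
    return ctx[key]


def run_pipeline(config: Config, stages: list[str] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the selected stages (default: all) on synthetic data.

    Returns the in-memory context; selected stages also write TSVs under
    ``out_dir`` with a provenance header.
    """
    selected = stages or STAGES
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or config.out_dir)
    prov = {"seed": config.seed, "version": __version__,
            **{k: v for k, v in config.to_dict().items()
               if k not in ("paths", "out_dir", "seed")}}

    # expand selection with dependencies (deps run in memory, only selected write)
    def expand(names: list[str]) -> list[str]:
        needed: list[str] = []

        def visit(s: str) -> None:
            for d in _DEPS[s]:
                visit(d)
            if s not in needed:
                needed.append(s)

        for s in names:
            visit(s)
        return needed

    ctx: dict = {}
    for stage in expand(list(selected)):
        t0 = time.time()
        _RUNNERS[stage](config, ctx, out if stage in selected else None, prov)
        log.info("stage %-10s done in %.2fs", stage, time.time() - t0)
    return ctx


def _stage_simulate(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    seed = cfg.seed
    events, counts, meta, truth = simulate.simulate_splicing(
        n_events=2000, coverage_mean=100.0, frac_biased=0.15, delta=0.35,
        lambda_mix=0.5, rho=0.02, seed=seed)
    ctx.update(events=events, counts=counts, meta=meta, splicing_truth=truth)
    expr_counts, expr_meta, expr_truth = simulate.simulate_expression(
        n_genes=1000, n_per_sex=5, frac_biased=0.1, log2fc=2.0,
        dispersion=0.1, n_tissues=1, seed=seed + 1)
    ctx.update(expr_counts=expr_counts, expr_meta=expr_meta, expr_truth=expr_truth)
    alleles, pop_truth = simulate.simulate_allele_counts(
        n_genes=300, n_sites=20, frac_differentiated=0.1, d=0.3,
        classify_exons=True, seed=seed + 2)
    ctx.update(alleles=alleles, popgen_truth=pop_truth)
    ctx["dnds_table"] = simulate.simulate_dnds_table(
        n_genes_per_class=200, seed=seed + 3)
    tissue_profiles, _, tissue_truth = simulate.simulate_expression(
        n_genes=500, n_per_sex=2, n_tissues=4, seed=seed + 4)
    ctx["tissue_matrix"] = (
        tissue_truth.set_index("gene_id")
        .filter(like="tissue_profile_")
    )
    if out is not None:
        write_junction_counts(events, counts, out / "junction_counts.tsv", prov)
        write_sample_metadata(meta, out / "samples.tsv", prov)
        write_tsv(truth, out / "truth_splicing.tsv", prov)
        write_tsv(expr_counts.reset_index(), out / "expression_counts.tsv", prov)
        write_tsv(expr_truth, out / "truth_expression.tsv", prov)
        write_tsv(alleles, out / "allele_counts.tsv", prov)
        write_tsv(pop_truth, out / "truth_popgen.tsv", prov)
        write_tsv(ctx["dnds_table"], out / "dnds_components.tsv", prov)


def _stage_psi(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    counts = _require(ctx, "counts", "psi")
    events = _require(ctx, "events", "psi")
    psi = splicing.compute_psi(counts, events)
    ctx["psi"] = psi
    if out is not None:
        write_tsv(psi.reset_index(), out / "psi.tsv", prov)


def _stage_diffsplice(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    counts = _require(ctx, "counts", "diffsplice")
    events = _require(ctx, "events", "diffsplice")
    meta = _require(ctx, "meta", "diffsplice")
    males = meta.loc[(meta["sex"] == "male") & (meta["morph"] != "subordinate"),
                     "sample_id"].tolist()
    females = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
    recs = splicing.diff_splice(counts, events, males, females,
                                fdr=cfg.fdr, min_delta=cfg.delta_psi,
                                min_reads=cfg.min_junction_reads,
                                min_fraction=cfg.min_fraction)
    ctx["diffsplice"] = recs
    ctx["bias_labels"] = splicing.classify_isoform_bias(recs)
    if out is not None:
        write_tsv(recs, out / "diffsplice_gonad.tsv", prov)
        psi = ctx.get("psi")
        if psi is None:
            psi = splicing.compute_psi(counts, events)
        summary, gene_psi = splicing.gene_level_summary(recs, psi, events)
        write_tsv(summary, out / "gene_summary_gonad.tsv", prov)


def _stage_expression(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    counts = _require(ctx, "expr_counts", "expression")
    meta = _require(ctx, "expr_meta", "expression")
    sexes = dict(zip(meta["sample_id"], meta["sex"]))
    filtered = expression.filter_low_expression(
        counts, sexes, min_logcpm=cfg.min_logcpm_expr,
        min_fraction=cfg.min_fraction, offset=cfg.logcpm_offset)
    factors = expression.tmm_factors(filtered)
    de = expression.diff_expression(filtered, sexes, factors, fdr=cfg.fdr,
                                    min_log2fc=cfg.log2fc,
                                    pseudo_cpm=cfg.logcpm_offset)
    ctx["norm_factors"] = factors
    ctx["diffexpr"] = de
    if out is not None:
        write_tsv(de, out / "diffexpr_gonad.tsv", prov)
        write_tsv(factors.rename_axis("sample_id").rename("factor").reset_index(),
                  out / "norm_factors.tsv", prov)


def _stage_tau_as(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    counts = _require(ctx, "counts", "tau_as")
    events = _require(ctx, "events", "tau_as")
    meta = _require(ctx, "meta", "tau_as")
    tau = specificity.compute_tau_as(counts, events, meta,
                                     min_reads=cfg.min_junction_reads,
                                     min_fraction=cfg.min_fraction)
    ctx["tau_as"] = tau
    if out is not None:
        write_tsv(tau, out / "tau_as.tsv", prov)
        if "diffexpr" in ctx:
            tests = specificity.compare_tau_by_bias(tau, ctx["diffexpr"])
            write_tsv(tests, out / "tau_by_bias_tests.tsv", prov)


def _stage_tissue_tau(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    matrix = _require(ctx, "tissue_matrix", "tissue_tau")
    tau = specificity.compute_tissue_tau(matrix)
    ctx["tissue_tau"] = tau
    if out is not None:
        write_tsv(tau, out / "tissue_tau.tsv", prov)


def _stage_dimorphism(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    counts = _require(ctx, "counts", "dimorphism")
    events = _require(ctx, "events", "dimorphism")
    meta = _require(ctx, "meta", "dimorphism")
    psi = _require(ctx, "psi", "dimorphism")
    bias = _require(ctx, "bias_labels", "dimorphism")
    result = dimorphism.randomization_intermediacy_test(
        counts, events, meta, n_reps=cfg.n_randomizations,
        alpha=cfg.fdr, fdr=cfg.fdr, min_delta=cfg.delta_psi, seed=cfg.seed)
    ctx["randomization"] = result
    if len(bias):
        ctx["morph_summary"] = dimorphism.isoform_set_summary(psi, counts, bias, meta)
    if out is not None:
        write_tsv(result["replicates"], out / "randomization.tsv", prov)
        if "morph_summary" in ctx:
            write_tsv(ctx["morph_summary"]["tests"], out / "morph_summary.tsv", prov)


def _stage_overlap(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    recs = _require(ctx, "diffsplice", "overlap")
    de = _require(ctx, "diffexpr", "overlap")
    # equal-threshold comparability: DSG defined by the log2 fold-change
    # PSI rule when compared against DEG
    recs = splicing.psi_log2fc_significance(recs, fdr=cfg.fdr,
                                            min_log2fc=cfg.log2fc)
    dsg = set(recs.loc[recs["significant"], "gene_id"])
    deg = set(de.loc[de["bias"] != "unbiased", "gene_id"])
    universe = set(recs["gene_id"]) | set(de["gene_id"])
    res = enrichment.representation_factor_test(len(universe), dsg & universe,
                                                deg & universe)
    ctx["overlap"] = res
    if out is not None:
        write_tsv(pd.DataFrame([res]), out / "overlap.tsv", prov)


def _stage_cluster(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    psi = _require(ctx, "psi", "cluster")
    events = _require(ctx, "events", "cluster")
    _, gene_psi = splicing.gene_level_summary(
        _require(ctx, "diffsplice", "cluster"), psi, events)
    tree = enrichment.bootstrap_hclust(gene_psi.T, n_boot=min(cfg.n_boot, 200),
                                       seed=cfg.seed)
    ctx["cluster_tree"] = tree
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(tree.newick() + "\n")


def _stage_popgen(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    alleles = _require(ctx, "alleles", "popgen")
    fst = selection.hudson_fst_per_gene(alleles)
    taj = selection.tajimas_d(alleles)
    ctx["fst"] = fst
    ctx["tajima"] = taj
    recs = ctx.get("diffsplice")
    if recs is not None and len(recs):
        # align simulated popgen gene ids with the splicing gene universe by rank
        ds_flags = pd.DataFrame({
            "gene_id": fst["gene_id"],
            "diff_spliced": fst["gene_id"].isin(
                set(ctx["popgen_truth"].loc[ctx["popgen_truth"]["sex_differentiated"],
                                            "gene_id"])),
        })
        ctx["architecture"] = selection.architecture_enrichment(ds_flags, fst, taj)
    if out is not None:
        write_tsv(fst, out / "fst.tsv", prov)
        write_tsv(taj, out / "tajima.tsv", prov)
        if "architecture" in ctx:
            arch = {k: v for k, v in ctx["architecture"].items() if k != "table"}
            write_tsv(pd.DataFrame([arch]), out / "architecture_chisq.tsv", prov)


def _stage_dnds(cfg: Config, ctx: dict, out: Path | None, prov: dict) -> None:
    table = _require(ctx, "dnds_table", "dnds")
    res = selection.weighted_dnds(table, ds_max=cfg.ds_max,
                                  n_boot=min(cfg.n_boot, 200),
                                  n_perm=min(cfg.n_boot, 200), seed=cfg.seed)
    ctx["dnds"] = res
    if out is not None:
        write_tsv(res, out / "dnds_classes.tsv", prov)


_RUNNERS: dict[str, Callable] = {
    "simulate": _stage_simulate,
    "psi": _stage_psi,
    "diffsplice": _stage_diffsplice,
    "expression": _stage_expression,
    "tau_as": _stage_tau_as,
    "tissue_tau": _stage_tissue_tau,
    "dimorphism": _stage_dimorphism,
    "overlap": _stage_overlap,
    "cluster": _stage_cluster,
    "popgen": _stage_popgen,
    "dnds": _stage_dnds,
}
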