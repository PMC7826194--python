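"""Morph-gradient splicing analysis.

Wild-turkey males occur as dominant and subordinate morphs spanning a
gradient of sexual dimorphism. This module asks whether subordinate males
sit transcriptionally between dominant males and females: it summarizes
sex-biased isoform expression and PSI per morph, and runs a randomization
control against regression to the mean — repeatedly discovering
sex-differential events on a subsample of dominant males and females, then
scoring splicing magnitude only on held-out samples.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import JunctionCounts
from .splicing import compute_psi, diff_splice

log = logging.getLogger("sexsplice")

MORPH_ORDER = ("dominant", "subordinate", "female")


def _morph_samples(meta: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "dominant": meta.loc[(meta["sex"] == "male") & (meta["morph"] == "dominant"),
                             "sample_id"].tolist(),
        "subordinate": meta.loc[(meta["sex"] == "male") & (meta["morph"] == "subordinate"),
                                "sample_id"].tolist(),
        "female": meta.loc[meta["sex"] == "female", "sample_id"].tolist(),
    }


def isoform_set_summary(psi: pd.DataFrame, counts: JunctionCounts,
                        bias_labels: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Per-morph means of sex-biased isoform expression and PSI, with
    pairwise paired Wilcoxon signed-rank tests across events.

    ``bias_labels`` comes from classify_isoform_bias on the dominant-male
    vs female contrast; the male-biased isoform set collects, per event,
    the junction counts of whichever form (inclusion or exclusion) was
    labeled male-biased, and symmetrically for female-biased.
    """
    if len(bias_labels) == 0:
        raise ValueError("empty bias set; relax the FDR/ΔPSI thresholds or "
                         "increase the planted effect")
    morphs = _morph_samples(meta)
    events = bias_labels["event_id"]
    inc_is_male = (bias_labels["inclusion_label"] == "male_biased").to_numpy()

    def isoform_counts(samples: Sequence[str], male_set: bool) -> np.ndarray:
        ijc = counts.ijc.loc[events, samples].to_numpy(dtype=float)
        sjc = counts.sjc.loc[events, samples].to_numpy(dtype=float)
        take_inc = inc_is_male if male_set else ~inc_is_male
        return np.where(take_inc[:, None], ijc, sjc).mean(axis=1)

    per_morph = {}
    for morph, samples in morphs.items():
        if not samples:
            continue
        per_morph[morph] = {
            "male_biased_expr": isoform_counts(samples, True),
            "female_biased_expr": isoform_counts(samples, False),
            "mean_psi": psi.loc[events, samples].mean(axis=1).to_numpy(),
        }
    summary = pd.DataFrame(
        {
            morph: {
                "mean_male_biased_expr": vals["male_biased_expr"].mean(),
                "mean_female_biased_expr": vals["female_biased_expr"].mean(),
                "mean_psi": np.nanmean(vals["mean_psi"]),
            }
            for morph, vals in per_morph.items()
        }
    ).T

    tests = []
    keys = list(per_morph)
    for i, m1 in enumerate(keys):
        for m2 in keys[i + 1:]:
            for measure in ("male_biased_expr", "female_biased_expr", "mean_psi"):
                a, b = per_morph[m1][measure], per_morph[m2][measure]
                ok = ~(np.isnan(a) | np.isnan(b))
                if ok.sum() < 5 or np.allclose(a[ok], b[ok]):
                    stat, p = np.nan, (1.0 if ok.sum() >= 5 else np.nan)
                else:
                    stat, p = stats.wilcoxon(a[ok], b[ok])
                tests.append((m1, m2, measure, float(np.nanmean(a)),
                              float(np.nanmean(b)), stat, p))
    tests_df = pd.DataFrame(
        tests, columns=["morph1", "morph2", "measure", "mean1", "mean2",
                        "statistic", "p"]
    )
    return {"summary": summary, "tests": tests_df, "n_events": len(events)}


def oriented_psi(psi: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Flip each significant event's PSI so the female-biased direction is
    positive: higher oriented PSI = more feminized splicing."""
    sig = records[records["significant"]]
    sub = psi.loc[sig["event_id"]]
    flip = (sig["delta_psi"] > 0).to_numpy()  # inclusion male-biased -> flip
    arr = sub.to_numpy(dtype=float)
    arr = np.where(flip[:, None], 1.0 - arr, arr)
    return pd.DataFrame(arr, index=sub.index, columns=sub.columns)


def randomization_intermediacy_test(counts: JunctionCounts, events: pd.DataFrame,
                                    meta: pd.DataFrame, n_reps: int = 100,
                                    discovery_n: int = 3, alpha: float = 0.05,
                                    fdr: float = 0.05, min_delta: float = 0.1,
                                    seed: int = 0) -> dict:
    """The regression-to-the-mean control.

    Per replicate: draw ``discovery_n`` dominant males and females, call
    differential splicing on that subset, orient discovered events so the
    female-biased direction is positive, then compare event-wise mean
    oriented PSI between held-out groups with Wilcoxon tests —
    subordinates vs held-out dominants (one-sided, sub higher),
    subordinates vs held-out females (one-sided, sub lower), and the
    dominant-vs-dominant / female-vs-female held-out splits as two-sided
    controls. Replicates that discover no event count as non-significant.
    """
    rng = np.random.default_rng(seed)
    morphs = _morph_samples(meta)
    doms, fems, subs = morphs["dominant"], morphs["female"], morphs["subordinate"]
    if len(doms) <= discovery_n or len(fems) <= discovery_n:
        raise ValueError("need more dominant males and females than discovery_n")
    if not subs:
        raise ValueError("no subordinate males in metadata")

    contrasts = ["sub_gt_dom", "sub_lt_fem", "dom_vs_dom", "fem_vs_fem"]
    sig_counts = dict.fromkeys(contrasts, 0)
    rep_rows = []
    for rep in range(n_reps):
        disc_d = list(rng.choice(doms, discovery_n, replace=False))
        disc_f = list(rng.choice(fems, discovery_n, replace=False))
        held_d = [s for s in doms if s not in disc_d]
        held_f = [s for s in fems if s not in disc_f]
        assert not (set(held_d) & set(disc_d)) and not (set(held_f) & set(disc_f))

        recs = diff_splice(counts, events, disc_d, disc_f,
                           fdr=fdr, min_delta=min_delta)
        sig = recs[recs["significant"]]
        rep_sig = {}
        if len(sig) == 0:
            log.info("replicate %d discovered no events", rep)
            rep_sig = dict.fromkeys(contrasts, False)
        else:
            psi = compute_psi(counts.subset_events(sig["event_id"]),
                              events.loc[sig["event_id"]])
            opsi = oriented_psi(psi, recs)

            def group_mean(samples: Sequence[str]) -> np.ndarray:
                return opsi[list(samples)].mean(axis=1).to_numpy()

            def rank_sum(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
                ok = ~(np.isnan(a) | np.isnan(b))
                if ok.sum() == 0:
                    return 1.0
                return float(stats.mannwhitneyu(a[ok], b[ok],
                                                alternative=alternative).pvalue)

            v_sub = group_mean(subs)
            v_dom = group_mean(held_d)
            v_fem = group_mean(held_f)
            rep_sig["sub_gt_dom"] = rank_sum(v_sub, v_dom, "greater") < alpha
            rep_sig["sub_lt_fem"] = rank_sum(v_sub, v_fem, "less") < alpha
            half_d = max(1, len(held_d) // 2)
            half_f = max(1, len(held_f) // 2)
            rep_sig["dom_vs_dom"] = rank_sum(
                group_mean(held_d[:half_d]), group_mean(held_d[half_d:]),
                "two-sided") < alpha
            rep_sig["fem_vs_fem"] = rank_sum(
                group_mean(held_f[:half_f]), group_mean(held_f[half_f:]),
                "two-sided") < alpha
        for c in contrasts:
            sig_counts[c] += bool(rep_sig[c])
        rep_rows.append({"replicate": rep, "n_discovered": len(sig), **rep_sig})

    return {
        "n_reps": n_reps,
        "significant_counts": sig_counts,
        "replicates": pd.DataFrame(rep_rows),
    }
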