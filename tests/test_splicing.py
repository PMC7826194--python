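"""PSI quantification and the beta-binomial differential-splicing test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sexsplice.simulate import simulate_splicing
from sexsplice.splicing import (
    classify_isoform_bias,
    compute_psi,
    diff_splice,
    filter_events,
    flag_alternative,
    gene_level_summary,
    psi_log2fc_significance as splicing_log2fc,
)

from conftest import make_counts, make_events


class TestComputePsi:
    @pytest.mark.parametrize(
        "etype,ijc,sjc,expected",
        [
            ("SE", 20, 10, 0.5),      # effective lengths 2:1
            ("SE", 50, 0, 1.0),       # single-isoform limit
            ("MXE", 30, 30, 0.5),     # equal support, lengths 2:2
            ("SE", 0, 30, 0.0),
            ("MXE", 60, 20, 0.75),
        ],
    )
    def test_effective_length_normalization(self, etype, ijc, sjc, expected):
        events = make_events(1, event_type=etype)
        counts = make_counts([[ijc]], [[sjc]], ["s1"])
        psi = compute_psi(counts, events)
        assert psi.loc["e0", "s1"] == pytest.approx(expected)

    def test_zero_total_is_missing_not_error(self):
        events = make_events(1)
        counts = make_counts([[0]], [[0]], ["s1"])
        psi = compute_psi(counts, events)
        assert np.isnan(psi.loc["e0", "s1"])

    def test_non_se_mxe_events_dropped(self):
        events = make_events(3, event_type=["SE", "RI", "A5SS"])
        counts = make_counts([[10]] * 3, [[10]] * 3, ["s1"])
        psi = compute_psi(counts, events)
        assert list(psi.index) == ["e0"]


class TestFilterEvents:
    def test_passing_and_failing_events(self):
        samples = ["a1", "a2", "b1", "b2"]
        # event 0: 25/25 everywhere -> retained; event 1: sjc 0 -> removed
        counts = make_counts(
            [[25, 25, 25, 25], [25, 25, 25, 25]],
            [[25, 25, 25, 25], [0, 0, 0, 0]],
            samples,
        )
        kept = filter_events(counts, ["a1", "a2"], ["b1", "b2"])
        assert list(kept) == ["e0"]

    def test_one_sided_coverage_removed(self):
        # passes in group A only -> removed
        counts = make_counts([[30, 30, 30, 5, 5, 5]], [[30, 30, 30, 5, 5, 5]],
                             list("abcdef"))
        kept = filter_events(counts, list("abc"), list("def"))
        assert len(kept) == 0

    def test_matches_brute_force_on_3v3_toy(self):
        """Enumerate 3v3 coverage patterns against a direct rule oracle."""
        rng = np.random.default_rng(7)
        group_a, group_b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        ijc = rng.integers(0, 60, (40, 6))
        sjc = rng.integers(0, 60, (40, 6))
        counts = make_counts(ijc, sjc, group_a + group_b)
        kept = set(filter_events(counts, group_a, group_b, min_reads=20,
                                 min_fraction=0.5))
        for e in range(40):
            ok = (ijc[e] >= 20) & (sjc[e] >= 20)
            expect = (ok[:3].sum() >= 1.5) and (ok[3:].sum() >= 1.5)
            assert (f"e{e}" in kept) == expect

    def test_empty_group_raises(self):
        counts = make_counts([[10, 10]], [[10, 10]], ["a", "b"])
        with pytest.raises(ValueError):
            filter_events(counts, [], ["a", "b"])


class TestFlagAlternative:
    @pytest.mark.parametrize(
        "psis,expected",
        [
            ((0.4, 0.6, 0.5), True),   # all interior
            ((1.0, 1.0, 0.5), False),  # only 1 of 3 interior
            ((0.0, 0.0, 0.0), False),
            ((0.3, 0.7, 1.0), True),   # 2 of 3 > half
        ],
    )
    def test_strict_interior_majority(self, psis, expected):
        psi = pd.DataFrame([psis], index=["e0"], columns=["s1", "s2", "s3"])
        flags = flag_alternative(psi, ["s1", "s2", "s3"])
        assert bool(flags.loc["e0"]) == expected


class TestDiffSplice:
    def test_sex_exclusive_isoforms_give_unit_delta(self, sexes_5v5):
        males, females = sexes_5v5
        ijc = [[50] * 5 + [0] * 5]
        sjc = [[0] * 5 + [50] * 5]
        counts = make_counts(ijc, sjc, males + females)
        events = make_events(1)
        rec = diff_splice(counts, events, males, females, prefilter=False)
        assert rec["delta_psi"].iloc[0] == pytest.approx(1.0)
        # mirrored: inclusion only in females
        rec2 = diff_splice(counts, events, females, males, prefilter=False)
        assert rec2["delta_psi"].iloc[0] == pytest.approx(-1.0)

    def test_identical_groups_null(self, sexes_5v5):
        males, females = sexes_5v5
        rng = np.random.default_rng(3)
        ij = rng.integers(20, 80, (30, 5))
        sj = rng.integers(20, 80, (30, 5))
        counts = make_counts(np.hstack([ij, ij]), np.hstack([sj, sj]),
                             males + females)
        events = make_events(30)
        rec = diff_splice(counts, events, males, females)
        assert (rec["delta_psi"] == 0).all()
        assert (rec["p"] > 0.9).all()
        assert not rec["significant"].any()

    def test_group_swap_antisymmetry(self, splicing_panel):
        events, counts, meta, _ = splicing_panel
        doms = meta.loc[meta["morph"] == "dominant", "sample_id"].tolist()
        fems = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
        a = diff_splice(counts, events, doms, fems)
        b = diff_splice(counts, events, fems, doms)
        np.testing.assert_allclose(a["delta_psi"], -b["delta_psi"], atol=1e-12)
        np.testing.assert_allclose(a["lrt_stat"], b["lrt_stat"], rtol=1e-6, atol=1e-6)

    def test_power_monotone_in_effect_and_coverage(self):
        """Recall of planted events grows with |ΔPSI| and with coverage."""
        powers = []
        for delta in (0.1, 0.25, 0.45):
            events, counts, meta, truth = simulate_splicing(
                n_events=400, coverage_mean=150, frac_biased=0.5, delta=delta,
                rho=0.01, seed=42)
            doms = meta.loc[meta["morph"] == "dominant", "sample_id"].tolist()
            fems = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
            rec = diff_splice(counts, events, doms, fems)
            tr = truth.set_index("event_id").loc[rec["event_id"], "sex_biased"]
            powers.append((rec["significant"].to_numpy() & tr.to_numpy()).sum()
                          / tr.sum())
        assert powers[0] < powers[1] < powers[2]

        cov_powers = []
        for cov in (80, 400):
            events, counts, meta, truth = simulate_splicing(
                n_events=400, coverage_mean=cov, frac_biased=0.5, delta=0.2,
                rho=0.01, seed=43)
            doms = meta.loc[meta["morph"] == "dominant", "sample_id"].tolist()
            fems = meta.loc[meta["sex"] == "female", "sample_id"].tolist()
            rec = diff_splice(counts, events, doms, fems)
            tr = truth.set_index("event_id").loc[rec["event_id"], "sex_biased"]
            cov_powers.append((rec["significant"].to_numpy() & tr.to_numpy()).sum()
                              / tr.sum())
        assert cov_powers[0] < cov_powers[1]


class TestLog2fcSignificanceMode:
    def test_equal_threshold_rule(self):
        recs = pd.DataFrame(
            {
                "event_id": ["e0", "e1", "e2"],
                "mean_psi_g1": [0.8, 0.30, 0.8],
                "mean_psi_g2": [0.2, 0.25, 0.2],
                "fdr": [0.01, 0.01, 0.5],
                "significant": [True, True, False],
            }
        )
        out = splicing_log2fc(recs)
        # e0: ~2-fold PSI change and low FDR -> kept
        assert out.loc[0, "significant"]
        # e1: small fold change -> dropped despite low FDR
        assert not out.loc[1, "significant"]
        # e2: high FDR -> dropped despite fold change
        assert not out.loc[2, "significant"]


class TestGeneSummaryAndBias:
    def test_gene_psi_is_unweighted_event_mean(self):
        events = make_events(2, genes=["g1", "g1"])
        counts = make_counts([[10, 0], [40, 0]], [[20, 0], [5, 0]], ["s1", "s2"])
        psi = compute_psi(counts, events)
        recs = pd.DataFrame(
            {"event_id": ["e0", "e1"], "gene_id": ["g1", "g1"],
             "significant": [True, False]}
        )
        summary, gene_psi = gene_level_summary(recs, psi, events)
        expect = (psi.loc["e0", "s1"] + psi.loc["e1", "s1"]) / 2
        assert gene_psi.loc["g1", "s1"] == pytest.approx(expect)
        assert summary.loc[summary["gene_id"] == "g1", "diff_spliced"].item()

    def test_gene_without_significant_events_not_flagged(self):
        recs = pd.DataFrame(
            {"event_id": ["e0"], "gene_id": ["g1"], "significant": [False]}
        )
        events = make_events(1, genes=["g1"])
        psi = pd.DataFrame([[0.5]], index=events.index, columns=["s1"])
        summary, _ = gene_level_summary(recs, psi, events)
        assert not summary["diff_spliced"].any()

    def test_isoform_bias_sign_rule(self):
        recs = pd.DataFrame(
            {
                "event_id": ["e0", "e1"],
                "gene_id": ["g1", "g2"],
                "delta_psi": [0.3, -0.3],
                "significant": [True, True],
            }
        )
        lab = classify_isoform_bias(recs).set_index("event_id")
        assert lab.loc["e0", "inclusion_label"] == "male_biased"
        assert lab.loc["e0", "exclusion_label"] == "female_biased"
        assert lab.loc["e1", "inclusion_label"] == "female_biased"
        # label flip under group swap
        swapped = recs.assign(delta_psi=-recs["delta_psi"])
        lab2 = classify_isoform_bias(swapped).set_index("event_id")
        assert (lab2["inclusion_label"].to_numpy()
                == lab["exclusion_label"].to_numpy()).all()
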