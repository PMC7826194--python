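"""Hudson FST, Tajima's D, architecture enrichment, and weighted dN/dS."""

import numpy as np
import pandas as pd
import pytest

from sexsplice.selection import (
    architecture_enrichment,
    dnds_covariate_control,
    exon_class_fst,
    hudson_fst_per_gene,
    immune_gene_filter,
    tajima_constants,
    tajimas_d,
    tajimas_d_from_counts,
    weighted_dnds,
    weighted_dnds_estimate,
)
from sexsplice.simulate import simulate_allele_counts, simulate_dnds_table


def spreadsheet_fst(rows):
    """Independent site-by-site evaluation of the ratio of sums."""
    nums, dens = [], []
    for m_alt, m_tot, f_alt, f_tot in rows:
        p1, p2 = m_alt / m_tot, f_alt / f_tot
        nums.append((p1 - p2) ** 2
                    - p1 * (1 - p1) / (m_tot - 1)
                    - p2 * (1 - p2) / (f_tot - 1))
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    dens_pos = [(n, d) for n, d in zip(nums, dens) if d > 0]
    return sum(n for n, _ in dens_pos) / sum(d for _, d in dens_pos)


def _table(rows, gene="g1"):
    return pd.DataFrame(
        [(gene, i, m_tot - m_alt, m_alt, f_tot - f_alt, f_alt)
         for i, (m_alt, m_tot, f_alt, f_tot) in enumerate(rows)],
        columns=["gene_id", "site", "male_ref", "male_alt",
                 "female_ref", "female_alt"],
    )


class TestHudsonFst:
    def test_two_site_hand_case(self):
        rows = [(6, 10, 2, 10), (5, 10, 5, 10)]
        fst = hudson_fst_per_gene(_table(rows))["fst"].iloc[0]
        assert fst == pytest.approx(spreadsheet_fst(rows), rel=1e-12)
        assert fst == pytest.approx(0.06 / 1.06, rel=1e-6)

    def test_fixed_difference_limit(self):
        rows = [(10, 10, 0, 10)] * 5
        fst = hudson_fst_per_gene(_table(rows))["fst"].iloc[0]
        assert fst == pytest.approx(1.0)

    def test_equal_frequencies_slightly_negative(self):
        rows = [(5, 10, 5, 10)]
        fst = hudson_fst_per_gene(_table(rows))["fst"].iloc[0]
        # numerator = -p(1-p)(1/(n1-1)+1/(n2-1)) = -0.25*2/9; den = 0.5
        assert fst == pytest.approx((-0.25 * 2 / 9) / 0.5)
        assert fst < 0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_sites = rng.integers(2, 8)
            rows = []
            for _ in range(n_sites):
                m_tot = int(rng.integers(4, 30))
                f_tot = int(rng.integers(4, 30))
                rows.append((int(rng.integers(1, m_tot)), m_tot,
                             int(rng.integers(1, f_tot)), f_tot))
            got = hudson_fst_per_gene(_table(rows))["fst"].iloc[0]
            oracle = spreadsheet_fst(rows)
            assert got == pytest.approx(oracle, rel=1e-10)
            ratios = []
            for m_alt, m_tot, f_alt, f_tot in rows:
                p1, p2 = m_alt / m_tot, f_alt / f_tot
                den = p1 * (1 - p2) + p2 * (1 - p1)
                if den > 0:
                    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (m_tot - 1)
                           - p2 * (1 - p2) / (f_tot - 1))
                    ratios.append(num / den)
            mean_of_ratios = np.mean(ratios)
            if abs(mean_of_ratios - oracle) > 1e-9:
                assert got != pytest.approx(mean_of_ratios, abs=1e-12)

    def test_monomorphic_gene_missing(self):
        rows = [(0, 10, 0, 10)]
        fst = hudson_fst_per_gene(_table(rows))["fst"].iloc[0]
        assert np.isnan(fst)

    def test_planted_differentiation_ranks_high(self):
        tab, truth = simulate_allele_counts(n_genes=500, d=0.4,
                                            frac_differentiated=0.1, seed=2)
        fst = hudson_fst_per_gene(tab).merge(truth, on="gene_id")
        fst["pct"] = fst["fst"].rank(pct=True)
        assert fst.loc[fst["sex_differentiated"], "pct"].mean() > 0.85


class TestTajimasD:
    def test_constants_hand_case(self):
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            counts = rng.integers(0, n + 1, rng.integers(1, 40))
            res = tajimas_d_from_counts(counts, n)
            if res["S"] == 0:
                assert np.isnan(res["D"])
                continue
            # independent arithmetic
            i = np.arange(1, n)
            a1 = (1 / i).sum()
            a2 = (1 / i ** 2).sum()
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
            e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
            S = res["S"]
            D = (res["pi"] - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
            assert res["D"] == pytest.approx(D, rel=1e-12)

    def test_centering_pi_equal_watterson_gives_zero(self):
        res = tajimas_d_from_counts([2, 2], 4)
        a1 = tajima_constants(4)["a1"]
        manual = (res["pi"] - res["S"] / a1)
        if abs(manual) < 1e-12:
            assert res["D"] == pytest.approx(0.0)
        # direct check of the centering property on the formula itself
        assert np.sign(res["D"]) == np.sign(manual)

    def test_neutral_sfs_mean_near_zero(self):
        tab, _ = simulate_allele_counts(n_genes=500, n_sites=30, d=0.0,
                                        frac_differentiated=0.0, seed=4)
        taj = tajimas_d(tab)
        assert abs(taj["D"].mean()) < 0.3


class TestArchitectureEnrichment:
    def _inputs(self, d, seed):
        # sex-differential architecture: a few strongly differentiated sites
        # inside genes whose remaining spectrum is skewed toward rare alleles
        tab, truth = simulate_allele_counts(n_genes=400, n_sites=40, d=d,
                                            frac_differentiated=0.15,
                                            frac_offset_sites=0.1,
                                            sfs_skew=2.0, seed=seed)
        fst = hudson_fst_per_gene(tab)
        taj = tajimas_d(tab)
        flags = pd.DataFrame(
            {"gene_id": truth["gene_id"],
             "diff_spliced": truth["sex_differentiated"]}
        )
        return flags, fst, taj

    def test_planted_effect_detected(self):
        flags, fst, taj = self._inputs(d=0.5, seed=6)
        res = architecture_enrichment(flags, fst, taj)
        assert res["p"] < 0.01

    def test_random_flags_null(self):
        ps = []
        for seed in range(10):
            flags, fst, taj = self._inputs(d=0.0, seed=100 + seed)
            rng = np.random.default_rng(seed)
            flags["diff_spliced"] = rng.random(len(flags)) < 0.15
            res = architecture_enrichment(flags, fst, taj)
            ps.append(res["p"])
        assert (np.array(ps) < 0.05).sum() <= 3

    def test_de_and_immune_genes_removed(self):
        flags, fst, taj = self._inputs(d=0.5, seed=7)
        res_all = architecture_enrichment(flags, fst, taj)
        drop = set(flags["gene_id"].iloc[:50])
        res = architecture_enrichment(flags, fst, taj, de_genes=drop)
        assert res["n_genes"] == res_all["n_genes"] - 50

    def test_immune_keyword_filter(self):
        ann = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"],
             "annotation": ["immune response", "MHC class I", "metabolism"]}
        )
        assert immune_gene_filter(ann) == {"g1", "g2"}


class TestExonClassFst:
    def test_identical_classes_zero_shift(self):
        rows = []
        for g in range(10):
            for s in range(4):
                rows.append((f"g{g}", s, 5, 5, 7, 3,
                             "sex_biased" if s % 2 else "unbiased"))
        tab = pd.DataFrame(rows, columns=["gene_id", "site", "male_ref",
                                          "male_alt", "female_ref",
                                          "female_alt", "exon_class"])
        res = exon_class_fst(tab)
        assert res["median_diff"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_planted_class_effect_and_label_swap(self):
        tab, _ = simulate_allele_counts(n_genes=300, d=0.5,
                                        frac_differentiated=1.0,
                                        classify_exons=True, seed=8)
        res = exon_class_fst(tab)
        assert res["median_diff"] > 0
        assert res["p"] < 0.01
        swapped = tab.replace({"exon_class": {"sex_biased": "unbiased",
                                              "unbiased": "sex_biased"}})
        res2 = exon_class_fst(swapped)
        assert res2["median_diff"] == pytest.approx(-res["median_diff"])


class TestWeightedDnds:
    def test_single_gene_closed_form(self):
        rec = pd.DataFrame(
            [{"gene_id": "g", "N": 100.0, "S": 50.0, "NdN": 1.0, "SdS": 1.0,
              "dS": 0.02, "class": "x"}]
        )
        # NdN/N = 0.01, SdS/S = 0.02 -> 0.5
        assert weighted_dnds_estimate(rec) == pytest.approx(0.5)

    def test_ds_saturated_genes_excluded(self):
        table = simulate_dnds_table(n_genes_per_class=50, frac_saturated=0.2,
                                    seed=9)
        assert (table["dS"] > 2).any()
        res = weighted_dnds(table, n_boot=10, n_perm=10, seed=0)
        assert (res["n_genes"] < 50).any()

    def test_identical_classes_null_permutation(self):
        table = simulate_dnds_table(
            n_genes_per_class=100,
            omega_by_class={"a": 0.1, "b": 0.1}, seed=10)
        res = weighted_dnds(table, n_boot=50, n_perm=200, seed=1)
        assert res.attrs["pairwise"]["p_perm"].iloc[0] > 0.05

    def test_planted_ordering_with_separated_cis(self):
        table = simulate_dnds_table(
            n_genes_per_class=500,
            omega_by_class={"spliced": 0.05, "expressed": 0.2}, seed=11)
        res = weighted_dnds(table, n_boot=200, n_perm=200, seed=2) \
            .set_index("class")
        assert res.loc["spliced", "dnds"] < res.loc["expressed", "dnds"]
        assert res.loc["spliced", "ci_hi"] < res.loc["expressed", "ci_lo"]
        assert res.attrs["pairwise"]["p_perm"].iloc[0] < 0.01


class TestCovariateControl:
    def test_orthogonal_class_effect_significant(self):
        table = simulate_dnds_table(
            n_genes_per_class=200,
            omega_by_class={"spliced": 0.05, "expressed": 0.25}, seed=12)
        rng = np.random.default_rng(12)
        table["expression"] = rng.lognormal(3, 1, len(table))
        res = dnds_covariate_control(table)
        assert res["class_p"] < 0.001

    def test_length_confounded_effect_vanishes(self):
        """dN/dS driven entirely by length: the class term stays null."""
        rng = np.random.default_rng(13)
        rows = []
        for i in range(400):
            cls = "a" if i < 200 else "b"
            length = rng.uniform(500, 5000)
            omega = 0.3 * (1000 / length)  # pure length effect, same per class
            ds_true = 0.2
            n_sites, s_sites = 0.75 * length, 0.25 * length
            rows.append((f"g{i}", n_sites, s_sites,
                         n_sites * omega * ds_true, s_sites * ds_true,
                         ds_true, cls, length))
        table = pd.DataFrame(rows, columns=["gene_id", "N", "S", "NdN",
                                            "SdS", "dS", "class", "cds_length"])
        table["expression"] = rng.lognormal(3, 1, len(table))
        res = dnds_covariate_control(table)
        assert res["class_p"] > 0.05

    def test_zero_variance_covariate_dropped(self):
        table = simulate_dnds_table(n_genes_per_class=50, seed=14)
        table["cds_length"] = 1000.0
        res = dnds_covariate_control(table)
        assert "log_length" not in res["covariates"]
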