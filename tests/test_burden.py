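"""Genotype QC, carrier counting, Fisher burden and corrections."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from chdburden.burden import (MultipleTestingConfig, adjust_bh,
                              adjust_bonferroni, count_carriers,
                              fisher_burden, minimal_p, qc_genotype,
                              recessive_burden, run_gene_burden,
                              synonymous_burden)


def exact_fisher_tail(a, n_case, b, n_ctrl):
    """Integer-exact one-sided tail by hypergeometric enumeration."""
    n, k = n_case + n_ctrl, a + b
    num = sum(comb(k, x) * comb(n - k, n_case - x)
              for x in range(a, min(k, n_case) + 1))
    return num / comb(n, n_case)


class TestQc:
    @pytest.mark.parametrize("zyg,dp,gq,ab,expected", [
        ("het", 9, 50, 0.5, False),    # DP below 10
        ("het", 10, 19, 0.5, False),   # GQ below 20
        ("hom_alt", 10, 20, 1.0, True),   # AB rule is het-only
        ("het", 30, 60, 0.2, False),   # AB strictly above 0.2
        ("het", 30, 60, 0.201, True),
        ("hemizygous", 10, 20, 1.0, True),
        ("missing", 99, 99, 0.5, False),
    ])
    def test_high_confidence_rule(self, zyg, dp, gq, ab, expected):
        call = {"zygosity": zyg, "dp": dp, "gq": gq, "ab": ab}
        assert qc_genotype(call) is expected


class TestCarrierCounting:
    def test_counts_on_tiny_cohort(self, tiny_cohort):
        # S3 is the only sCHD hcLOF carrier; S1's call fails DP
        assert count_carriers(tiny_cohort, "GA", "hcLOF", "sCHD") == 1
        assert count_carriers(tiny_cohort, "GA", "hcLOF", "control") == 0
        # S5 hom_alt at missC passes (AB gate only applies to het)
        assert count_carriers(tiny_cohort, "GA", "missC", "nsCHD") == 1
        # hemizygous synonymous carrier on X
        assert count_carriers(tiny_cohort, "GB", "synonymous", "sCHD") == 1
        # non-qualifying missense contributes to no category
        assert count_carriers(tiny_cohort, "GB", "missC", "nsCHD") == 0

    def test_sample_counted_once_per_gene_category(self, tiny_cohort):
        gt = pd.concat([tiny_cohort.genotypes, pd.DataFrame([{
            # second qualifying missC call for S5 in GA — still 1 carrier
            "sample_id": "S5", "variant_id": "1:1000:A:T",
            "zygosity": "het", "dp": 40, "gq": 80, "ab": 0.5}])],
            ignore_index=True)
        ds = tiny_cohort
        ds2 = type(ds)(ds.variants, gt, ds.samples, ds.genes).validate()
        assert count_carriers(ds2, "GA", "hcLOF", "nsCHD") == 1

    def test_unknown_gene_is_error(self, tiny_cohort):
        with pytest.raises(KeyError):
            count_carriers(tiny_cohort, "NOPE", "hcLOF", "sCHD")


class TestFisher:
    def test_worked_example(self):
        # all three carriers in cases: tail = (100*99*98)/(200*199*198)
        assert fisher_burden(3, 100, 0, 100) == pytest.approx(
            100 * 99 * 98 / (200 * 199 * 198), rel=1e-12)

    def test_no_case_carriers_gives_one(self):
        assert fisher_burden(0, 1818, 5, 52881) == 1.0

    def test_matches_exact_enumeration_spot(self):
        assert fisher_burden(8, 1818, 0, 52881) == pytest.approx(
            exact_fisher_tail(8, 1818, 0, 52881), rel=1e-10)

    def test_monotone_in_case_carriers(self):
        ps = [fisher_burden(a, 100, 5, 1000) for a in range(0, 20)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_burden(5, 4, 0, 100)
        with pytest.raises(ValueError):
            fisher_burden(-1, 10, 0, 100)


class TestMinimalP:
    @pytest.mark.parametrize("p_lof,p_miss,expected", [
        (1e-8, 1e-3, (1e-8, "hcLOF")),
        (1.0, 1.0, (1.0, "hcLOF")),      # tie resolves to hcLOF
        (0.5, 1e-4, (1e-4, "missC")),
    ])
    def test_componentwise_minimum(self, p_lof, p_miss, expected):
        assert minimal_p(p_lof, p_miss) == expected


def bh_bruteforce(p, n_tests):
    """Direct definition: q_i = min_{j>=i} min(1, p_(j) * n / j)."""
    order = np.argsort(p, kind="mergesort")
    k = len(p)
    out = np.empty(k)
    for pos in range(k):
        out[order[pos]] = min(
            min(1.0, p[order[j]] * n_tests / (j + 1))
            for j in range(pos, k))
    return out


class TestCorrections:
    def test_bonferroni_caps_at_one(self):
        cfg = MultipleTestingConfig()
        assert cfg.n_tests == 32702
        assert adjust_bonferroni(9.76e-13, cfg) == pytest.approx(3.19e-8,
                                                                 rel=1e-3)
        assert adjust_bonferroni(3.15e-5, cfg) == 1.0
        assert adjust_bonferroni(1.0, cfg) == 1.0

    def test_bh_single_element(self):
        out = adjust_bh([1e-6], MultipleTestingConfig())
        assert out[0] == pytest.approx(1e-6 * 32702)

    def test_bh_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        cfg = MultipleTestingConfig(n_genes_tested=50)
        for _ in range(50):
            k = int(rng.integers(1, 50))
            p = rng.uniform(1e-9, 1, size=k)
            assert adjust_bh(p, cfg) == pytest.approx(
                bh_bruteforce(p, cfg.n_tests), abs=1e-14)

    def test_bh_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            adjust_bh([0.0, 0.5], MultipleTestingConfig())


class TestPipelines:
    def test_planted_gene_attains_smallest_p(self, planted_cohort):
        res = run_gene_burden(planted_cohort)
        top = res.loc[res["p_min"].idxmin()]
        assert top["gene_id"] == "G00007"
        assert top["stratum"] == "sCHD"
        assert top["min_category"] == "hcLOF"

    def test_null_cohort_no_bonferroni_hit(self, null_cohort):
        res = run_gene_burden(null_cohort)
        assert (res["p_bonferroni"] < 0.05).sum() == 0

    def test_adjusted_never_below_raw(self, null_cohort):
        res = run_gene_burden(null_cohort)
        assert (res["p_bonferroni"] >= res["p_min"] - 1e-15).all()
        assert (res["p_bh"] >= res["p_min"] - 1e-15).all()
        assert (res["p_bh"] <= 1.0).all()
        assert np.allclose(res["p_min"],
                           np.minimum(res["p_lof"], res["p_miss"]))

    def test_synonymous_control_not_anticonservative(self, null_cohort):
        """Null synonymous p-values sit at or above the uniform quantiles
        (one-sided discrete tests are conservative)."""
        p = np.sort(synonymous_burden(null_cohort)["p"].to_numpy())
        quantiles = (np.arange(1, p.size + 1) - 0.5) / p.size
        checked = slice(p.size // 10, None)  # tested quantiles
        assert (p[checked] >= quantiles[checked] * 0.5).all()
        assert np.median(p) >= 0.45


class TestRecessive:
    def _with_calls(self, ds, rows):
        gt = pd.concat([ds.genotypes, pd.DataFrame(rows)], ignore_index=True)
        return type(ds)(ds.variants, gt, ds.samples, ds.genes).validate()

    def test_two_het_hits_count_once_hom_counts(self, tiny_cohort):
        # S3 already has two distinct qualifying het variants in GA
        res = recessive_burden(tiny_cohort)
        ga = res[(res.gene_id == "GA") & (res.stratum == "sCHD")]
        assert ga["carriers_case"].iloc[0] == 1
        # S5 hom_alt at one qualifying missC variant in GA
        ga_ns = res[(res.gene_id == "GA") & (res.stratum == "nsCHD")]
        assert ga_ns["carriers_case"].iloc[0] == 1

    def test_single_het_is_not_recessive_carrier(self, tiny_cohort):
        ds = self._with_calls(tiny_cohort, [{
            "sample_id": "S6", "variant_id": "1:1000:A:T",
            "zygosity": "het", "dp": 40, "gq": 80, "ab": 0.5}])
        res = recessive_burden(ds)
        ga_ns = res[(res.gene_id == "GA") & (res.stratum == "nsCHD")]
        # S5 (hom) yes, S6 (one het) no
        assert ga_ns["carriers_case"].iloc[0] == 1

    def test_null_cohort_recessive_no_significant(self, null_cohort):
        res = recessive_burden(null_cohort)
        if len(res):
            assert (res["p_bonferroni"] < 0.05).sum() == 0
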