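"""Constraint bins, MAC aggregation and the logistic burden test."""

import numpy as np
import pandas as pd
import pytest

from chdburden.burden import qualifying_genotypes
from chdburden.data_model import GeneSetCollection
from chdburden.geneset import (logistic_geneset_test, mac_by_sample,
                               make_constraint_bins, per_sample_mac,
                               run_geneset_battery)


class TestConstraintBins:
    def test_exact_division(self):
        genes = pd.DataFrame({"gene_id": [f"G{i}" for i in range(20)],
                              "loeuf": np.linspace(0.1, 2.0, 20),
                              "moeuf": np.nan})
        b = make_constraint_bins(genes, "loeuf", n_bins=10)
        sizes = pd.Series(b.assignment).value_counts()
        assert (sizes == 2).all()

    def test_study_scale_bin_sizes(self):
        genes = pd.DataFrame({"gene_id": [f"G{i:05d}" for i in range(19923)],
                              "loeuf": np.random.default_rng(0).uniform(
                                  0.01, 2, 19923),
                              "moeuf": np.nan})
        b = make_constraint_bins(genes, "loeuf")
        sizes = pd.Series(b.assignment).value_counts()
        assert set(sizes) == {1992, 1993}

    def test_most_constrained_gene_in_bin_one(self):
        genes = pd.DataFrame({"gene_id": ["A", "B", "C", "D"],
                              "loeuf": [0.9, 0.05, 0.5, 1.4],
                              "moeuf": np.nan})
        b = make_constraint_bins(genes, "loeuf", n_bins=2)
        assert b.assignment["B"] == 1
        assert b.assignment["D"] == 2

    def test_partition_and_unassigned(self):
        genes = pd.DataFrame({"gene_id": [f"G{i}" for i in range(30)],
                              "loeuf": [np.nan if i % 3 == 0 else i * 0.1
                                        for i in range(30)],
                              "moeuf": np.nan})
        b = make_constraint_bins(genes, "loeuf", n_bins=5)
        assert set(b.assignment) == set(
            genes.loc[genes.loeuf.notna(), "gene_id"])
        coll = b.as_collection()
        all_ids = [g for ids in coll.sets.values() for g in ids]
        assert len(all_ids) == len(set(all_ids))

    def test_metric_absent_everywhere_is_error(self):
        genes = pd.DataFrame({"gene_id": ["A"], "loeuf": [np.nan],
                              "moeuf": [np.nan]})
        with pytest.raises(ValueError):
            make_constraint_bins(genes, "loeuf")


class TestMac:
    def test_dosage_sum(self, tiny_cohort):
        # S3: het hcLOF (1); S5: hom_alt missC (2); S4: hemizygous syn (1)
        assert per_sample_mac(tiny_cohort, "S3", ["GA"], "hcLOF") == 1
        assert per_sample_mac(tiny_cohort, "S5", ["GA"], "missC") == 2
        assert per_sample_mac(tiny_cohort, "S4", ["GB"], "synonymous") == 1
        assert per_sample_mac(tiny_cohort, "S2", ["GA", "GB"], "hcLOF") == 0

    def test_qc_failing_call_excluded(self, tiny_cohort):
        # S1's het at the hcLOF variant fails DP
        assert per_sample_mac(tiny_cohort, "S1", ["GA"], "hcLOF") == 0

    def test_additive_over_disjoint_sets(self, planted_cohort):
        qual = qualifying_genotypes(planted_cohort)
        ids = planted_cohort.samples["sample_id"]
        genes = planted_cohort.genes["gene_id"].tolist()
        a, b = genes[:150], genes[150:]
        total = mac_by_sample(qual, genes, "missC", ids)
        parts = (mac_by_sample(qual, a, "missC", ids)
                 + mac_by_sample(qual, b, "missC", ids))
        assert (total == parts).all()


def newton_logistic(X, y, tol=1e-12, maxit=200):
    """Independent IRLS/Newton fit used as the reference solver."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxit):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        w = mu * (1 - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestLogistic:
    def test_agrees_with_independent_newton_solver(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(80, 200))
            mac = rng.poisson(0.5, size=n).astype(float)
            cov = rng.standard_normal((n, 3))
            logit = -0.5 + 0.4 * mac + cov @ np.array([0.2, -0.1, 0.0])
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            if y.sum() < 5 or y.sum() > n - 5 or np.ptp(mac) == 0:
                continue
            res = logistic_geneset_test(mac, y, cov)
            if not res.converged or res.quasi_separated:
                continue
            X = np.column_stack([np.ones(n), mac, cov])
            beta_ref = newton_logistic(X, y)
            assert res.beta == pytest.approx(beta_ref[1], abs=1e-6)

    def test_all_zero_mac_flagged_degenerate(self):
        res = logistic_geneset_test(np.zeros(100),
                                    np.r_[np.ones(50), np.zeros(50)])
        assert res.degenerate
        assert np.isnan(res.beta)
        assert res.p == 1.0

    def test_single_class_response_is_error(self):
        with pytest.raises(ValueError):
            logistic_geneset_test(np.arange(10.0), np.ones(10))

    def test_rank_deficient_covariates_dropped(self):
        rng = np.random.default_rng(2)
        n = 300
        mac = rng.poisson(0.5, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        cov = rng.standard_normal((n, 2))
        cov = np.column_stack([cov, cov[:, 0] * 2.0])  # duplicate column
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = logistic_geneset_test(mac, y, cov)
        assert np.isfinite(res.beta)

    def test_result_invariants(self):
        rng = np.random.default_rng(9)
        n = 500
        mac = rng.poisson(0.3, n).astype(float)
        y = (rng.random(n) < 0.3 + 0.1 * (mac > 0)).astype(float)
        res = logistic_geneset_test(mac, y)
        lo, hi = res.ci95
        assert 0 < lo < res.odds_ratio < hi
        assert 0 < res.p <= 1
        assert res.p_bonferroni >= res.p


class TestBattery:
    def test_planted_cluster_recovered(self, planted_cohort,
                                       planted_sim_config):
        from chdburden.simulate import simulate_deg_clusters
        clusters = simulate_deg_clusters(planted_sim_config)
        res = run_geneset_battery(planted_cohort, clusters)
        assert set(res["set_label"]) == {f"C{i}" for i in range(15)}
        assert res["n_tests_family"].iloc[0] == 45
        hit = res[(res.set_label == "C14") & (res.stratum == "sCHD")
                  & (res.category == "hcLOF")]
        assert hit["p_bonferroni"].iloc[0] < 0.05
        assert hit["odds_ratio"].iloc[0] > 1.5
        miss = res[(res.set_label == "C14") & (res.stratum == "nsCHD")
                   & (res.category == "hcLOF")]
        assert miss["p_bonferroni"].iloc[0] > 0.05

    def test_synonymous_category_flags_nothing(self, planted_cohort,
                                               planted_sim_config):
        from chdburden.simulate import simulate_deg_clusters
        clusters = simulate_deg_clusters(planted_sim_config)
        res = run_geneset_battery(planted_cohort, clusters,
                                  categories=("synonymous",))
        assert (res["p_bonferroni"] < 0.05).sum() == 0
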