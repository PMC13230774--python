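"""Category rules, rarity filter, and ROC-based threshold selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chdburden.classify import (CategoryConfig, is_hclof, is_missc, is_rare,
                                select_score_thresholds, variant_category,
                                classify_variants, youden_threshold, _auc)
from chdburden.simulate import simulate_labeled_scores

CFG = CategoryConfig()


def make_variant(consequence="missense", lof_hc=0, cadd=None, revel=None,
                 mvp=None, **afs):
    v = {"consequence": consequence, "lof_hc": lof_hc,
         "cadd": cadd, "revel": revel, "mvp": mvp,
         "af_internal": None, "af_gnomad_exomes": None,
         "af_gnomad_genomes": None, "af_rumc": None, "af_inhouse": None}
    v.update(afs)
    return v


class TestHclof:
    @pytest.mark.parametrize("csq,flag,expected", [
        ("stop_gained", 1, True),
        ("frameshift", 1, True),
        ("essential_splice", 1, True),
        ("stop_gained", 0, False),   # flag gate
        ("missense", 1, False),      # consequence gate (flag irrelevant)
        ("synonymous", 0, False),
    ])
    def test_consequence_and_flag_gates(self, csq, flag, expected):
        # the invariant layer forbids lof_hc on non-LOF rows, but the
        # rule itself must still gate on consequence
        assert is_hclof(make_variant(consequence=csq, lof_hc=flag)) is expected


class TestMissc:
    @pytest.mark.parametrize("cadd,revel,mvp,expected", [
        (25.0, 0.61, 0.10, True),    # CADD + REVEL pass
        (30.0, 0.40, 0.50, False),   # only CADD passes
        (None, 0.9, 0.9, True),      # missing counts as fail; 2 remain
        (24.0, 0.5, 0.0, True),      # thresholds are inclusive
        (23.99, 0.499, 0.799, False),
        (None, None, 0.9, False),
    ])
    def test_two_of_three_rule(self, cadd, revel, mvp, expected):
        v = make_variant(cadd=cadd, revel=revel, mvp=mvp)
        assert is_missc(v, CFG) is expected

    def test_non_missense_never_missc(self):
        v = make_variant(consequence="synonymous", cadd=40, revel=1, mvp=1)
        assert is_missc(v, CFG) is False

    @given(cadd=st.floats(0, 50), revel=st.floats(0, 1), mvp=st.floats(0, 1),
           bump=st.floats(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_scores(self, cadd, revel, mvp, bump):
        """Raising any score never demotes a missC variant."""
        base = is_missc(make_variant(cadd=cadd, revel=revel, mvp=mvp), CFG)
        bumped = is_missc(make_variant(cadd=cadd + bump,
                                       revel=min(1, revel + bump),
                                       mvp=min(1, mvp + bump)), CFG)
        assert bumped >= base


class TestRarity:
    def test_any_source_at_threshold_fails(self):
        v = make_variant(af_gnomad_exomes=0.0015, af_internal=0.0,
                         af_rumc=0.0)
        assert is_rare(v, CFG) is False

    def test_all_absent_or_zero_is_rare(self):
        assert is_rare(make_variant(), CFG) is True
        assert is_rare(make_variant(af_internal=0.0), CFG) is True

    def test_internal_af_also_binds(self):
        v = make_variant(af_internal=0.002, af_gnomad_exomes=0.0)
        assert is_rare(v, CFG) is False

    def test_threshold_strict(self):
        assert is_rare(make_variant(af_rumc=0.001), CFG) is False
        assert is_rare(make_variant(af_rumc=0.000999), CFG) is True


class TestCategoryPartition:
    @pytest.mark.parametrize("variant,expected", [
        (make_variant(consequence="frameshift", lof_hc=1), "hcLOF"),
        (make_variant(consequence="synonymous"), "synonymous"),
        (make_variant(cadd=30.0, revel=0.1, mvp=0.1), "none"),
        (make_variant(cadd=30.0, revel=0.9, mvp=0.1), "missC"),
        (make_variant(consequence="other"), "none"),
    ])
    def test_examples(self, variant, expected):
        assert variant_category(variant, CFG) == expected

    @given(csq=st.sampled_from(["stop_gained", "frameshift",
                                "essential_splice", "missense",
                                "synonymous", "other"]),
           lof=st.booleans(),
           cadd=st.one_of(st.none(), st.floats(0, 60)),
           revel=st.one_of(st.none(), st.floats(0, 1)),
           mvp=st.one_of(st.none(), st.floats(0, 1)))
    @settings(max_examples=300, deadline=None)
    def test_every_variant_gets_exactly_one_category(self, csq, lof, cadd,
                                                     revel, mvp):
        lof = lof and csq in ("stop_gained", "frameshift", "essential_splice")
        cat = variant_category(make_variant(consequence=csq, lof_hc=int(lof),
                                            cadd=cadd, revel=revel, mvp=mvp))
        assert cat in ("hcLOF", "missC", "synonymous", "none")

    def test_vectorised_matches_scalar(self, tiny_cohort):
        v = classify_variants(tiny_cohort.variants)
        scalar = [variant_category(row) for _, row in
                  tiny_cohort.variants.iterrows()]
        assert list(v["category"]) == scalar
        scalar_rare = [is_rare(row) for _, row in
                       tiny_cohort.variants.iterrows()]
        assert list(v["rare"]) == scalar_rare


def auc_pair_oracle(scores, y):
    """Brute force over all (pathogenic, benign) pairs, ties count half."""
    pos = scores[y]
    neg = scores[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocMachinery:
    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n).round(1)  # induce ties
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            assert _auc(scores, y) == pytest.approx(
                auc_pair_oracle(scores, y), abs=1e-12)

    def test_perfect_separation(self):
        df = pd.DataFrame({
            "label": ["benign"] * 20 + ["pathogenic"] * 20,
            "gene_loeuf": [0.1, 0.5] * 20,
            "cadd": np.r_[np.zeros(20), np.ones(20) * 30.0],
        })
        rep, = select_score_thresholds(df, score_names=("cadd",))
        assert rep.auc_constrained == 1.0
        assert rep.auc_nonconstrained == 1.0
        assert rep.qualifies

    def test_null_labels_do_not_qualify(self):
        rng = np.random.default_rng(11)
        n = 2000
        df = pd.DataFrame({
            "label": rng.choice(["benign", "pathogenic"], size=n),
            "gene_loeuf": rng.choice([0.1, 0.6], size=n),
            "cadd": rng.normal(size=n),
        })
        rep, = select_score_thresholds(df, score_names=("cadd",))
        assert rep.auc_constrained == pytest.approx(0.5, abs=0.05)
        assert rep.auc_nonconstrained == pytest.approx(0.5, abs=0.05)
        assert not rep.qualifies

    def test_youden_threshold_equal_variance_gaussians(self):
        """For N(0,1) vs N(2,1) the J-optimal cut is the midpoint 1.0."""
        rng = np.random.default_rng(3)
        n = 5000
        scores = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        assert youden_threshold(scores, y) == pytest.approx(1.0, abs=0.15)

    def test_single_class_stratum_is_error(self):
        df = pd.DataFrame({
            "label": ["benign"] * 5 + ["pathogenic"] * 5,
            "gene_loeuf": [0.1] * 5 + [0.6] * 5,  # constrained all benign
            "cadd": np.arange(10.0),
        })
        with pytest.raises(ValueError, match="stratum"):
            select_score_thresholds(df, score_names=("cadd",))


class TestLabeledScoreSimulation:
    def test_strong_separation_qualifies_all_scores(self):
        df = simulate_labeled_scores(seed=4, n_per_class=2000, separation=3.0)
        reps = select_score_thresholds(df)
        assert {r.score_name for r in reps} == {"cadd", "revel", "mvp", "mpc"}
        for r in reps:
            assert r.qualifies, r
            assert min(r.auc_constrained, r.auc_nonconstrained) > 0.95

    def test_zero_separation_qualifies_nothing(self):
        df = simulate_labeled_scores(seed=4, n_per_class=2000, separation=0.0)
        for r in select_score_thresholds(df):
            assert not r.qualifies
            assert abs(r.auc_constrained - 0.5) < 0.06

    def test_rejects_empty_request(self):
        with pytest.raises(ValueError):
            simulate_labeled_scores(seed=1, n_per_class=0)
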