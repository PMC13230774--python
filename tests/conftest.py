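"""Shared fixtures: a hand-built miniature cohort and a simulated one."""

import numpy as np
import pandas as pd
import pytest

from chdburden.data_model import CohortDataset
from chdburden.simulate import PlantedEffect, SimulationConfig, simulate_cohort


def _variants():
    rows = [
        # qualifying hcLOF in GA
        ("1", 1000, "A", "T", "GA", "stop_gained", 1, 35.0, np.nan, np.nan,
         1e-5, 1e-5, np.nan, 0.0, 0.0),
        # qualifying missC in GA (CADD + REVEL pass)
        ("1", 2000, "C", "G", "GA", "missense", 0, 25.0, 0.61, 0.10,
         1e-5, 2e-4, 1e-4, np.nan, 0.0),
        # synonymous in GB (X-linked)
        ("X", 3000, "G", "A", "GB", "synonymous", 0, 2.0, np.nan, np.nan,
         1e-4, 5e-4, np.nan, np.nan, np.nan),
        # non-qualifying missense in GB (only one score passes)
        ("X", 4000, "T", "C", "GB", "missense", 0, 30.0, 0.40, 0.50,
         1e-5, 1e-5, 0.0, 0.0, 0.0),
    ]
    cols = ["chrom", "pos", "ref", "alt", "gene_id", "consequence", "lof_hc",
            "cadd", "revel", "mvp", "af_internal", "af_gnomad_exomes",
            "af_gnomad_genomes", "af_rumc", "af_inhouse"]
    v = pd.DataFrame(rows, columns=cols)
    v["variant_id"] = [f"{c}:{p}:{r}:{a}" for c, p, r, a in
                       zip(v.chrom, v.pos, v.ref, v.alt)]
    return v[["variant_id"] + cols]


def _samples():
    rows = [
        ("S1", "control", "female"), ("S2", "control", "male"),
        ("S3", "sCHD", "female"), ("S4", "sCHD", "male"),
        ("S5", "nsCHD", "female"), ("S6", "nsCHD", "male"),
    ]
    s = pd.DataFrame(rows, columns=["sample_id", "stratum", "sex"])
    rng = np.random.default_rng(1)
    for j in range(5):
        s[f"pc{j + 1}"] = rng.standard_normal(len(s))
    return s


def _genes():
    return pd.DataFrame({
        "gene_id": ["GA", "GB"],
        "symbol": ["GENEA", "GENEB"],
        "chrom": ["1", "X"],
        "loeuf": [0.10, 0.80],
        "moeuf": [0.50, 1.10],
    })


def _genotypes():
    rows = [
        # S3 (sCHD): QC-passing het at the hcLOF variant
        ("S3", "1:1000:A:T", "het", 30, 60, 0.5),
        # S3 also het at the missC variant (same gene, other category)
        ("S3", "1:2000:C:G", "het", 25, 50, 0.45),
        # S4 (sCHD, male): hemizygous at the X synonymous variant
        ("S4", "X:3000:G:A", "hemizygous", 40, 70, 1.0),
        # S1 (control): het at hcLOF but FAILS DP
        ("S1", "1:1000:A:T", "het", 9, 50, 0.5),
        # S5 (nsCHD): hom_alt at missC, passes (AB rule is het-only)
        ("S5", "1:2000:C:G", "hom_alt", 12, 20, 1.0),
        # S6 (nsCHD): het at non-qualifying missense, passes QC
        ("S6", "X:4000:T:C", "het", 50, 90, 0.4),
    ]
    return pd.DataFrame(rows, columns=["sample_id", "variant_id",
                                       "zygosity", "dp", "gq", "ab"])


@pytest.fixture
def tiny_cohort() -> CohortDataset:
    """Six samples, four variants, two genes — every edge by hand."""
    return CohortDataset(variants=_variants(), genotypes=_genotypes(),
                         samples=_samples(), genes=_genes()).validate()


@pytest.fixture(scope="session")
def null_sim_config() -> SimulationConfig:
    """Small cohort with no planted enrichment."""
    return SimulationConfig(seed=20260930, n_sCHD=250, n_nsCHD=350,
                            n_control=2500, n_genes=400, cluster_size=25)


@pytest.fixture(scope="session")
def null_cohort(null_sim_config) -> CohortDataset:
    return simulate_cohort(null_sim_config)


@pytest.fixture(scope="session")
def planted_sim_config() -> SimulationConfig:
    """Strong single-gene + cluster enrichment for recovery checks."""
    return SimulationConfig(
        seed=77, n_sCHD=600, n_nsCHD=700, n_control=6000, n_genes=400,
        cluster_size=25,
        planted=(PlantedEffect("G00007", "hcLOF", "sCHD", 20.0),
                 PlantedEffect("C14", "hcLOF", "sCHD", 3.0)))


@pytest.fixture(scope="session")
def planted_cohort(planted_sim_config) -> CohortDataset:
    return simulate_cohort(planted_sim_config)
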