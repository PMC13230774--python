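"""Negative-control calibration of the burden test statistics.

Burden p-values have no analytic guarantee of uniformity under real
cohort structure (ancestry mismatch, capture platform differences), so
the pipeline carries three diagnostics:

* genomic inflation **lambda_GC** — the median chi-square(1) quantile of
  the observed p-values over the null median 0.4549; and its rescaling
  **lambda_1000** to a reference study of 1000 cases / 1000 controls,
  which makes inflation comparable across cohort sizes;
* a **label-permutation null**: case/control labels are shuffled
  (stratum counts preserved) and the chosen test pipeline re-run, giving
  an empirical null distribution of lambda_GC;
* **MAF-stratified synonymous checks**: the synonymous-variant burden
  recomputed within allele-frequency bins, each with its own lambda_GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .burden import synonymous_burden
from .classify import CategoryConfig, classify_variants
from .data_model import CohortDataset

_CHI2_MEDIAN = chi2.ppf(0.5, df=1)  # 0.45494...


@dataclass
class CalibrationReport:
    lambda_gc: float
    lambda_1000: float
    n_case: int
    n_control: int
    qq_points: list[tuple[float, float]] = field(default_factory=list)
    permutation_lambdas: list[float] = field(default_factory=list)
    n_permutations: int = 0
    seed: int = 0

    @property
    def observed_percentile(self) -> float:
        """Empirical percentile of the observed lambda among permutations."""
        if not self.permutation_lambdas:
            return float("nan")
        arr = np.asarray(self.permutation_lambdas)
        return float(100.0 * np.mean(arr <= self.lambda_gc))

    def to_dict(self) -> dict:
        return {
            "lambda_gc": self.lambda_gc,
            "lambda_1000": self.lambda_1000,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "qq_points": [list(p) for p in self.qq_points],
            "permutation_lambdas": list(self.permutation_lambdas),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def lambda_gc(p_values) -> float:
    """Median-based genomic inflation factor.

    median(qchisq(1 - p, 1)) / qchisq(0.5, 1); equals 1 for uniform p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / _CHI2_MEDIAN)


def lambda_1000(lam: float, n_case: int, n_control: int) -> float:
    """Rescale lambda_GC to an equal-arm study of 1000/1000.

    lambda_1000 = 1 + (lambda - 1) * (1/n_case + 1/n_control) / (2/1000).
    Linear in lambda; fixed point at lambda = 1; identity when both arms
    are 1000.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if n_case < 1 or n_control < 1:
        raise ValueError("arm sizes must be >= 1")
    return 1.0 + (lam - 1.0) * (1.0 / n_case + 1.0 / n_control) / (2.0 / 1000)


def qq_points(p_values) -> list[tuple[float, float]]:
    """(expected, observed) -log10 p pairs; expected_i = -log10((i-.5)/n)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return list(zip(expected[::-1].tolist(), observed[::-1].tolist()))


def permute_labels(samples: pd.DataFrame, rng: np.random.Generator,
                   stratified: bool = True) -> pd.DataFrame:
    """Return samples with case/control labels permuted.

    Stratified mode (default, closer to the study design) preserves the
    exact control/sCHD/nsCHD counts by shuffling the stratum column as a
    multiset; non-stratified mode preserves only the total case count,
    reassigning case labels to the original sCHD/nsCHD mix at random.
    """
    out = samples.copy()
    strata = out["stratum"].to_numpy().copy()
    if stratified:
        rng.shuffle(strata)
        out["stratum"] = strata
    else:
        labels = np.where(strata == "control", "control", "case")
        rng.shuffle(labels)
        case_labels = strata[strata != "control"]
        rng.shuffle(case_labels)
        strata_new = np.asarray(labels, dtype=object)
        strata_new[labels == "case"] = case_labels
        out["stratum"] = strata_new
    return out


def permutation_null(ds: CohortDataset, test, n_perm: int, seed: int,
                     stratified: bool = True,
                     cfg: CategoryConfig = CategoryConfig(),
                     ) -> CalibrationReport:
    """Empirical null distribution of lambda_GC under label permutation.

    ``test`` maps a CohortDataset to a vector of p-values (e.g. the
    per-gene minimal P of the gene burden, or a gene-set battery's p
    column).  The observed lambda comes from the unpermuted dataset;
    each permutation shuffles the case/control labels (preserving
    stratum counts in stratified mode) and re-runs the identical test
    pipeline.  Fully reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed_p = np.asarray(test(ds), dtype=float)
    lam_obs = lambda_gc(observed_p)
    perm_lambdas = []
    for _ in range(n_perm):
        permuted = CohortDataset(variants=ds.variants,
                                 genotypes=ds.genotypes,
                                 samples=permute_labels(ds.samples, rng,
                                                        stratified),
                                 genes=ds.genes)
        perm_lambdas.append(lambda_gc(np.asarray(test(permuted),
                                                 dtype=float)))
    n_case = int((ds.samples["stratum"] != "control").sum())
    n_control = int((ds.samples["stratum"] == "control").sum())
    return CalibrationReport(
        lambda_gc=lam_obs,
        lambda_1000=lambda_1000(lam_obs, n_case, n_control),
        n_case=n_case, n_control=n_control,
        qq_points=qq_points(observed_p),
        permutation_lambdas=perm_lambdas,
        n_permutations=n_perm, seed=seed)


def maf_stratified_synonymous(ds: CohortDataset, maf_breaks,
                              cfg: CategoryConfig = CategoryConfig(),
                              ) -> pd.DataFrame:
    """lambda_GC of the synonymous burden within allele-frequency bins.

    ``maf_breaks`` is a strictly ascending break vector; bin i covers
    (break_i, break_{i+1}] except the first, which covers
    [break_0, break_1], so that the bins partition (0, rare_maf] when the
    breaks do.  A bin with no testable gene reports lambda = NaN.
    """
    breaks = np.asarray(maf_breaks, dtype=float)
    if breaks.size < 2 or (np.diff(breaks) <= 0).any():
        raise ValueError("maf_breaks must be strictly ascending, length >= 2")

    v = classify_variants(ds.variants, cfg)
    syn = v[(v["category"] == "synonymous") & v["rare"]].copy()
    af_cols = [c for c in v.columns if c.startswith("af_")]
    max_af = syn[af_cols].max(axis=1).fillna(0.0)

    rows = []
    for i in range(breaks.size - 1):
        lo, hi = breaks[i], breaks[i + 1]
        in_bin = (max_af > lo) & (max_af <= hi)
        if i == 0:
            in_bin |= max_af == lo
        sub_ids = set(syn.loc[in_bin, "variant_id"])
        sub = CohortDataset(
            variants=ds.variants[ds.variants["variant_id"].isin(sub_ids)],
            genotypes=ds.genotypes[ds.genotypes["variant_id"].isin(sub_ids)],
            samples=ds.samples, genes=ds.genes)
        lam = np.nan
        n_tested = 0
        if len(sub.variants):
            # every gene with >= 1 qualifying carrier is a performed test;
            # p = 1 rows (no case carriers) belong to the null distribution
            p = synonymous_burden(sub, cfg)["p"]
            n_tested = int(p.size)
            if n_tested:
                lam = lambda_gc(p)
        rows.append({"maf_low": lo, "maf_high": hi,
                     "n_variants": int(in_bin.sum()),
                     "n_tests": n_tested, "lambda_gc": lam})
    return pd.DataFrame(rows)
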