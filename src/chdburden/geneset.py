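"""Gene-set burden via MAC-aggregating logistic regression.

Each sample's exposure for a gene set is its Minimal Allele Count (MAC):
the sum of alternate-allele dosages (het = 1, hom_alt = 2, hemizygous = 1)
over QC-passing genotypes at rare variants of one category within the
set's genes.  Enrichment is tested by logistic regression of case/control
status on MAC with the first five ancestry principal components and sex
as covariates; the MAC coefficient's exp(beta) is the per-allele odds
ratio.

Gene sets come in two flavours: constraint decile bins (genes ranked by
LOEUF or MOEUF and cut into ten near-equal bins, bin 1 = most
constrained) and externally defined sets such as the fifteen embryonic
heart cell-cluster DEG lists (C0-C14).  Tests run per category x stratum
(aCHD pools the syndromic and non-syndromic cases) with per-category
Bonferroni over #sets x #strata (45 for 15 clusters x 3 strata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .burden import qualifying_genotypes
from .classify import CategoryConfig, TEST_CATEGORIES
from .data_model import CohortDataset, GeneSetCollection, PC_COLUMNS

GENESET_STRATA = ("aCHD", "sCHD", "nsCHD")

_DOSAGE = {"het": 1, "hom_alt": 2, "hemizygous": 1}


@dataclass(frozen=True)
class GenesetTestResult:
    """One logistic burden test: a gene set x case stratum x category."""

    set_label: str
    stratum: str
    category: str
    beta: float
    se: float
    p: float
    n_tests_family: int = 1
    converged: bool = True
    degenerate: bool = False
    quasi_separated: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - 1.96 * self.se)),
                float(np.exp(self.beta + 1.96 * self.se)))

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p * self.n_tests_family)


@dataclass(frozen=True)
class ConstraintBinning:
    metric: str
    n_bins: int
    assignment: dict[str, int] = field(default_factory=dict)

    def as_collection(self) -> GeneSetCollection:
        sets: dict[str, list[str]] = {f"bin_{i}": []
                                      for i in range(1, self.n_bins + 1)}
        for gene, b in self.assignment.items():
            sets[f"bin_{b}"].append(gene)
        for ids in sets.values():
            ids.sort()
        return GeneSetCollection(name=f"{self.metric}_bins", sets=sets)


def make_constraint_bins(genes: pd.DataFrame, metric: str = "loeuf",
                         n_bins: int = 10) -> ConstraintBinning:
    """Rank genes by a constraint metric and cut into near-equal bins.

    Bin 1 holds the lowest metric values (most constrained genes); ties
    break by gene_id so the partition is deterministic.  Bin sizes differ
    by at most one.  Genes lacking the metric are left unassigned.
    """
    if metric not in ("loeuf", "moeuf"):
        raise ValueError("metric must be 'loeuf' or 'moeuf'")
    scored = genes.loc[genes[metric].notna(), ["gene_id", metric]]
    if scored.empty:
        raise ValueError(f"no gene carries the {metric!r} metric")
    if len(scored) < n_bins:
        raise ValueError(f"need >= {n_bins} genes with {metric!r}")
    scored = scored.sort_values([metric, "gene_id"], kind="mergesort")
    # np.array_split yields sizes differing by at most one, larger first
    chunks = np.array_split(scored["gene_id"].to_numpy(), n_bins)
    assignment = {g: i + 1 for i, chunk in enumerate(chunks) for g in chunk}
    return ConstraintBinning(metric=metric, n_bins=n_bins,
                             assignment=assignment)


def mac_by_sample(qual: pd.DataFrame, gene_ids, category: str,
                  sample_ids) -> pd.Series:
    """MAC per sample over ``gene_ids`` for one category (vectorised)."""
    gene_ids = set(gene_ids)
    sub = qual[(qual["category"] == category) & qual["gene_id"].isin(gene_ids)]
    dosage = sub["zygosity"].map(_DOSAGE).fillna(0)
    mac = dosage.groupby(sub["sample_id"]).sum()
    return mac.reindex(sample_ids, fill_value=0).astype(float)


def per_sample_mac(ds: CohortDataset, sample_id: str,
                   gene_set, category: str,
                   cfg: CategoryConfig = CategoryConfig()) -> int:
    """MAC for a single sample (het = 1, hom_alt = 2, hemizygous = 1)."""
    if isinstance(gene_set, str):
        raise KeyError("gene_set must be an iterable of gene ids")
    qual = qualifying_genotypes(ds, cfg)
    return int(mac_by_sample(qual, gene_set, category, [sample_id]).iloc[0])


def _sex_numeric(sex: pd.Series) -> tuple[np.ndarray, bool]:
    """0/1 encoding; unknown sex imputed to the cohort majority."""
    known = sex[sex != "unknown"]
    majority = known.mode().iloc[0] if len(known) else "female"
    imputed = (sex == "unknown").any()
    filled = sex.replace("unknown", majority)
    return (filled == "male").to_numpy(dtype=float), bool(imputed)


def logistic_geneset_test(mac, status, covariates=None, *,
                          set_label: str = "", stratum: str = "",
                          category: str = "", n_tests_family: int = 1,
                          ) -> GenesetTestResult:
    """Wald test of the MAC coefficient in a covariate-adjusted logistic fit.

    ``status`` is the binary case indicator; ``covariates`` an optional
    (n, k) array (five PCs + sex in the standard battery).  Degenerate
    exposures (MAC constant across samples) and quasi-separation are
    flagged on the result instead of raising; a single-class response is
    an error.  Rank-deficient covariate columns are dropped with a
    warning.
    """
    mac = np.asarray(mac, dtype=float)
    y = np.asarray(status, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("response contains a single class")
    if np.ptp(mac) == 0:
        return GenesetTestResult(set_label=set_label, stratum=stratum,
                                 category=category, beta=np.nan, se=np.nan,
                                 p=1.0, n_tests_family=n_tests_family,
                                 converged=False, degenerate=True)

    X = [mac.reshape(-1, 1)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        keep: list[int] = []
        base = np.column_stack([np.ones(len(mac)), mac])
        for j in range(cov.shape[1]):
            trial = np.column_stack([base, cov[:, keep + [j]]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(j)
        if len(keep) < cov.shape[1]:
            warnings.warn(
                f"dropped {cov.shape[1] - len(keep)} rank-deficient "
                f"covariate column(s)", stacklevel=2)
        if keep:
            X.append(cov[:, keep])
    design = sm.add_constant(np.column_stack(X), has_constant="add")

    converged, quasi = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            return GenesetTestResult(set_label=set_label, stratum=stratum,
                                     category=category, beta=np.nan,
                                     se=np.nan, p=1.0,
                                     n_tests_family=n_tests_family,
                                     converged=False, quasi_separated=True)
    beta = float(fit.params[1])   # column 1: MAC (0 is the intercept)
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 50:
        quasi = True
    p = float(fit.pvalues[1]) if np.isfinite(se) else 1.0
    return GenesetTestResult(set_label=set_label, stratum=stratum,
                             category=category, beta=beta, se=se,
                             p=max(p, np.nextafter(0, 1)),
                             n_tests_family=n_tests_family,
                             converged=converged, quasi_separated=quasi)


def run_geneset_battery(ds: CohortDataset, sets: GeneSetCollection,
                        strata=GENESET_STRATA, categories=TEST_CATEGORIES,
                        cfg: CategoryConfig = CategoryConfig(),
                        n_tests_family: int | None = None) -> pd.DataFrame:
    """One logistic burden test per (set, stratum) within each category.

    The per-category Bonferroni family defaults to #sets x #strata (the
    0.05/45 rule for 15 clusters x 3 strata).  aCHD pools sCHD and nsCHD
    cases against the same controls.
    """
    family = n_tests_family or len(sets.sets) * len(strata)
    qual = qualifying_genotypes(ds, cfg)
    samples = ds.samples
    pcs = samples[list(PC_COLUMNS)].to_numpy(dtype=float)
    sex, _ = _sex_numeric(samples["sex"])
    covariates = np.column_stack([pcs, sex])
    is_control = (samples["stratum"] == "control").to_numpy()

    rows = []
    for category in categories:
        for label in sorted(sets.sets):
            mac_all = mac_by_sample(qual, sets.sets[label], category,
                                    samples["sample_id"]).to_numpy()
            for stratum in strata:
                if stratum == "aCHD":
                    is_case = samples["stratum"].isin(("sCHD", "nsCHD"))
                else:
                    is_case = samples["stratum"] == stratum
                mask = is_control | is_case.to_numpy()
                res = logistic_geneset_test(
                    mac_all[mask], is_case.to_numpy()[mask],
                    covariates[mask], set_label=label, stratum=stratum,
                    category=category, n_tests_family=family)
                rows.append({
                    "set_label": label, "stratum": stratum,
                    "category": category, "beta": res.beta, "se": res.se,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                    "p": res.p, "p_bonferroni": res.p_bonferroni,
                    "n_tests_family": family, "converged": res.converged,
                    "degenerate": res.degenerate,
                    "quasi_separated": res.quasi_separated,
                })
    return pd.DataFrame(rows)
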