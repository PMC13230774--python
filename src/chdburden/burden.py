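"""Per-gene case-control burden testing.

For every gene and each discovery category (hcLOF, missC) the pipeline
counts *carriers* — individuals with at least one QC-passing, rare,
qualifying genotype in the gene — in a case stratum (sCHD or nsCHD) and in
controls, and applies a one-sided Fisher exact test for enrichment in
cases.  The per-gene study-wide P is the minimum of the hcLOF and missC
p-values, and is corrected for multiple testing with a factor of
n_genes_tested x 2 categories (study value: 2 x 16,351 = 32,702), by
Bonferroni and by Benjamini-Hochberg step-up.

Genotype QC follows the high-confidence call rule: DP >= 10, GQ >= 20 and,
for heterozygous calls only, allelic balance strictly above 0.2.

Sidedness: the test is one-sided toward case enrichment, so a gene with no
case carriers has p = 1 by construction.  Carrier counting is
per-individual (never per-allele) and hemizygous male X genotypes count as
carriers, so X-linked genes are testable in males.

The BH scheme mirrors the study design: ranks are computed within each
case stratum's gene list, but the multiplier n stays at the full 32,702.
Genes whose category has no qualifying variants in either arm contribute
p = 1 and are excluded from the BH rank list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .classify import CategoryConfig, classify_variants
from .data_model import CohortDataset

CASE_STRATA = ("sCHD", "nsCHD")
DISCOVERY_CATEGORIES = ("hcLOF", "missC")


@dataclass(frozen=True)
class MultipleTestingConfig:
    """Correction family: genes tested x categories per gene."""

    n_genes_tested: int = 16351
    n_categories: int = 2
    alpha: float = 0.05

    @property
    def n_tests(self) -> int:
        return self.n_genes_tested * self.n_categories


def qc_genotype(call) -> bool:
    """High-confidence genotype rule: DP >= 10, GQ >= 20, het AB > 0.2."""
    zyg = call["zygosity"]
    if zyg in ("missing", "hom_ref"):
        return False
    if call["dp"] < 10 or call["gq"] < 20:
        return False
    if zyg == "het":
        ab = call["ab"]
        return not pd.isna(ab) and ab > 0.2
    return True


def qc_mask(genotypes: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`qc_genotype` over a genotype table."""
    zyg = genotypes["zygosity"]
    ok = (~zyg.isin(("missing", "hom_ref"))
          & (genotypes["dp"] >= 10) & (genotypes["gq"] >= 20))
    het = zyg == "het"
    ab_ok = genotypes["ab"].notna() & (genotypes["ab"] > 0.2)
    return (ok & (~het | ab_ok)).to_numpy()


def qualifying_genotypes(ds: CohortDataset,
                         cfg: CategoryConfig = CategoryConfig(),
                         classified: pd.DataFrame | None = None,
                         ) -> pd.DataFrame:
    """QC-passing genotypes at rare categorised variants.

    Returns one row per call with sample_id, gene_id, category, zygosity
    and the sample's stratum attached.  This is the shared substrate for
    carrier counting and for gene-set MAC aggregation.
    """
    v = classified if classified is not None else classify_variants(ds.variants, cfg)
    keep = v.loc[v["rare"] & (v["category"] != "none"),
                 ["variant_id", "gene_id", "category"]]
    gt = ds.genotypes[qc_mask(ds.genotypes)]
    merged = gt.merge(keep, on="variant_id", how="inner")
    strata = ds.samples.set_index("sample_id")["stratum"]
    merged = merged.assign(stratum=merged["sample_id"].map(strata))
    return merged


def count_carriers(ds: CohortDataset, gene_id: str, category: str,
                   stratum: str, cfg: CategoryConfig = CategoryConfig(),
                   ) -> int:
    """Carriers of >=1 qualifying variant of ``category`` in ``gene_id``
    within ``stratum``; each individual counted at most once."""
    if gene_id not in set(ds.genes["gene_id"]):
        raise KeyError(f"unknown gene_id {gene_id!r}")
    q = qualifying_genotypes(ds, cfg)
    sub = q[(q["gene_id"] == gene_id) & (q["category"] == category)
            & (q["stratum"] == stratum)]
    return int(sub["sample_id"].nunique())


def carrier_table(qual: pd.DataFrame) -> pd.DataFrame:
    """Unique carriers per (gene, category, stratum) from qualifying calls."""
    dedup = qual.drop_duplicates(["sample_id", "gene_id", "category"])
    counts = (dedup.groupby(["gene_id", "category", "stratum"], sort=True)
              .size().rename("n_carriers").reset_index())
    return counts


def fisher_burden(carriers_case: int, n_case: int,
                  carriers_ctrl: int, n_ctrl: int) -> float:
    """One-sided Fisher exact p for carrier enrichment in cases.

    The p-value is the upper hypergeometric tail
    P(X >= carriers_case | N, K, n_case) with K = total carriers; it
    equals 1 whenever there are no case carriers.
    """
    for name, val in (("carriers_case", carriers_case), ("n_case", n_case),
                      ("carriers_ctrl", carriers_ctrl), ("n_ctrl", n_ctrl)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if carriers_case > n_case or carriers_ctrl > n_ctrl:
        raise ValueError("carrier count exceeds stratum size")
    total_carriers = carriers_case + carriers_ctrl
    n_total = n_case + n_ctrl
    return float(hypergeom.sf(carriers_case - 1, n_total,
                              total_carriers, n_case))


def minimal_p(p_lof: float, p_miss: float) -> tuple[float, str]:
    """Study-wide per-gene P: minimum over categories, tie -> hcLOF."""
    if p_lof <= p_miss:
        return p_lof, "hcLOF"
    return p_miss, "missC"


def adjust_bonferroni(p_min: float,
                      cfg: MultipleTestingConfig = MultipleTestingConfig(),
                      ) -> float:
    """min(1, p x n_tests)."""
    return min(1.0, p_min * cfg.n_tests)


def adjust_bh(p_values,
              cfg: MultipleTestingConfig = MultipleTestingConfig(),
              ) -> np.ndarray:
    """Benjamini-Hochberg step-up with an externally fixed family size.

    For the vector of per-gene minimal P within one stratum, the gene at
    ascending rank i receives  min_{j >= i} min(1, p_(j) * n_tests / j).
    This is the standard step-up construction except that the multiplier
    n_tests is the full study family (32,702), not the vector length.
    Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, p.size + 1)
    scaled = np.minimum(1.0, p[order] * cfg.n_tests / ranks)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = stepped
    return out


def burden_from_counts(counts: pd.DataFrame,
                       mt_cfg: MultipleTestingConfig = MultipleTestingConfig(),
                       ) -> pd.DataFrame:
    """Fisher tests + corrections from a prepared carrier-count table.

    ``counts`` has one row per (gene_id, stratum) with columns
    carriers_case, n_case, carriers_ctrl_lof/miss ... — see
    :func:`run_gene_burden` for the end-to-end path.  Exposed separately
    so published carrier tables can be re-analysed directly.
    """
    rows = []
    for _, r in counts.iterrows():
        p_lof = fisher_burden(r["lof_case"], r["n_case"],
                              r["lof_ctrl"], r["n_ctrl"])
        p_miss = fisher_burden(r["miss_case"], r["n_case"],
                               r["miss_ctrl"], r["n_ctrl"])
        p_min, cat = minimal_p(p_lof, p_miss)
        rows.append({**r, "p_lof": p_lof, "p_miss": p_miss,
                     "p_min": p_min, "min_category": cat})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = [adjust_bonferroni(p, mt_cfg) for p in out["p_min"]]
    out["p_bh"] = np.nan
    for stratum, idx in out.groupby("stratum").groups.items():
        tested = out.loc[idx, "p_min"] < 1.0
        sub = out.loc[idx][tested]
        if len(sub):
            out.loc[sub.index, "p_bh"] = adjust_bh(sub["p_min"], mt_cfg)
        out.loc[out.loc[idx][~tested].index, "p_bh"] = 1.0
    return out


def _counts_frame(qual: pd.DataFrame, genes, ds: CohortDataset,
                  categories=DISCOVERY_CATEGORIES) -> pd.DataFrame:
    counts = carrier_table(qual)
    pivot = counts.pivot_table(index="gene_id", columns=["category", "stratum"],
                               values="n_carriers", fill_value=0,
                               aggfunc="sum")

    def get(gene, category, stratum):
        try:
            return int(pivot.loc[gene, (category, stratum)])
        except KeyError:
            return 0

    sizes = {s: ds.stratum_size(s) for s in (*CASE_STRATA, "control")}
    rows = []
    for stratum in CASE_STRATA:
        if sizes[stratum] == 0 or sizes["control"] == 0:
            raise ValueError(f"empty stratum: {stratum!r} or control")
        for gene in genes:
            rows.append({
                "gene_id": gene, "stratum": stratum,
                "lof_case": get(gene, categories[0], stratum),
                "lof_ctrl": get(gene, categories[0], "control"),
                "miss_case": get(gene, categories[1], stratum),
                "miss_ctrl": get(gene, categories[1], "control"),
                "n_case": sizes[stratum], "n_ctrl": sizes["control"],
            })
    return pd.DataFrame(rows)


def run_gene_burden(ds: CohortDataset,
                    cfg: CategoryConfig = CategoryConfig(),
                    mt_cfg: MultipleTestingConfig | None = None,
                    ) -> pd.DataFrame:
    """End-to-end per-gene burden: classify, QC, count, test, correct.

    Tests every gene with at least one qualifying hcLOF or missC carrier
    in either arm, for each case stratum vs controls.  When ``mt_cfg`` is
    None the correction family is sized from the data (tested genes x 2),
    the same construction the study applied at full scale.  Returns the
    discovery table only; the parallel synonymous negative-control
    p-values come from :func:`synonymous_burden` and are routed to the
    calibration module, never to the discovery table.
    """
    qual = qualifying_genotypes(ds, cfg)
    disc = qual[qual["category"].isin(DISCOVERY_CATEGORIES)]
    genes = sorted(disc["gene_id"].unique())
    if mt_cfg is None:
        mt_cfg = MultipleTestingConfig(n_genes_tested=max(len(genes), 1))
    counts = _counts_frame(disc, genes, ds)
    return burden_from_counts(counts, mt_cfg)


def synonymous_burden(ds: CohortDataset,
                      cfg: CategoryConfig = CategoryConfig(),
                      qual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene one-sided Fisher p for synonymous carriers (negative
    control; consumed by the calibration module, not the discovery table)."""
    if qual is None:
        qual = qualifying_genotypes(ds, cfg)
    syn = qual[qual["category"] == "synonymous"]
    genes = sorted(syn["gene_id"].unique())
    counts = carrier_table(syn)
    pivot = counts.pivot_table(index="gene_id", columns="stratum",
                               values="n_carriers", fill_value=0,
                               aggfunc="sum")
    sizes = {s: ds.stratum_size(s) for s in (*CASE_STRATA, "control")}
    rows = []
    for stratum in CASE_STRATA:
        for gene in genes:
            case = int(pivot.loc[gene, stratum]) if stratum in pivot.columns else 0
            ctrl = int(pivot.loc[gene, "control"]) if "control" in pivot.columns else 0
            rows.append({
                "gene_id": gene, "stratum": stratum,
                "carriers_case": case, "carriers_ctrl": ctrl,
                "p": fisher_burden(case, sizes[stratum], ctrl, sizes["control"]),
            })
    return pd.DataFrame(rows)


def recessive_burden(ds: CohortDataset,
                     cfg: CategoryConfig = CategoryConfig(),
                     mt_cfg: MultipleTestingConfig | None = None,
                     ) -> pd.DataFrame:
    """Recessive-model burden: homozygous or likely compound-het carriers.

    A recessive carrier has, within one gene, either >=1 QC-passing
    hom_alt rare protein-altering genotype, or >=2 distinct QC-passing
    rare het protein-altering variants (an unphased proxy for compound
    heterozygosity).  Protein-altering means the hcLOF or missC category.
    """
    qual = qualifying_genotypes(ds, cfg)
    pa = qual[qual["category"].isin(DISCOVERY_CATEGORIES)]
    hom = pa[pa["zygosity"].isin(("hom_alt", "hemizygous"))]
    hom_carriers = hom[["sample_id", "gene_id"]].drop_duplicates()
    het = pa[pa["zygosity"] == "het"]
    het_counts = (het.drop_duplicates(["sample_id", "gene_id", "variant_id"])
                  .groupby(["sample_id", "gene_id"]).size())
    comp_carriers = het_counts[het_counts >= 2].reset_index()[
        ["sample_id", "gene_id"]]
    carriers = pd.concat([hom_carriers, comp_carriers]).drop_duplicates()
    strata = ds.samples.set_index("sample_id")["stratum"]
    carriers = carriers.assign(stratum=carriers["sample_id"].map(strata))

    genes = sorted(carriers["gene_id"].unique())
    if mt_cfg is None:
        mt_cfg = MultipleTestingConfig(n_genes_tested=max(len(genes), 1),
                                       n_categories=1)
    counts = (carriers.groupby(["gene_id", "stratum"]).size()
              .rename("n").reset_index())
    pivot = counts.pivot_table(index="gene_id", columns="stratum", values="n",
                               fill_value=0, aggfunc="sum")
    sizes = {s: ds.stratum_size(s) for s in (*CASE_STRATA, "control")}
    rows = []
    for stratum in CASE_STRATA:
        for gene in genes:
            case = int(pivot.loc[gene, stratum]) if stratum in pivot.columns else 0
            ctrl = int(pivot.loc[gene, "control"]) if "control" in pivot.columns else 0
            rows.append({"gene_id": gene, "stratum": stratum,
                         "carriers_case": case, "carriers_ctrl": ctrl,
                         "n_case": sizes[stratum], "n_ctrl": sizes["control"],
                         "p_min": fisher_burden(case, sizes[stratum], ctrl,
                                                sizes["control"])})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_bonferroni"] = [adjust_bonferroni(p, mt_cfg) for p in out["p_min"]]
    out["p_bh"] = np.nan
    for stratum, idx in out.groupby("stratum").groups.items():
        tested = out.loc[idx, "p_min"] < 1.0
        sub = out.loc[idx][tested]
        if len(sub):
            out.loc[sub.index, "p_bh"] = adjust_bh(sub["p_min"], mt_cfg)
        out.loc[out.loc[idx][~tested].index, "p_bh"] = 1.0
    return out
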