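"""Variant categorisation: hcLOF, constrained missense (missC), synonymous.

The discovery categories are

* **hcLOF** — stop-gained, frameshift or essential-splice variants carrying
  a high-confidence loss-of-function flag from upstream LOFTEE-style
  annotation;
* **missC** — missense variants called likely deleterious by at least two
  of three ensemble scores at fixed thresholds (CADD >= 24, REVEL >= 0.5,
  MVP >= 0.8);
* **synonymous** — the negative-control category;
* everything else is ``none`` and takes no part in any test.

Rarity requires MAF < 0.001 in *every* allele-frequency source that reports
the variant (internal cohort frequency plus external reference panels); a
source that does not report the variant imposes no constraint.

The score thresholds themselves come from a ROC analysis of labelled
benign/pathogenic missense variants, stratified by gene LOF constraint
(LOEUF < 0.35 vs >= 0.35): a score qualifies if its AUC exceeds 0.9 in both
strata, and its working threshold is the Youden-optimal point on the pooled
set.  :func:`select_score_thresholds` reproduces that selection machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .data_model import AF_COLUMNS, LOF_CONSEQUENCES

CATEGORIES = ("hcLOF", "missC", "synonymous", "none")
TEST_CATEGORIES = ("hcLOF", "missC", "synonymous")


@dataclass(frozen=True)
class CategoryConfig:
    """Thresholds for the missC ensemble rule and the rarity filter."""

    cadd_threshold: float = 24.0
    revel_threshold: float = 0.5
    mvp_threshold: float = 0.8
    min_scores_passing: int = 2
    rare_maf: float = 0.001

    def __post_init__(self):
        if not (1 <= self.min_scores_passing <= 3):
            raise ValueError("min_scores_passing must be in 1..3")


def _get(variant, key):
    val = variant[key] if not hasattr(variant, "get") else variant.get(key)
    return val


def is_hclof(variant) -> bool:
    """High-confidence LOF: LOF consequence AND the high-confidence flag."""
    return (_get(variant, "consequence") in LOF_CONSEQUENCES
            and bool(_get(variant, "lof_hc")))


def is_missc(variant, cfg: CategoryConfig = CategoryConfig()) -> bool:
    """Constrained missense: >= ``min_scores_passing`` of the three scores
    at or above threshold.  A missing score counts as not passing."""
    if _get(variant, "consequence") != "missense":
        return False
    n_pass = 0
    for key, thr in (("cadd", cfg.cadd_threshold),
                     ("revel", cfg.revel_threshold),
                     ("mvp", cfg.mvp_threshold)):
        val = _get(variant, key)
        if val is not None and not pd.isna(val) and val >= thr:
            n_pass += 1
    return n_pass >= cfg.min_scores_passing


def is_rare(variant, cfg: CategoryConfig = CategoryConfig()) -> bool:
    """Rare iff every reported AF source is below ``rare_maf``."""
    for col in AF_COLUMNS:
        val = _get(variant, col)
        if val is not None and not pd.isna(val) and val >= cfg.rare_maf:
            return False
    return True


def variant_category(variant, cfg: CategoryConfig = CategoryConfig()) -> str:
    """Mutually exclusive category, severity-ordered: hcLOF beats missC."""
    if is_hclof(variant):
        return "hcLOF"
    if is_missc(variant, cfg):
        return "missC"
    if _get(variant, "consequence") == "synonymous":
        return "synonymous"
    return "none"


def classify_variants(variants: pd.DataFrame,
                      cfg: CategoryConfig = CategoryConfig()) -> pd.DataFrame:
    """Vectorised categorisation + rarity over a variant table.

    Returns a copy with ``category`` and ``rare`` columns appended.
    """
    v = variants.copy()
    lof = v["consequence"].isin(LOF_CONSEQUENCES) & v["lof_hc"].astype(bool)
    n_pass = (
        (v["cadd"] >= cfg.cadd_threshold).fillna(False).astype(int)
        + (v["revel"] >= cfg.revel_threshold).fillna(False).astype(int)
        + (v["mvp"] >= cfg.mvp_threshold).fillna(False).astype(int)
    )
    missc = (v["consequence"] == "missense") & (n_pass >= cfg.min_scores_passing)
    category = np.where(
        lof, "hcLOF",
        np.where(missc, "missC",
                 np.where(v["consequence"] == "synonymous",
                          "synonymous", "none")))
    v["category"] = category

    rare = np.ones(len(v), dtype=bool)
    for col in AF_COLUMNS:
        af = v[col]
        rare &= (af.isna() | (af < cfg.rare_maf)).to_numpy()
    v["rare"] = rare
    return v


# ---------------------------------------------------------------------------
# ROC-based score threshold selection


@dataclass(frozen=True)
class ScoreThresholdReport:
    """Per-score selection outcome.

    ``qualifies`` is true iff AUC > 0.9 in both the constrained
    (LOEUF < 0.35) and non-constrained (LOEUF >= 0.35) gene strata; the
    ``threshold`` maximises Youden's J on the pooled labelled set.
    """

    score_name: str
    auc_constrained: float
    auc_nonconstrained: float
    qualifies: bool = field(init=False)
    threshold: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "qualifies",
            min(self.auc_constrained, self.auc_nonconstrained) > 0.9)


LOEUF_CONSTRAINED_CUTOFF = 0.35


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC (ties by midrank) — identical to the Mann-Whitney
    pair-ordering probability."""
    return float(roc_auc_score(y, scores))


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1.

    Candidate thresholds are the observed score values (a variant is
    called pathogenic when its score >= threshold).  Ties on J resolve to
    the smallest qualifying threshold, for determinism.
    """
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    j = tpr - fpr
    best = j.max()
    candidates = thresholds[np.isclose(j, best)]
    finite = candidates[np.isfinite(candidates)]
    return float(finite.min()) if finite.size else float(candidates.min())


def select_score_thresholds(labeled: pd.DataFrame,
                            score_names=("cadd", "revel", "mvp", "mpc"),
                            ) -> list[ScoreThresholdReport]:
    """Reproduce the ensemble-score selection step.

    ``labeled`` has one row per labelled missense variant with columns
    ``label`` (benign / pathogenic), ``gene_loeuf`` and one column per
    score.  Scores absent from the table are skipped.  Each score is
    evaluated by AUC within the constrained and non-constrained gene
    strata; a stratum containing a single class is an error.
    """
    y = (labeled["label"] == "pathogenic").to_numpy()
    constrained = (labeled["gene_loeuf"] < LOEUF_CONSTRAINED_CUTOFF).to_numpy()
    for name, mask in (("constrained", constrained),
                       ("non-constrained", ~constrained)):
        cls = np.unique(y[mask])
        if cls.size < 2:
            raise ValueError(
                f"stratum {name!r} contains a single label class; "
                "AUC is undefined")

    reports = []
    for score in score_names:
        if score not in labeled.columns:
            continue
        s = labeled[score].to_numpy(dtype=float)
        ok = ~np.isnan(s)
        reports.append(ScoreThresholdReport(
            score_name=score,
            auc_constrained=_auc(s[ok & constrained], y[ok & constrained]),
            auc_nonconstrained=_auc(s[ok & ~constrained], y[ok & ~constrained]),
            threshold=youden_threshold(s[ok], y[ok]),
        ))
    return reports
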