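"""Synthetic case-control cohort generator.

Generates fully in-silico cohorts carrying the statistical structure the
burden analyses assume — constraint-binned genes, rare variants with
score triplets and multi-source allele frequencies, sparse genotype
calls with sequencing-quality fields, and case/control strata with
ancestry PCs — so the whole pipeline is testable without any
access-controlled download.

Default sizes are the study conditions this package models: 1818
syndromic and 2929 non-syndromic cases against 52,881 controls, over
19,923 protein-coding genes, a per-gene per-category baseline carrier
rate of 1e-3, and the MAF < 0.001 rarity regime.  Tests and examples run
the same generator at smaller sizes.

Enrichment is planted on *carrier probability at the gene level*: for a
planted (target, category, stratum, OR), each targeted gene's per-sample
carrier probability in that stratum's cases is the baseline rate shifted
by ln(OR) on the log-odds scale.  Targets are a gene id, a LOEUF decile
bin label (``bin_1`` .. ``bin_10``, computed from the generated LOEUF
values), or a DEG cell-cluster label (``C0`` .. ``C14``); a cluster
target resolves to a dedicated random gene set which
:func:`simulate_deg_clusters` then reports as that cluster's DEG list.
Non-planted clusters are drawn from genes carrying no planted effect, so
with no planted overlap the cluster battery is null-calibrated.

All randomness flows from the mandatory config seed through named
``numpy`` SeedSequence children, so the gene/variant/cluster scaffold is
bit-reproducible on its own — the cluster collection regenerated from a
config always matches the cohort generated from the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CohortDataset, GeneSetCollection, make_variant_id
from .geneset import make_constraint_bins

AUTOSOMES = [str(c) for c in range(1, 23)]

# SeedSequence child indices: the scaffold streams (genes, variants,
# clusters) must not depend on the sample/genotype streams
_STREAM_GENES, _STREAM_VARIANTS, _STREAM_CLUSTERS = 0, 1, 2
_STREAM_SAMPLES, _STREAM_GENOTYPES = 3, 4


@dataclass(frozen=True)
class PlantedEffect:
    """Carrier-probability enrichment for one (target, category, stratum).

    ``stratum`` is sCHD, nsCHD or aCHD (aCHD applies to every case).
    """

    target: str
    category: str
    stratum: str
    odds_ratio: float

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.stratum not in ("sCHD", "nsCHD", "aCHD"):
            raise ValueError(f"unknown stratum {self.stratum!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; the seed is mandatory."""

    seed: int
    n_sCHD: int = 1818
    n_nsCHD: int = 2929
    n_control: int = 52881
    n_genes: int = 19923
    baseline_carrier_rate: float = 1e-3
    # rare synonymous variation is roughly an order of magnitude more
    # abundant per gene than qualifying hcLOF/missC sites; its carrier
    # rate also sets the granularity of the negative-control null
    synonymous_carrier_rate: float = 0.05
    planted: tuple[PlantedEffect, ...] = ()
    # constraint model: LOEUF/MOEUF ~ log-normal (gnomAD-like spread)
    loeuf_mu: float = -0.35
    loeuf_sigma: float = 0.6
    moeuf_mu: float = -0.1
    moeuf_sigma: float = 0.4
    frac_x_genes: float = 0.03
    # variant model
    n_rare_per_gene_category: int = 3
    common_variant_fraction: float = 0.1
    rare_maf: float = 0.001
    af_missing_rate: float = 0.2
    lof_flag_rate: float = 0.85
    # genotype noise: DP ~ NB, GQ ~ discretised Gaussian, het AB ~ Beta
    dp_mean: float = 40.0
    dp_dispersion: float = 5.0
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    ab_alpha: float = 20.0
    ab_beta: float = 20.0
    hom_rate: float = 0.01
    second_hit_rate: float = 0.01
    # DEG clusters; deg_overlap plants (cluster_label, n_genes) overlap
    # between a named cluster and the genes carrying planted effects
    n_clusters: int = 15
    cluster_size: int = 100
    deg_overlap: tuple[tuple[str, int], ...] = ()
    # covariates
    pc1_case_shift: float = 0.0  # confounding mode when non-zero
    frac_male: float = 0.5

    def __post_init__(self):
        for name in ("baseline_carrier_rate", "synonymous_carrier_rate",
                     "common_variant_fraction",
                     "af_missing_rate", "lof_flag_rate", "hom_rate",
                     "second_hit_rate", "frac_x_genes", "frac_male"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_sCHD", "n_nsCHD", "n_control", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


def study_preset(seed: int, **overrides) -> SimulationConfig:
    """The study-mirroring preset: hcLOF enrichment in the most
    LOF-constrained decile, stronger in syndromic than non-syndromic
    cases (planted ORs 2.27 / 1.52)."""
    cfg = SimulationConfig(
        seed=seed,
        planted=(PlantedEffect("bin_1", "hcLOF", "sCHD", 2.27),
                 PlantedEffect("bin_1", "hcLOF", "nsCHD", 1.52)),
    )
    return cfg.scaled(**overrides) if overrides else cfg


def _streams(cfg: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def _simulate_genes(cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    ids = np.array([f"G{i:05d}" for i in range(n)])
    loeuf = rng.lognormal(cfg.loeuf_mu, cfg.loeuf_sigma, size=n)
    # MOEUF correlated with LOEUF (constrained genes tend to be both)
    moeuf = np.exp(cfg.moeuf_mu
                   + 0.5 * (np.log(loeuf) - cfg.loeuf_mu)
                   + cfg.moeuf_sigma * rng.standard_normal(n))
    chrom = rng.choice(AUTOSOMES, size=n)
    x_mask = rng.random(n) < cfg.frac_x_genes
    chrom = np.where(x_mask, "X", chrom)
    return pd.DataFrame({
        "gene_id": ids,
        "symbol": np.char.add("SYM", ids.astype(str)),
        "chrom": chrom,
        "loeuf": loeuf,
        "moeuf": moeuf,
    })


def _rare_afs(rng, n, cfg):
    """Multi-source AFs all below rare_maf; some sources missing."""
    out = {}
    for src in ("internal", "gnomad_exomes", "gnomad_genomes", "rumc",
                "inhouse"):
        vals = rng.uniform(0.0, 0.8 * cfg.rare_maf, size=n)
        miss = rng.random(n) < cfg.af_missing_rate
        out[f"af_{src}"] = np.where(miss, np.nan, vals)
    return out


def _simulate_variants(cfg: SimulationConfig, genes: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Variant scaffold: per gene, rare sites for each category plus a
    non-qualifying missense; a fraction of extra common sites."""
    frames = []
    n_genes = len(genes)
    k = cfg.n_rare_per_gene_category

    def base(n, gene_idx, kind):
        g = genes.iloc[gene_idx]
        pos = rng.integers(1, 200_000_000, size=n)
        bases = np.array(list("ACGT"))
        ref_idx = rng.integers(0, 4, size=n)
        shift = rng.integers(1, 4, size=n)
        ref = bases[ref_idx]
        alt = bases[(ref_idx + shift) % 4]
        return pd.DataFrame({
            "chrom": g["chrom"].to_numpy(),
            "pos": pos,
            "ref": ref, "alt": alt,
            "gene_id": g["gene_id"].to_numpy(),
            "_kind": kind,
        })

    idx_all = np.repeat(np.arange(n_genes), k)

    # intended hcLOF sites
    v = base(len(idx_all), idx_all, "hcLOF")
    v["consequence"] = rng.choice(
        ["stop_gained", "frameshift", "essential_splice"], size=len(v))
    v["lof_hc"] = (rng.random(len(v)) < cfg.lof_flag_rate).astype(int)
    v["cadd"] = np.nan
    v["revel"] = np.nan
    v["mvp"] = np.nan
    frames.append(v)

    # intended missC sites: scores guarantee >= 2 of 3 thresholds
    v = base(len(idx_all), idx_all, "missC")
    v["consequence"] = "missense"
    v["lof_hc"] = 0
    v["cadd"] = rng.uniform(24.0, 45.0, size=len(v))
    v["revel"] = rng.uniform(0.5, 1.0, size=len(v))
    v["mvp"] = rng.uniform(0.0, 1.0, size=len(v))
    frames.append(v)

    # synonymous sites
    v = base(len(idx_all), idx_all, "synonymous")
    v["consequence"] = "synonymous"
    v["lof_hc"] = 0
    v["cadd"] = rng.uniform(0.0, 10.0, size=len(v))
    v["revel"] = np.nan
    v["mvp"] = np.nan
    frames.append(v)

    # non-qualifying missense background (at most one score passes)
    idx_one = np.arange(n_genes)
    v = base(len(idx_one), idx_one, "none")
    v["consequence"] = "missense"
    v["lof_hc"] = 0
    v["cadd"] = rng.uniform(0.0, 23.9, size=len(v))
    v["revel"] = rng.uniform(0.0, 0.49, size=len(v))
    v["mvp"] = rng.uniform(0.0, 1.0, size=len(v))
    frames.append(v)

    variants = pd.concat(frames, ignore_index=True)
    for col, vals in _rare_afs(rng, len(variants), cfg).items():
        variants[col] = vals

    # common-site mixture component: AF above the rarity threshold
    n_common = int(round(cfg.common_variant_fraction * len(variants)
                         / max(1e-12, 1 - cfg.common_variant_fraction)))
    if n_common:
        gi = rng.integers(0, n_genes, size=n_common)
        v = base(n_common, gi, "common")
        v["consequence"] = rng.choice(["missense", "synonymous"],
                                      size=n_common)
        v["lof_hc"] = 0
        v["cadd"] = rng.uniform(0.0, 30.0, size=n_common)
        v["revel"] = rng.uniform(0.0, 1.0, size=n_common)
        v["mvp"] = rng.uniform(0.0, 1.0, size=n_common)
        for col, vals in _rare_afs(rng, n_common, cfg).items():
            v[col] = vals
        v["af_gnomad_exomes"] = rng.uniform(cfg.rare_maf, 0.05,
                                            size=n_common)
        variants = pd.concat([variants, v], ignore_index=True)

    variants["variant_id"] = [
        make_variant_id(c, p, r, a)
        for c, p, r, a in zip(variants["chrom"], variants["pos"],
                              variants["ref"], variants["alt"])]
    variants = variants.drop_duplicates("variant_id").reset_index(drop=True)
    return variants


def _resolve_targets(cfg: SimulationConfig, genes: pd.DataFrame,
                     rng_clusters: np.random.Generator,
                     ) -> tuple[dict[str, list[str]], GeneSetCollection]:
    """Resolve planted targets to gene lists and build the DEG clusters.

    Returns (target -> gene list, cluster collection).  Cluster-label
    targets get dedicated gene sets sampled from genes not already
    carrying a planted effect; non-planted clusters avoid all
    effect-carrying genes so the battery is null-calibrated outside the
    planted combinations.
    """
    cluster_labels = [f"C{i}" for i in range(cfg.n_clusters)]
    gene_ids = genes["gene_id"].to_numpy()
    bins = None
    resolved: dict[str, list[str]] = {}

    gene_targets = set()
    for eff in cfg.planted:
        t = eff.target
        if t in resolved:
            continue
        if t.startswith("bin_") or t.startswith("mbin_"):
            metric = "moeuf" if t.startswith("mbin_") else "loeuf"
            if bins is None or bins.metric != metric:
                bins = make_constraint_bins(genes, metric=metric, n_bins=10)
            b = int(t.split("_")[1])
            resolved[t] = sorted(g for g, i in bins.assignment.items()
                                 if i == b)
        elif t in cluster_labels:
            continue  # resolved below, after gene/bin targets are known
        elif t in set(gene_ids):
            resolved[t] = [t]
        else:
            raise KeyError(f"planted target {t!r} not found")
        gene_targets.update(resolved[t])

    # dedicated gene sets for cluster targets, disjoint from other targets
    free = np.array(sorted(set(gene_ids) - gene_targets))
    for eff in cfg.planted:
        t = eff.target
        if t in cluster_labels and t not in resolved:
            size = min(cfg.cluster_size, len(free))
            pick = rng_clusters.choice(free, size=size, replace=False)
            resolved[t] = sorted(pick)
            gene_targets.update(resolved[t])
            free = np.array(sorted(set(free) - set(pick)))

    # non-planted clusters sample from effect-free genes; overlap
    # clusters mix planted risk genes with neutral filler
    overlap = dict(cfg.deg_overlap)
    for label in overlap:
        if label not in cluster_labels:
            raise KeyError(f"deg_overlap names unknown cluster {label!r}")
    neutral_pool = np.array(sorted(set(gene_ids) - gene_targets))
    effect_pool = np.array(sorted(gene_targets))
    sets = {}
    for label in cluster_labels:
        if label in resolved:
            sets[label] = list(resolved[label])
        elif label in overlap:
            n_risk = min(overlap[label], len(effect_pool))
            risk = rng_clusters.choice(effect_pool, size=n_risk,
                                       replace=False)
            n_fill = min(cfg.cluster_size - n_risk, len(neutral_pool))
            fill = rng_clusters.choice(neutral_pool, size=n_fill,
                                       replace=False)
            sets[label] = sorted(np.concatenate([risk, fill]))
        else:
            size = min(cfg.cluster_size, len(neutral_pool))
            sets[label] = sorted(rng_clusters.choice(
                neutral_pool, size=size, replace=False))
    clusters = GeneSetCollection(name="deg_clusters", sets=sets)
    return resolved, clusters


def _scaffold(cfg: SimulationConfig):
    streams = _streams(cfg)
    genes = _simulate_genes(cfg, streams[_STREAM_GENES])
    variants = _simulate_variants(cfg, genes, streams[_STREAM_VARIANTS])
    resolved, clusters = _resolve_targets(cfg, genes,
                                          streams[_STREAM_CLUSTERS])
    return streams, genes, variants, resolved, clusters


def simulate_deg_clusters(cfg: SimulationConfig) -> GeneSetCollection:
    """The 15 cell-cluster DEG sets consistent with :func:`simulate_cohort`.

    Regenerated from the config seed alone, so the collection always
    matches the cohort simulated from the same config.
    """
    _, _, _, _, clusters = _scaffold(cfg)
    return clusters


def _carrier_prob(base: float, odds_ratio: float) -> float:
    logit = np.log(base / (1 - base)) + np.log(odds_ratio)
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_cohort(cfg: SimulationConfig) -> CohortDataset:
    """Generate a full validated cohort (see module docstring)."""
    streams, genes, variants, resolved, _ = _scaffold(cfg)
    rng_s = streams[_STREAM_SAMPLES]
    rng_g = streams[_STREAM_GENOTYPES]

    # ----- samples ---------------------------------------------------
    strata = np.concatenate([
        np.repeat("control", cfg.n_control),
        np.repeat("sCHD", cfg.n_sCHD),
        np.repeat("nsCHD", cfg.n_nsCHD)])
    n_samples = strata.size
    sample_ids = np.array([f"S{i:06d}" for i in range(n_samples)])
    sex = np.where(rng_s.random(n_samples) < cfg.frac_male, "male", "female")
    pcs = rng_s.standard_normal((n_samples, 5))
    if cfg.pc1_case_shift:
        pcs[:, 0] += np.where(strata == "control", 0.0, cfg.pc1_case_shift)
    samples = pd.DataFrame({"sample_id": sample_ids, "stratum": strata,
                            "sex": sex})
    for j in range(5):
        samples[f"pc{j + 1}"] = pcs[:, j]

    # ----- per-(gene, category, stratum) carrier probabilities -------
    gene_ids = genes["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    categories = ("hcLOF", "missC", "synonymous")
    base_rate = {c: (cfg.synonymous_carrier_rate if c == "synonymous"
                     else cfg.baseline_carrier_rate) for c in categories}
    prob = {(c, s): np.full(len(gene_ids), base_rate[c])
            for c in categories for s in ("control", "sCHD", "nsCHD")}
    for eff in cfg.planted:
        target_genes = resolved[eff.target]
        idx = [gene_pos[g] for g in target_genes]
        strata_hit = (("sCHD", "nsCHD") if eff.stratum == "aCHD"
                      else (eff.stratum,))
        for s in strata_hit:
            prob[(eff.category, s)][idx] = _carrier_prob(
                base_rate[eff.category], eff.odds_ratio)

    # rare qualifying variant ids per (gene, category), by intent
    rare_sites: dict[tuple[str, str], np.ndarray] = {}
    vsub = variants[variants["_kind"].isin(categories)]
    for (g, c), grp in vsub.groupby(["gene_id", "_kind"], sort=False):
        rare_sites[(g, c)] = grp["variant_id"].to_numpy()

    male_mask = sex == "male"
    x_gene_mask = (genes["chrom"] == "X").to_numpy()

    stratum_idx = {s: np.flatnonzero(strata == s)
                   for s in ("control", "sCHD", "nsCHD")}

    # vectorised per gene: draw the carrier count, pick carriers, assign
    # each a qualifying site (an occasional unphased second het models
    # compound heterozygosity; hom_alt and X-male hemizygosity likewise)
    parts_sample, parts_variant, parts_zyg = [], [], []
    for c in categories:
        for s, s_idx in stratum_idx.items():
            if s_idx.size == 0:
                continue
            counts = rng_g.binomial(s_idx.size, prob[(c, s)])
            for gi in np.flatnonzero(counts):
                sites = rare_sites.get((gene_ids[gi], c))
                if sites is None or sites.size == 0:
                    continue
                m = int(counts[gi])
                carriers = rng_g.choice(s_idx, size=m, replace=False)
                first = rng_g.integers(0, sites.size, size=m)
                second = ((rng_g.random(m) < cfg.second_hit_rate)
                          & (sites.size > 1))
                hom = (rng_g.random(m) < cfg.hom_rate) & ~second
                hemi = x_gene_mask[gi] & male_mask[carriers]
                parts_sample.append(sample_ids[carriers])
                parts_variant.append(sites[first])
                parts_zyg.append(np.where(hemi, "hemizygous",
                                          np.where(hom, "hom_alt", "het")))
                if second.any():
                    i2 = np.flatnonzero(second)
                    offset = 1 + rng_g.integers(0, sites.size - 1,
                                                size=i2.size)
                    parts_sample.append(sample_ids[carriers[i2]])
                    parts_variant.append(sites[(first[i2] + offset)
                                               % sites.size])
                    parts_zyg.append(np.where(hemi[i2], "hemizygous",
                                              "het"))

    if parts_sample:
        rows_sample = np.concatenate(parts_sample)
        rows_variant = np.concatenate(parts_variant)
        rows_zyg = np.concatenate(parts_zyg)
    else:
        rows_sample = rows_variant = rows_zyg = np.array([], dtype=object)
    n_calls = len(rows_sample)
    dp = rng_g.negative_binomial(
        cfg.dp_dispersion,
        cfg.dp_dispersion / (cfg.dp_dispersion + cfg.dp_mean),
        size=n_calls)
    gq = np.clip(np.round(rng_g.normal(cfg.gq_mean, cfg.gq_sd,
                                       size=n_calls)), 0, 99).astype(int)
    ab = rng_g.beta(cfg.ab_alpha, cfg.ab_beta, size=n_calls)
    genotypes = pd.DataFrame({
        "sample_id": rows_sample,
        "variant_id": rows_variant,
        "zygosity": rows_zyg,
        "dp": dp.astype(int),
        "gq": gq,
        "ab": ab,
    })
    # AB is only meaningful for heterozygous calls
    genotypes.loc[genotypes["zygosity"] != "het", "ab"] = 1.0
    genotypes = genotypes.drop_duplicates(["sample_id", "variant_id"])
    genotypes = genotypes.reset_index(drop=True)

    variants = variants.drop(columns=["_kind"])
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "gene_id",
            "consequence", "lof_hc", "cadd", "revel", "mvp",
            "af_internal", "af_gnomad_exomes", "af_gnomad_genomes",
            "af_rumc", "af_inhouse"]
    ds = CohortDataset(variants=variants[cols], genotypes=genotypes,
                       samples=samples, genes=genes)
    return ds.validate()


# ---------------------------------------------------------------------------
# synthetic bulk developmental expression


def simulate_expression(seed: int, gene_ids, tissues=("heart", "kidney",
                                                      "brain", "liver"),
                        stages=(4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0),
                        shifted_genes=(), shift_tissues=(),
                        log_shift: float = 1.0) -> pd.DataFrame:
    """Long-format RPKM table over tissues x developmental stages.

    Expression is log-normal per gene with a gene-specific baseline
    shared across tissues plus independent tissue/stage noise.  Genes in
    ``shifted_genes`` get ``log_shift`` added on the log scale in
    ``shift_tissues`` only — the planted pattern for set-comparison
    recovery checks.  Stages beyond 8 weeks post conception fall outside
    the default early-window analysis.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    shifted = set(shifted_genes)
    baseline = rng.normal(1.0, 1.0, size=len(gene_ids))
    rows = []
    for t in tissues:
        tissue_effect = rng.normal(0.0, 0.3)
        for stage in stages:
            noise = rng.normal(0.0, 0.5, size=len(gene_ids))
            logx = baseline + tissue_effect + noise
            if t in set(shift_tissues):
                logx = logx + np.array([log_shift if g in shifted else 0.0
                                        for g in gene_ids])
            for g, v in zip(gene_ids, np.exp(logx)):
                rows.append((g, t, stage, v))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "stage",
                                       "rpkm"])


# ---------------------------------------------------------------------------
# labelled benign/pathogenic score sets for threshold selection


def simulate_labeled_scores(seed: int, n_per_class: int = 2000,
                            separation: float = 3.0,
                            score_noise: float = 0.3) -> pd.DataFrame:
    """Labelled missense score table for threshold-selection tests.

    Pathogenic variants share a latent deleteriousness z ~ N(separation,
    1), benign z ~ N(0, 1); each score is an affine transform of z plus
    independent N(0, score_noise) noise, mapped onto its natural scale.
    Gene LOEUF spans both constraint strata.  With separation d' and
    noise tau, each score's AUC is Phi(d' / sqrt(2 (1 + tau^2))).
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be > 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat(["benign", "pathogenic"], n_per_class)
    z = rng.standard_normal(n) + np.where(y == "pathogenic", separation, 0.0)

    def score(a, b, lo=None, hi=None):
        s = a + b * (z + score_noise * rng.standard_normal(n))
        if lo is not None:
            s = np.clip(s, lo, hi)
        return s

    loeuf = np.exp(rng.uniform(np.log(0.03), np.log(2.0), size=n))
    df = pd.DataFrame({
        "label": y,
        "gene_loeuf": loeuf,
        "cadd": score(18.0, 4.0),
        "revel": score(0.35, 0.10, 0.0, 1.0),
        "mvp": score(0.55, 0.18, 0.0, 1.0),
        "mpc": score(1.0, 0.5),
    })
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                     ).reset_index(drop=True)
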