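"""Core domain model: cohort containers, validation, and tabular I/O.

A cohort is held as four pandas DataFrames (variants, genotypes, samples,
genes) wrapped in :class:`CohortDataset`.  Coordinates follow the 1-based
VCF convention.  Genotype storage is sparse: only non-reference calls are
stored and absence of a row means homozygous reference — at the rare allele
frequencies this pipeline targets (MAF < 0.001) dense storage would be
overwhelmingly zeros.

Missing scores and missing allele frequencies are kept as NaN, never
coerced to 0: a variant without a REVEL score is *unscored*, which is a
different thing from a variant scored benign, and downstream
classification rules state their own missing-value semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONSEQUENCES = (
    "stop_gained",
    "frameshift",
    "essential_splice",
    "missense",
    "synonymous",
    "other",
)
LOF_CONSEQUENCES = ("stop_gained", "frameshift", "essential_splice")
ZYGOSITIES = ("hom_ref", "het", "hom_alt", "hemizygous", "missing")
STRATA = ("control", "sCHD", "nsCHD")
SEXES = ("female", "male", "unknown")
AF_SOURCES = ("internal", "gnomad_exomes", "gnomad_genomes", "rumc", "inhouse")

AF_COLUMNS = tuple(f"af_{s}" for s in AF_SOURCES)
PC_COLUMNS = ("pc1", "pc2", "pc3", "pc4", "pc5")

VARIANT_COLUMNS = (
    "variant_id", "chrom", "pos", "ref", "alt", "gene_id", "consequence",
    "lof_hc", "cadd", "revel", "mvp", *AF_COLUMNS,
)
GENOTYPE_COLUMNS = ("sample_id", "variant_id", "zygosity", "dp", "gq", "ab")
SAMPLE_COLUMNS = ("sample_id", "stratum", "sex", *PC_COLUMNS)
GENE_COLUMNS = ("gene_id", "symbol", "chrom", "loeuf", "moeuf")


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def make_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class CohortDataset:
    """A validated case-control cohort.

    Attributes
    ----------
    variants : DataFrame indexed 0..n with columns VARIANT_COLUMNS.
    genotypes : DataFrame of non-hom_ref calls (sparse convention).
    samples : DataFrame with stratum / sex / five ancestry PCs.
    genes : DataFrame with LOEUF / MOEUF constraint metrics.
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def validate(self) -> "CohortDataset":
        _check_columns(self.variants, VARIANT_COLUMNS, "variants")
        _check_columns(self.genotypes, GENOTYPE_COLUMNS, "genotypes")
        _check_columns(self.samples, SAMPLE_COLUMNS, "samples")
        _check_columns(self.genes, GENE_COLUMNS, "genes")
        _validate_variants(self.variants)
        _validate_samples(self.samples)
        _validate_genes(self.genes)
        _validate_genotypes(self.genotypes, self.variants, self.samples)
        return self

    def stratum_ids(self, stratum: str) -> pd.Index:
        if stratum == "aCHD":
            mask = self.samples["stratum"].isin(("sCHD", "nsCHD"))
        else:
            mask = self.samples["stratum"] == stratum
        return pd.Index(self.samples.loc[mask, "sample_id"])

    def stratum_size(self, stratum: str) -> int:
        return len(self.stratum_ids(stratum))


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _fail(name: str, idx, msg: str) -> None:
    raise ValidationError(f"{name} [record {idx}]: {msg}")


def _validate_variants(v: pd.DataFrame) -> None:
    if (v["pos"] < 1).any():
        _fail("variants", v.index[v["pos"] < 1][0], "pos must be >= 1")
    same = v["ref"] == v["alt"]
    if same.any():
        _fail("variants", v.index[same][0], "ref must differ from alt")
    bad_csq = ~v["consequence"].isin(CONSEQUENCES)
    if bad_csq.any():
        _fail("variants", v.index[bad_csq][0],
              f"consequence not in {CONSEQUENCES}")
    for col in AF_COLUMNS:
        af = v[col]
        bad = af.notna() & ((af < 0) | (af > 1))
        if bad.any():
            _fail("variants", v.index[bad][0],
                  f"allele frequency {col} outside [0, 1]")
    for col, lo, hi in (("cadd", 0, np.inf), ("revel", 0, 1), ("mvp", 0, 1)):
        s = v[col]
        bad = s.notna() & ((s < lo) | (s > hi))
        if bad.any():
            _fail("variants", v.index[bad][0], f"score {col} out of range")
    # the high-confidence LOF flag only makes sense on LOF consequences
    bad_flag = v["lof_hc"].astype(bool) & ~v["consequence"].isin(LOF_CONSEQUENCES)
    if bad_flag.any():
        _fail("variants", v.index[bad_flag][0],
              "lof_hc set on a non-LOF consequence")
    dup = v["variant_id"].duplicated()
    if dup.any():
        _fail("variants", v.loc[dup, "variant_id"].iloc[0],
              "duplicate variant_id")


def _validate_samples(s: pd.DataFrame) -> None:
    bad = ~s["stratum"].isin(STRATA)
    if bad.any():
        _fail("samples", s.index[bad][0], f"stratum not in {STRATA}")
    bad = ~s["sex"].isin(SEXES)
    if bad.any():
        _fail("samples", s.index[bad][0], f"sex not in {SEXES}")
    pcs = s[list(PC_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(pcs).all():
        _fail("samples", s.index[~np.isfinite(pcs).all(axis=1)][0],
              "ancestry PCs must be finite")
    dup = s["sample_id"].duplicated()
    if dup.any():
        _fail("samples", s.loc[dup, "sample_id"].iloc[0],
              "duplicate sample_id")


def _validate_genes(g: pd.DataFrame) -> None:
    dup = g["gene_id"].duplicated()
    if dup.any():
        _fail("genes", g.loc[dup, "gene_id"].iloc[0], "duplicate gene_id")
    for col in ("loeuf", "moeuf"):
        s = g[col]
        bad = s.notna() & ((s <= 0) | ~np.isfinite(s))
        if bad.any():
            _fail("genes", g.index[bad][0], f"{col} must be finite and > 0")


def _validate_genotypes(gt: pd.DataFrame, v: pd.DataFrame,
                        s: pd.DataFrame) -> None:
    bad = ~gt["zygosity"].isin(ZYGOSITIES)
    if bad.any():
        _fail("genotypes", gt.index[bad][0], f"zygosity not in {ZYGOSITIES}")
    ab = gt["ab"]
    bad = ab.notna() & ((ab < 0) | (ab > 1))
    if bad.any():
        _fail("genotypes", gt.index[bad][0], "allelic balance outside [0, 1]")
    if (gt["dp"] < 0).any() or (gt["gq"] < 0).any():
        _fail("genotypes", gt.index[(gt["dp"] < 0) | (gt["gq"] < 0)][0],
              "dp and gq must be >= 0")
    unknown_v = ~gt["variant_id"].isin(set(v["variant_id"]))
    if unknown_v.any():
        _fail("genotypes", gt.loc[unknown_v, "variant_id"].iloc[0],
              "genotype references unknown variant_id")
    unknown_s = ~gt["sample_id"].isin(set(s["sample_id"]))
    if unknown_s.any():
        _fail("genotypes", gt.loc[unknown_s, "sample_id"].iloc[0],
              "genotype references unknown sample_id")
    dup = gt.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        pair = gt.loc[dup, ["sample_id", "variant_id"]].iloc[0].tolist()
        _fail("genotypes", tuple(pair), "duplicate (sample_id, variant_id)")


# ---------------------------------------------------------------------------
# tabular I/O


def _read_tsv(path, name: str, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_columns(df, [c for c in required if c not in ("variant_id",)], name)
    return df


def read_cohort(paths: Mapping[str, str | Path]) -> CohortDataset:
    """Read a cohort from the TSV bundle and validate every invariant.

    ``paths`` maps ``{"variants", "genotypes", "samples", "genes"}`` to file
    paths.  Variant identity is reconstructed as ``chrom:pos:ref:alt``.
    """
    for key in ("variants", "genotypes", "samples", "genes"):
        if key not in paths:
            raise SchemaError(f"paths missing entry for '{key}'")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])

    variants = _read_tsv(paths["variants"], "variants", VARIANT_COLUMNS)
    variants["variant_id"] = [
        make_variant_id(c, p, r, a)
        for c, p, r, a in zip(variants["chrom"], variants["pos"],
                              variants["ref"], variants["alt"])
    ]
    variants["lof_hc"] = variants["lof_hc"].fillna(0).astype(int)

    genotypes = _read_tsv(paths["genotypes"], "genotypes",
                          ("sample_id", "chrom", "pos", "ref", "alt",
                           "zygosity", "dp", "gq", "ab"))
    genotypes["variant_id"] = [
        make_variant_id(c, p, r, a)
        for c, p, r, a in zip(genotypes["chrom"], genotypes["pos"],
                              genotypes["ref"], genotypes["alt"])
    ]
    genotypes = genotypes[list(GENOTYPE_COLUMNS)]

    samples = _read_tsv(paths["samples"], "samples", SAMPLE_COLUMNS)
    genes = _read_tsv(paths["genes"], "genes", GENE_COLUMNS)

    ds = CohortDataset(variants=variants[list(VARIANT_COLUMNS)],
                       genotypes=genotypes, samples=samples, genes=genes)
    return ds.validate()


def write_cohort(ds: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV bundle with deterministic (sorted) row order.

    Round-trip stability: ``write_cohort(read_cohort(x))`` is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    v = ds.variants.sort_values(["chrom", "pos", "ref", "alt"],
                                kind="mergesort")
    v = v.drop(columns=["variant_id"])
    paths["variants"] = out / "variants.tsv"
    v.to_csv(paths["variants"], sep="\t", index=False, float_format="%.6g")

    key = ds.variants.set_index("variant_id")[["chrom", "pos", "ref", "alt"]]
    gt = ds.genotypes.join(key, on="variant_id")
    gt = gt[["sample_id", "chrom", "pos", "ref", "alt",
             "zygosity", "dp", "gq", "ab"]]
    gt = gt.sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                        kind="mergesort")
    paths["genotypes"] = out / "genotypes.tsv"
    gt.to_csv(paths["genotypes"], sep="\t", index=False, float_format="%.6g")

    s = ds.samples.sort_values("sample_id", kind="mergesort")
    paths["samples"] = out / "samples.tsv"
    s.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")

    g = ds.genes.sort_values("gene_id", kind="mergesort")
    paths["genes"] = out / "genes.tsv"
    g.to_csv(paths["genes"], sep="\t", index=False, float_format="%.6g")
    return paths


@dataclass
class GeneSetCollection:
    """Named collection of labelled gene sets (bins, cell clusters, ...)."""

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def restrict_to(self, known_genes) -> "GeneSetCollection":
        """Drop gene ids not present in the gene table (logged, not fatal)."""
        known = set(known_genes)
        kept = {}
        for label, ids in self.sets.items():
            resolvable = [g for g in ids if g in known]
            dropped = len(ids) - len(resolvable)
            if dropped:
                warnings.warn(
                    f"gene set {label!r}: dropped {dropped} unresolvable "
                    f"gene id(s)", stacklevel=2)
            kept[label] = resolvable
        return GeneSetCollection(name=self.name, sets=kept)


def read_genesets(path: str | Path, name: str = "genesets",
                  known_genes=None) -> GeneSetCollection:
    """Read long-format gene sets (columns: set_label, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ("set_label", "gene_id"), "genesets")
    sets: dict[str, list[str]] = {}
    for label, sub in df.groupby("set_label", sort=True):
        sets[str(label)] = sub["gene_id"].astype(str).tolist()
    coll = GeneSetCollection(name=name, sets=sets)
    if known_genes is not None:
        coll = coll.restrict_to(known_genes)
    return coll


def write_genesets(coll: GeneSetCollection, path: str | Path) -> None:
    rows = [(label, g) for label in sorted(coll.sets) for g in coll.sets[label]]
    pd.DataFrame(rows, columns=["set_label", "gene_id"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF import

_DEFAULT_FIELD_MAP = {
    "consequence": "CSQ_CONSEQUENCE",
    "lof_hc": "LOF_HC",
    "gene_id": "GENE",
    "cadd": "CADD_PHRED",
    "revel": "REVEL",
    "mvp": "MVP",
    "af_internal": "AF_INTERNAL",
    "af_gnomad_exomes": "AF_GNOMAD_EX",
    "af_gnomad_genomes": "AF_GNOMAD_WG",
    "af_rumc": "AF_RUMC",
    "af_inhouse": "AF_INHOUSE",
}

X_CHROMS = {"X", "chrX"}


def import_vcf(vcf_path: str | Path, field_map: Mapping[str, str] | None = None,
               male_samples: set[str] | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Import annotated variants and genotype calls from a VCF.

    ``field_map`` maps domain fields (consequence, lof_hc, gene_id, scores,
    AF sources) to INFO field names; per-allele INFO values (Number=A) are
    split across alternate alleles.  A missing mapped field produces a
    warning and NaN, not a crash.  AB is taken from the FORMAT/AD pair when
    available (alt depth over total depth); unparseable genotypes become
    ``missing``.  Male genotypes on the X chromosome are imported as
    hemizygous (``male_samples`` supplies the sample ids).
    """
    import pysam

    fmap = dict(_DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    male_samples = male_samples or set()

    vf = pysam.VariantFile(str(vcf_path))
    info_keys = set(vf.header.info.keys())
    warned: set[str] = set()

    def info_value(rec, domain_field, alt_index, n_alts):
        name = fmap[domain_field]
        if name not in info_keys or name not in rec.info:
            if name not in warned and name not in info_keys:
                warnings.warn(f"VCF lacks mapped INFO field {name!r}; "
                              f"{domain_field} set to missing", stacklevel=2)
                warned.add(name)
            return None
        val = rec.info[name]
        if isinstance(val, tuple):
            # Number=A annotation: one value per alternate allele
            if len(val) == n_alts:
                return val[alt_index]
            return val[0] if val else None
        return val

    var_rows, gt_rows = [], []
    for rec in vf:
        alts = rec.alts or ()
        n_alts = len(alts)
        for ai, alt in enumerate(alts):
            csq = info_value(rec, "consequence", ai, n_alts)
            lof = info_value(rec, "lof_hc", ai, n_alts)
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "variant_id": make_variant_id(rec.chrom, rec.pos, rec.ref, alt),
                "gene_id": info_value(rec, "gene_id", ai, n_alts),
                "consequence": csq if csq in CONSEQUENCES else "other",
                "lof_hc": int(bool(int(lof))) if lof is not None else 0,
            }
            for fld in ("cadd", "revel", "mvp", *AF_COLUMNS):
                val = info_value(rec, fld, ai, n_alts)
                row[fld] = float(val) if val is not None else np.nan
            var_rows.append(row)

        allele_idx = 1 + np.arange(n_alts)
        for sample_id, call in rec.samples.items():
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            alleles = [a for a in gt if a is not None]
            for ai in range(n_alts):
                alt_allele = int(allele_idx[ai])
                n_alt = sum(a == alt_allele for a in alleles)
                if n_alt == 0:
                    continue  # hom_ref w.r.t. this alt: not stored
                if len(alleles) < len(gt):
                    zyg = "missing"
                elif len(alleles) == 1:
                    zyg = ("hemizygous" if sample_id in male_samples
                           and rec.chrom in X_CHROMS else "hom_alt"
                           if n_alt == 1 else "missing")
                elif n_alt == len(alleles):
                    zyg = ("hemizygous" if sample_id in male_samples
                           and rec.chrom in X_CHROMS else "hom_alt")
                else:
                    zyg = "het"
                dp = call.get("DP")
                gq = call.get("GQ")
                ad = call.get("AD")
                ab = np.nan
                if ad is not None and len(ad) > alt_allele and ad[0] is not None:
                    total = sum(x for x in ad if x is not None)
                    if total > 0:
                        ab = ad[alt_allele] / total
                gt_rows.append({
                    "sample_id": sample_id,
                    "variant_id": make_variant_id(rec.chrom, rec.pos,
                                                  rec.ref, alts[ai]),
                    "zygosity": zyg,
                    "dp": int(dp) if dp is not None else 0,
                    "gq": int(gq) if gq is not None else 0,
                    "ab": ab,
                })

    variants = pd.DataFrame(var_rows, columns=list(VARIANT_COLUMNS))
    genotypes = pd.DataFrame(gt_rows, columns=list(GENOTYPE_COLUMNS))
    return variants, genotypes
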