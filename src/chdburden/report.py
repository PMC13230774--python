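"""Figure and table outputs: Manhattan-style plots, summary tables.

Numbers are printed in 3-significant-digit scientific notation (e.g.
``9.76E-13``), the convention of published burden tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def sci(x: float) -> str:
    """3-significant-digit scientific notation, upper-case E."""
    if pd.isna(x):
        raise ValueError("cannot format NaN")
    return f"{x:.2E}"


def manhattan_plot(burden_results: pd.DataFrame, out_path: str | Path,
                   threshold_bonferroni: float | None = None,
                   threshold_fdr: float | None = None,
                   genes: pd.DataFrame | None = None) -> Path:
    """-log10 minimal P per gene along the genome.

    ``burden_results`` needs gene_id, p_min and either chrom (+ optional
    pos) columns or a ``genes`` table to join them from.  Two horizontal
    reference lines mark the Bonferroni and FDR-5% cutoffs expressed on
    the raw-P scale.  Genes without coordinates are dropped with a
    warning; an empty result set is an error.
    """
    df = burden_results.copy()
    if "chrom" not in df.columns:
        if genes is None:
            raise ValueError("results lack 'chrom'; pass the gene table")
        df = df.merge(genes[["gene_id", "chrom"]], on="gene_id", how="left")
    if "pos" not in df.columns:
        # deterministic fallback layout: alphabetical within chromosome
        df["pos"] = df.groupby("chrom")["gene_id"].rank(method="first")
    missing = df["chrom"].isna()
    if missing.any():
        import warnings
        warnings.warn(f"dropped {int(missing.sum())} gene(s) without "
                      "coordinates", stacklevel=2)
        df = df[~missing]
    if df.empty:
        raise ValueError("no plottable results")

    df["_corder"] = df["chrom"].map(CHROM_ORDER).fillna(99)
    df = df.sort_values(["_corder", "pos", "gene_id"],
                        kind="mergesort").reset_index(drop=True)
    df["_x"] = np.arange(len(df))

    fig, ax = plt.subplots(figsize=(10, 4))
    for i, (_, sub) in enumerate(df.groupby("_corder", sort=True)):
        ax.scatter(sub["_x"], -np.log10(sub["p_min"]), s=8,
                   color="C0" if i % 2 == 0 else "C1")
    for thr, style, label in ((threshold_bonferroni, "r--", "Bonferroni"),
                              (threshold_fdr, "k:", "FDR 5%")):
        if thr is not None:
            ax.axhline(-np.log10(thr), ls=style[1:], color=style[0],
                       label=label)
    ticks = df.groupby("chrom", sort=False)["_x"].mean()
    ax.set_xticks(ticks.to_numpy(), ticks.index, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}$ minimal $P$")
    if threshold_bonferroni is not None or threshold_fdr is not None:
        ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def fdr_threshold_raw_p(results: pd.DataFrame, alpha: float = 0.05,
                        ) -> float | None:
    """Largest raw minimal P whose BH-adjusted value is below alpha."""
    hits = results.loc[results["p_bh"] < alpha, "p_min"]
    return float(hits.max()) if len(hits) else None


def report_tables(out_dir: str | Path,
                  gene_results: pd.DataFrame | None = None,
                  geneset_results: pd.DataFrame | None = None,
                  calibration: dict | None = None) -> dict[str, Path]:
    """Write the summary bundle: top-gene table (sorted by minimal P),
    gene-set OR table, calibration JSON.  Deterministic: identical
    inputs yield identical files."""
    if gene_results is None and geneset_results is None and calibration is None:
        raise ValueError("no analysis results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if gene_results is not None:
        df = gene_results.copy()
        if df["p_min"].isna().any():
            raise ValueError("gene results contain NaN p-values")
        df = df.sort_values(["p_min", "gene_id"], kind="mergesort")
        for col in ("p_lof", "p_miss", "p_min", "p_bh", "p_bonferroni"):
            if col in df.columns:
                df[col] = df[col].map(sci)
        path = out / "burden_results.tsv"
        df.to_csv(path, sep="\t", index=False)
        written["gene"] = path

    if geneset_results is not None:
        df = geneset_results.copy()
        if df["p"].isna().any():
            raise ValueError("gene-set results contain NaN p-values")
        for col in ("p", "p_bonferroni"):
            df[col] = df[col].map(sci)
        for col in ("beta", "se", "odds_ratio", "ci_low", "ci_high"):
            if col in df.columns:
                df[col] = df[col].map(lambda x: f"{x:.3f}")
        path = out / "geneset_results.tsv"
        df.to_csv(path, sep="\t", index=False)
        written["geneset"] = path

    if calibration is not None:
        path = out / "calibration_report.json"
        path.write_text(json.dumps(calibration, indent=2, sort_keys=True))
        written["calibration"] = path
    return written
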