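"""Simulate the working case-control cohort and write its TSV bundle.

Emits the four cohort tables (variants, genotypes, samples, genes), the
DEG cluster sets, and the resolved simulation config next to them.
"""

import dataclasses

import yaml

from chdburden.data_model import write_genesets
from chdburden.simulate import simulate_cohort, simulate_deg_clusters
from chdburden.data_model import write_cohort
from common import parse_args, working_config


def main():
    args = parse_args(__doc__)
    cfg = working_config(args.seed)
    out = args.out / "cohort"
    ds = simulate_cohort(cfg)
    paths = write_cohort(ds, out)
    write_genesets(simulate_deg_clusters(cfg), out / "deg_clusters.tsv")

    resolved = dataclasses.asdict(cfg)
    resolved["planted"] = [dataclasses.asdict(e) for e in cfg.planted]
    (out / "config.yaml").write_text(yaml.safe_dump(resolved))

    n_case = (ds.samples["stratum"] != "control").sum()
    print(f"cohort: {len(ds.samples)} samples ({n_case} cases), "
          f"{len(ds.variants)} variants, {len(ds.genotypes)} genotype rows")
    for k, p in paths.items():
        print(f"  wrote {p}")


if __name__ == "__main__":
    main()
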