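"""Shared setup for the analysis drivers: the working cohort definition.

The working cohort is a scaled-down rendition of the study conditions:
case/control arms in the same ~1:4.4 imbalance, a thousand genes in ten
LOEUF deciles, hcLOF enrichment planted in the most constrained decile
(OR 2.27 syndromic / 1.52 non-syndromic) and DEG cluster C14 overlapping
the constrained risk genes.  Scripts re-simulate deterministically from
the seed, so they can run independently and in any order.
"""

from pathlib import Path

from chdburden.simulate import (PlantedEffect, SimulationConfig,
                                simulate_cohort)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def working_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_sCHD=1200, n_nsCHD=1500, n_control=12_000,
        n_genes=1000, cluster_size=100,
        planted=(PlantedEffect("bin_1", "hcLOF", "sCHD", 2.27),
                 PlantedEffect("bin_1", "hcLOF", "nsCHD", 1.52)),
        deg_overlap=(("C14", 50),))


def working_cohort(seed: int = 1):
    return simulate_cohort(working_config(seed))


def parse_args(description: str):
    import argparse
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=RESULTS)
    return ap.parse_args()
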