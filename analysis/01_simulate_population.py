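#!/usr/bin/env python
"""Simulate the study-style population and write it to results/simdata/.

Conditions: 20 clonal parents selfed with ~62% true selfing (the rest
pollen contamination), 1-33 seed per parent, ~10k SNPs with LD on 11
chromosomes, a DBH-like trait (mean 12.25 cm, SD 4.18 cm, h2 = 0.4 plus
a small dominance share) on a 30-block RCBD, and 62 genotyped but
unphenotyped "orchard" individuals.
"""

import sys
from pathlib import Path

from selfpred.simdata import SimConfig, simulate_population, write_population

OUT = Path("results/simdata")


def main(seed: int = 1):
    cfg = SimConfig(seed=seed)
    geno, ped, pheno, truth = simulate_population(cfg)
    write_population(OUT, geno, ped, pheno, truth, cfg)
    off = ped.table[ped.table["cohort"] != "founder"]
    n_selfed = int((off["sire"] == off["dam"]).sum())
    print(f"simulated {geno.n_individuals} individuals x {geno.n_markers} markers")
    print(f"  offspring: {len(off)} ({n_selfed} truly selfed, "
          f"{100 * n_selfed / len(off):.1f}%)")
    print(f"  phenotyped field trees: {len(pheno)}; orchard: {len(truth.orchard_ids)}")
    print(f"  trait: mean {pheno['dbh_cm'].mean():.2f} cm, SD {pheno['dbh_cm'].std():.2f} cm")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
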