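"""Generate the synthetic mixed-ploid study panel.

Emulates the study design: 6 genotypes x 3 RNA-Seq replicates, ~4 SNPs per
transcript, per-call ploidy drawn from a 6..14 spectrum with a dodecaploid
mode, 10% of heterozygous SNP x genotype pairs carrying a true logit-scale
expression shift of 1.5.  Writes the dosage VCF, allele-count table, ground
truth and gene/GO maps under results/fixture/.

Run from the repository root: python analysis/01_simulate_panel.py [seed]
"""

import sys
from pathlib import Path

from polyase import SimConfig, simulate_fixture

OUT = Path("results/fixture")


def main(seed: int = 2022) -> None:
    cfg = SimConfig(seed=seed)
    calls, counts, truth = simulate_fixture(cfg, OUT)
    het = truth[(truth["alpha"] >= 1) & (truth["beta"] >= 1)]
    print(f"panel: {calls.groupby(['transcript', 'position']).ngroups} sites x "
          f"{calls['genotype'].nunique()} genotypes -> {len(calls)} calls")
    print(f"heterozygous calls: {len(het)} ({len(het) / len(truth):.1%} of non-missing); "
          f"true-ASE pairs: {int(het['is_ase_truth'].sum())}")
    print(f"fixture written to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2022)
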