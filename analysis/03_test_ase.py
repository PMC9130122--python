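"""Run the Beta-Binomial HDI test on every testable unit.

Posterior Beta(alpha + sum y, beta + sum(n - y)) per unit; ASE when the
genomic ratio P = alpha/(alpha+beta) falls outside the HDI at credibility
mass 1 - 0.05/1000 = 0.99995.  Writes results/snp_results.tsv and
results/gene_summaries.tsv and reports detection against the simulated truth.
"""

from pathlib import Path

import pandas as pd

from polyase import aggregate_genes, tally_ase, test_units
from polyase import io as pio

KEY = ["transcript", "position", "genotype"]


def main() -> None:
    units = pio.read_units("results/units.tsv")
    results = test_units(units, zeta=0.05, n_tests=1000)
    tx2gene, _ = pio.read_gene_maps("results/fixture/gene_map.tsv", "results/fixture/go_map.tsv")
    genes = aggregate_genes(results, tx2gene)
    tallies = tally_ase(results, genes)
    pio.write_results(results, genes, tallies, "results")
    print(tallies.to_string(index=False))

    truth = pd.read_csv("results/fixture/truth.tsv", sep="\t")
    merged = results.merge(truth[KEY + ["is_ase_truth"]], on=KEY)
    tp = int((merged["is_ase"] & merged["is_ase_truth"]).sum())
    fp = int((merged["is_ase"] & ~merged["is_ase_truth"]).sum())
    recall = tp / max(int(merged["is_ase_truth"].sum()), 1)
    print(f"vs truth: {tp} true positives, {fp} false positives, recall {recall:.3f}")


if __name__ == "__main__":
    main()
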