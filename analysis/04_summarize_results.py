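"""Cross-genotype summaries: ASEG intersections, GO frequencies, clustering.

Writes results/intersections.tsv (exclusive subset counts, UpSet-style),
results/go_frequency*.tsv, results/distances.tsv and results/tree.nwk
(average-linkage dendrogram of genotypes from per-SNP reference-allele
expression fractions).
"""

from pathlib import Path

import pandas as pd

from polyase import dissimilarity_cluster, go_frequency, intersect_asegs
from polyase import io as pio

OUT = Path("results")


def main() -> None:
    results = pd.read_csv(OUT / "snp_results.tsv", sep="\t")
    genes = pd.read_csv(OUT / "gene_summaries.tsv", sep="\t")
    _, go = pio.read_gene_maps("results/fixture/gene_map.tsv", "results/fixture/go_map.tsv")

    inter = intersect_asegs(genes)
    inter.exclusive.to_csv(OUT / "intersections.tsv", sep="\t", index=False)
    exclusive = inter.exclusive.query("degree == 1")["n_exclusive_asegs"].sum()
    union = inter.exclusive["n_exclusive_asegs"].sum()
    print(f"ASEG union: {union}; exclusive to a single genotype: {exclusive} "
          f"({exclusive / max(union, 1):.0%})")

    per_geno, shared = go_frequency(genes, go)
    per_geno.to_csv(OUT / "go_frequency.tsv", sep="\t", index=False)
    shared.to_csv(OUT / "go_frequency_shared.tsv", sep="\t", index=False)

    for kind, subset, tag in [("relative_expression", "all", "expr_all"),
                              ("relative_expression", "ase_only", "expr_ase"),
                              ("relative_dosage", "all", "dose_all")]:
        dist, newick = dissimilarity_cluster(results, kind, subset)
        dist.to_csv(OUT / f"distances_{tag}.tsv", sep="\t", float_format="%.8g")
        (OUT / f"tree_{tag}.nwk").write_text(newick + "\n")
    print("distance matrices and dendrograms written (expr_all, expr_ase, dose_all)")


if __name__ == "__main__":
    main()
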