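"""Descriptive layers over the per-SNP ASE results.

Per-genotype tallies, UpSet-style exclusive intersections of ASEG sets,
per-gene SNP views (relative dosage vs relative expression), genotype
dissimilarity clustering, GO-term ASEG frequencies, and hypergeometric GO
enrichment with Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from skbio.tree import TreeNode
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tally_ase",
    "IntersectionTable",
    "intersect_asegs",
    "snp_view",
    "dissimilarity_cluster",
    "go_frequency",
    "enrich",
]

_MAX_INTERSECTION_GENOTYPES = 10


def tally_ase(results: pd.DataFrame, gene_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype counts of tested SNPs, ASE-SNPs, tested genes and ASEGs."""
    genotypes = sorted(set(results["genotype"]) | set(gene_summaries["genotype"]))
    rows = []
    for g in genotypes:
        snp = results[results["genotype"] == g]
        gene = gene_summaries[gene_summaries["genotype"] == g]
        n_snps, n_ase = len(snp), int(snp["is_ase"].sum())
        n_genes, n_asegs = len(gene), int(gene["is_aseg"].sum())
        rows.append(
            {
                "genotype": g,
                "n_snps_tested": n_snps,
                "n_ase_snps": n_ase,
                "prop_ase_snps": n_ase / n_snps if n_snps else 0.0,
                "n_genes_tested": n_genes,
                "n_asegs": n_asegs,
                "prop_asegs": n_asegs / n_genes if n_genes else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntersectionTable:
    """Exclusive ASEG intersection counts plus per-genotype totals.

    ``exclusive`` has one row per non-empty genotype subset with the number
    of ASEGs found in exactly that subset; rows with zero genes are kept so
    the partition over 2^K - 1 subsets is explicit.  The exclusive counts sum
    to the size of the union of the ASEG sets.
    """

    exclusive: pd.DataFrame
    totals: pd.DataFrame


def intersect_asegs(gene_summaries: pd.DataFrame) -> IntersectionTable:
    """Partition the union of per-genotype ASEG sets by exact membership subset."""
    genotypes = sorted(gene_summaries["genotype"].unique())
    if not genotypes:
        raise ValueError("no genotypes in gene summaries")
    if len(genotypes) > _MAX_INTERSECTION_GENOTYPES:
        raise ValueError(
            f"{len(genotypes)} genotypes: exclusive intersections over 2^K-1 subsets "
            f"are limited to K <= {_MAX_INTERSECTION_GENOTYPES}; aggregate genotypes first"
        )
    aseg_sets = {
        g: set(gene_summaries.query("genotype == @g and is_aseg")["gene_id"])
        for g in genotypes
    }
    membership: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*aseg_sets.values()):
        membership[gene] = tuple(g for g in genotypes if gene in aseg_sets[g])
    rows = []
    for k in range(1, len(genotypes) + 1):
        for subset in combinations(genotypes, k):
            n = sum(1 for m in membership.values() if m == subset)
            rows.append({"genotypes": "+".join(subset), "degree": k, "n_exclusive_asegs": n})
    exclusive = pd.DataFrame(rows)
    totals = pd.DataFrame(
        {
            "genotype": genotypes,
            "n_asegs": [len(aseg_sets[g]) for g in genotypes],
            "n_genes_tested": [
                int((gene_summaries["genotype"] == g).sum()) for g in genotypes
            ],
        }
    )
    return IntersectionTable(exclusive=exclusive, totals=totals)


def snp_view(
    gene_id: str, results: pd.DataFrame, transcript_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Plot-ready per-SNP table for one gene: dosage ratio vs expression.

    One row per SNP x genotype where the SNP was tested in that genotype,
    echoing the results table (no recomputation); ``mean_allele_expression``
    is the pooled per-replicate read total split by allele.
    """
    transcripts = {t for t, g in transcript_to_gene.items() if g == gene_id}
    sub = results[results["transcript"].isin(transcripts)]
    if sub.empty:
        raise ValueError(f"unknown gene or no tested SNPs: {gene_id!r}")
    view = sub[
        ["transcript", "position", "genotype", "P", "relative_expression", "is_ase", "direction"]
    ].copy()
    view["mean_ref_expression"] = sub["pooled_y"]
    view["mean_alt_expression"] = sub["pooled_n"] - sub["pooled_y"]
    view.insert(0, "gene_id", gene_id)
    return view.sort_values(["transcript", "position", "genotype"], kind="mergesort").reset_index(
        drop=True
    )


def dissimilarity_cluster(
    results: pd.DataFrame,
    matrix_kind: str = "relative_dosage",
    snp_subset: str = "all",
) -> tuple[pd.DataFrame, str]:
    """Genotype dissimilarity from per-SNP vectors, with UPGMA dendrogram.

    ``matrix_kind`` selects the per-SNP value: the relative genomic dosage
    ``P`` or the relative expression of the reference allele.  ``snp_subset``
    is ``all`` or ``ase_only`` (SNPs ASE in at least one genotype).
    Distances are Euclidean over pairwise-complete SNPs (SNPs tested in both
    genotypes of a pair); clustering is average linkage with genotypes sorted
    by name for deterministic tie-breaking.  Returns the symmetric distance
    matrix and a Newick string.
    """
    value_col = {"relative_dosage": "P", "relative_expression": "relative_expression"}.get(
        matrix_kind
    )
    if value_col is None:
        raise ValueError(f"matrix_kind must be relative_dosage or relative_expression")
    if snp_subset not in ("all", "ase_only"):
        raise ValueError("snp_subset must be 'all' or 'ase_only'")
    sub = results
    if snp_subset == "ase_only":
        ase_sites = results.loc[results["is_ase"], ["transcript", "position"]].drop_duplicates()
        sub = results.merge(ase_sites, on=["transcript", "position"], how="inner")
    mat = sub.pivot_table(
        index=["transcript", "position"], columns="genotype", values=value_col
    ).sort_index(axis=1)
    genotypes = list(mat.columns)
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes to compute dissimilarities")
    arr = mat.to_numpy(dtype=float)
    k = len(genotypes)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
            d = float(np.sqrt(np.sum((arr[both, i] - arr[both, j]) ** 2)))
            dist[i, j] = dist[j, i] = d
    linkage = average(squareform(dist, checks=False))
    tree = TreeNode.from_linkage_matrix(linkage, genotypes)
    newick = str(tree).strip()
    dist_df = pd.DataFrame(dist, index=genotypes, columns=genotypes)
    return dist_df, newick


def go_frequency(
    gene_summaries: pd.DataFrame, go_map: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GO-term ASEG frequencies per genotype, and shared-vs-exclusive counts.

    A gene counts as a *shared* ASEG when it is an ASEG in every genotype in
    which it was tested (genes cannot be tested in genotypes lacking a
    heterozygous SNP); an *exclusive* ASEG is one flagged in exactly one
    genotype.
    """
    per_geno_rows = []
    for g, sub in gene_summaries.groupby("genotype", sort=True):
        tested = set(sub["gene_id"])
        asegs = set(sub.loc[sub["is_aseg"], "gene_id"])
        gm = go_map[go_map["gene_id"].isin(tested)]
        agg = gm.groupby("go_term")["gene_id"].agg(
            n_tested_genes="nunique",
            n_asegs=lambda s: s.isin(asegs).sum(),
        )
        agg = agg.reset_index()
        agg.insert(0, "genotype", g)
        per_geno_rows.append(agg)
    per_genotype = (
        pd.concat(per_geno_rows, ignore_index=True)
        if per_geno_rows
        else pd.DataFrame(columns=["genotype", "go_term", "n_tested_genes", "n_asegs"])
    )
    per_genotype["n_asegs"] = per_genotype["n_asegs"].astype(int)

    status = gene_summaries.groupby("gene_id")["is_aseg"].agg(n_aseg="sum", n_tested="size")
    shared = set(status[(status["n_aseg"] == status["n_tested"]) & (status["n_aseg"] >= 1)].index)
    exclusive = set(status[status["n_aseg"] == 1].index)
    gm = go_map.drop_duplicates()
    shared_tab = (
        gm.groupby("go_term")["gene_id"]
        .agg(
            n_shared_asegs=lambda s: s.isin(shared).sum(),
            n_exclusive_asegs=lambda s: s.isin(exclusive).sum(),
        )
        .reset_index()
    )
    return per_genotype, shared_tab


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    go_map: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms in the selected genes.

    ``selected`` (e.g. ASEGs) must be a subset of ``background`` (e.g. all
    genes with a heterozygous tested SNP).  For each term with at least one
    background gene, the upper-tail hypergeometric probability of observing
    at least the seen number of selected genes is computed, then adjusted
    across terms with Benjamini-Hochberg; terms with adjusted p below
    ``fdr_threshold`` are flagged as over-represented.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected genes not in background: {extra}")
    gm = go_map[go_map["gene_id"].isin(background)].drop_duplicates()
    if gm.empty or not selected:
        return pd.DataFrame(
            columns=[
                "go_term",
                "n_selected_in_term",
                "n_background_in_term",
                "p_value",
                "fdr_adjusted_p",
                "significant",
            ]
        )
    M, N = len(background), len(selected)
    rows = []
    for term, genes in gm.groupby("go_term")["gene_id"]:
        in_term = set(genes)
        K = len(in_term)
        k = len(in_term & selected)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "go_term": term,
                "n_selected_in_term": k,
                "n_background_in_term": K,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).sort_values("go_term", kind="mergesort").reset_index(drop=True)
    reject, adj, _, _ = multipletests(out["p_value"], alpha=fdr_threshold, method="fdr_bh")
    out["fdr_adjusted_p"] = adj
    out["significant"] = reject
    return out
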