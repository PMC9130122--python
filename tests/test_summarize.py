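"""Tests for tallies, intersections, clustering, GO frequencies and enrichment."""

import numpy as np
import pandas as pd
import pytest

from polyase import (
    dissimilarity_cluster,
    enrich,
    go_frequency,
    intersect_asegs,
    snp_view,
    tally_ase,
)

from oracles import bh_adjust, hypergeom_enumerate


def gene_summary(rows):
    return pd.DataFrame(rows, columns=["gene_id", "genotype", "n_snps_tested", "n_ase_snps"]).assign(
        is_aseg=lambda d: d["n_ase_snps"] >= 1
    )


def results_frame(rows):
    cols = ["transcript", "position", "genotype", "P", "relative_expression", "is_ase",
            "direction", "pooled_y", "pooled_n"]
    return pd.DataFrame(rows, columns=cols)


class TestTally:
    def test_proportions(self):
        res = results_frame(
            [("t1", p, "G1", 0.5, 0.5, p < 31, "none", 5, 10) for p in range(1, 11)]
        )
        genes = gene_summary([("g1", "G1", 10, 3)])
        t = tally_ase(res, genes).iloc[0]
        assert t["n_snps_tested"] == 10 and t["n_ase_snps"] == 10
        res2 = results_frame(
            [("t1", p, "G1", 0.5, 0.5, p <= 3, "none", 5, 10) for p in range(1, 11)]
        )
        t2 = tally_ase(res2, genes).iloc[0]
        assert t2["prop_ase_snps"] == pytest.approx(0.3)
        assert t2["n_asegs"] == 1 and t2["n_genes_tested"] == 1

    def test_zero_tested_genotype_gives_zero_row(self):
        res = results_frame([])
        genes = gene_summary([("g1", "G2", 1, 0)])
        t = tally_ase(res, genes).set_index("genotype")
        assert t.loc["G2", "n_snps_tested"] == 0 and t.loc["G2", "prop_ase_snps"] == 0.0


class TestIntersections:
    def test_exclusive_partition_matches_set_algebra(self):
        genes = gene_summary(
            [("g1", "A", 1, 1), ("g2", "A", 1, 1), ("g2", "B", 1, 1), ("g3", "B", 1, 1)]
        )
        tab = intersect_asegs(genes)
        ex = tab.exclusive.set_index("genotypes")["n_exclusive_asegs"]
        assert ex["A"] == 1 and ex["B"] == 1 and ex["A+B"] == 1
        assert ex.sum() == 3  # size of the union

    def test_identical_sets_all_mass_on_full_subset(self):
        genes = gene_summary([("g1", g, 1, 1) for g in "ABC"] + [("g2", g, 1, 1) for g in "ABC"])
        ex = intersect_asegs(genes).exclusive.set_index("genotypes")["n_exclusive_asegs"]
        assert ex["A+B+C"] == 2 and ex.drop("A+B+C").sum() == 0

    def test_disjoint_sets_only_singletons(self):
        genes = gene_summary([("g1", "A", 1, 1), ("g2", "B", 1, 1)])
        ex = intersect_asegs(genes).exclusive.set_index("genotypes")["n_exclusive_asegs"]
        assert ex["A"] == 1 and ex["B"] == 1 and ex["A+B"] == 0

    def test_too_many_genotypes_guarded(self):
        genes = gene_summary([("g1", f"G{i}", 1, 1) for i in range(11)])
        with pytest.raises(ValueError, match="aggregate"):
            intersect_asegs(genes)

    def test_brute_force_on_fixture(self, small_units):
        from polyase import aggregate_genes, test_units

        res = test_units(small_units.head(300))
        genes = aggregate_genes(res, {t: t for t in res["transcript"].unique()})
        tab = intersect_asegs(genes)
        sets = {
            g: set(genes.query("genotype == @g and is_aseg")["gene_id"])
            for g in genes["genotype"].unique()
        }
        union = set().union(*sets.values())
        assert tab.exclusive["n_exclusive_asegs"].sum() == len(union)
        for row in tab.exclusive.itertuples(index=False):
            members = set(row.genotypes.split("+"))
            expected = sum(
                1 for gene in union if {g for g, s in sets.items() if gene in s} == members
            )
            assert row.n_exclusive_asegs == expected


class TestSnpView:
    def test_echoes_results_rows(self):
        res = results_frame(
            [("t1", 10, g, 0.5, 0.6, False, "none", 6, 10) for g in ("A", "B")]
            + [("t1", 20, "A", 0.25, 0.9, True, "ref_biased", 9, 10)]
        )
        view = snp_view("geneX", res, {"t1": "geneX"})
        assert len(view) == 3
        assert view["mean_ref_expression"].tolist() == [6, 6, 9]
        assert (view["gene_id"] == "geneX").all()

    def test_unknown_gene_raises(self):
        res = results_frame([("t1", 10, "A", 0.5, 0.5, False, "none", 5, 10)])
        with pytest.raises(ValueError, match="unknown gene"):
            snp_view("nope", res, {"t1": "geneX"})


class TestDissimilarity:
    def test_identical_vectors_zero_distance(self):
        res = results_frame(
            [("t1", p, g, v, v, False, "none", 5, 10) for g in ("A", "B")
             for p, v in [(1, 0.2), (2, 0.8)]]
        )
        dist, _ = dissimilarity_cluster(res, "relative_dosage")
        assert dist.loc["A", "B"] == 0.0
        assert np.allclose(dist.to_numpy(), dist.to_numpy().T)
        assert np.allclose(np.diag(dist.to_numpy()), 0.0)

    def test_identical_pair_merges_first(self):
        import io as _io

        from skbio.tree import TreeNode

        rows = []
        for p in range(1, 6):
            rows += [("t1", p, "A", 0.1, 0.1, False, "none", 1, 10),
                     ("t1", p, "B", 0.1, 0.1, False, "none", 1, 10),
                     ("t1", p, "C", 0.9, 0.9, False, "none", 9, 10)]
        _, newick = dissimilarity_cluster(results_frame(rows), "relative_dosage")
        tree = TreeNode.read(_io.StringIO(newick))
        parent_of_a = tree.find("A").parent
        assert {t.name for t in parent_of_a.tips()} == {"A", "B"}

    def test_designed_clusters_recovered(self):
        """Two dosage-divergent genotype groups split at the dendrogram root."""
        rng = np.random.default_rng(42)
        rows = []
        for p in range(1, 41):
            lo, hi = rng.uniform(0.05, 0.3), rng.uniform(0.7, 0.95)
            for g in ("A1", "A2", "A3"):
                rows.append(("t1", p, g, lo + rng.normal(0, 0.01), lo, False, "none", 1, 10))
            for g in ("B1", "B2", "B3"):
                rows.append(("t1", p, g, hi + rng.normal(0, 0.01), hi, False, "none", 9, 10))
        dist, newick = dissimilarity_cluster(results_frame(rows), "relative_dosage")
        # brute-force check of one entry
        res = results_frame(rows)
        a = res.query("genotype == 'A1'").sort_values("position")["P"].to_numpy()
        b = res.query("genotype == 'B1'").sort_values("position")["P"].to_numpy()
        assert dist.loc["A1", "B1"] == pytest.approx(float(np.sqrt(((a - b) ** 2).sum())))
        # root bipartition = {A1,A2,A3} vs {B1,B2,B3}
        import io as _io

        from skbio.tree import TreeNode

        tree = TreeNode.read(_io.StringIO(newick))
        left = {t.name for t in tree.children[0].tips()} or {tree.children[0].name}
        assert left in ({"A1", "A2", "A3"}, {"B1", "B2", "B3"})

    def test_fewer_than_two_genotypes_rejected(self):
        res = results_frame([("t1", 1, "A", 0.5, 0.5, False, "none", 5, 10)])
        with pytest.raises(ValueError, match="two genotypes"):
            dissimilarity_cluster(res)


class TestGoFrequency:
    def test_counts_and_shared_subset(self):
        genes = gene_summary(
            [("g1", "A", 2, 1), ("g1", "B", 2, 1), ("g2", "A", 1, 1), ("g3", "A", 1, 0)]
        )
        go = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3", "g1"], "go_term": ["T1", "T1", "T1", "T2"]}
        )
        per_geno, shared = go_frequency(genes, go)
        a = per_geno.query("genotype == 'A' and go_term == 'T1'").iloc[0]
        assert a["n_tested_genes"] == 3 and a["n_asegs"] == 2
        sh = shared.set_index("go_term")
        # g1 and g2 are ASEGs everywhere they were tested (shared); g2, tested in
        # only one genotype, is also genotype-exclusive; g3 is neither
        assert sh.loc["T1", "n_shared_asegs"] == 2
        assert sh.loc["T1", "n_exclusive_asegs"] == 1
        assert sh.loc["T2", "n_shared_asegs"] == 1
        assert sh.loc["T2", "n_exclusive_asegs"] == 0

    def test_term_with_no_asegs_kept_at_zero(self):
        genes = gene_summary([("g1", "A", 1, 0)])
        go = pd.DataFrame({"gene_id": ["g1"], "go_term": ["T1"]})
        per_geno, _ = go_frequency(genes, go)
        assert per_geno.iloc[0]["n_asegs"] == 0


class TestEnrichment:
    def test_exact_probability_matches_enumeration(self):
        """Hypergeometric tail equals exhaustive subset enumeration on a 10-gene toy."""
        background = [f"g{i}" for i in range(10)]
        term = {"g0", "g1", "g2", "g3"}
        selected = {"g0", "g1", "g4"}
        go = pd.DataFrame({"gene_id": sorted(term), "go_term": "T"})
        out = enrich(selected, background, go)
        expected = hypergeom_enumerate(background, term, selected)
        assert out.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_fully_concentrated_term(self):
        """Term covering all selected genes and nothing else: p = 1 / C(100, 10)."""
        from math import comb

        background = [f"g{i}" for i in range(100)]
        selected = set(background[:10])
        go = pd.DataFrame({"gene_id": sorted(selected), "go_term": "T"})
        out = enrich(selected, background, go)
        assert out.iloc[0]["p_value"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_selected_equal_background_gives_p_one(self):
        background = ["a", "b", "c"]
        go = pd.DataFrame({"gene_id": ["a", "b"], "go_term": ["T1", "T2"]})
        out = enrich(set(background), background, go)
        assert (out["p_value"] == 1.0).all()

    def test_empty_selected_empty_result(self):
        go = pd.DataFrame({"gene_id": ["a"], "go_term": ["T"]})
        assert enrich(set(), {"a"}, go).empty

    def test_selected_outside_background_rejected(self):
        go = pd.DataFrame({"gene_id": ["a"], "go_term": ["T"]})
        with pytest.raises(ValueError, match="not in background"):
            enrich({"z"}, {"a"}, go)

    def test_bh_adjustment_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        background = [f"g{i}" for i in range(40)]
        selected = set(rng.choice(background, size=12, replace=False))
        go = pd.DataFrame(
            {
                "gene_id": rng.choice(background, size=120),
                "go_term": rng.choice([f"T{i}" for i in range(15)], size=120),
            }
        ).drop_duplicates()
        out = enrich(selected, background, go)
        expected = bh_adjust(out["p_value"].to_numpy())
        np.testing.assert_allclose(out["fdr_adjusted_p"], np.minimum(expected, 1.0), atol=1e-12)
        ranked = out.sort_values("p_value")
        assert ranked["fdr_adjusted_p"].is_monotonic_increasing
        assert (out["fdr_adjusted_p"] <= 1.0).all()

    def test_null_go_assignment_controls_fdr(self):
        """Random GO maps over a null selection flag <= 5% of terms on average."""
        rng = np.random.default_rng(2024)
        background = [f"g{i}" for i in range(60)]
        terms = [f"T{i}" for i in range(12)]
        flagged = []
        for _ in range(200):
            go = pd.DataFrame(
                {
                    "gene_id": rng.choice(background, size=180),
                    "go_term": rng.choice(terms, size=180),
                }
            ).drop_duplicates()
            selected = set(rng.choice(background, size=15, replace=False))
            out = enrich(selected, background, go)
            flagged.append(out["significant"].mean() if len(out) else 0.0)
        assert float(np.mean(flagged)) <= 0.05
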