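import dendropy
import numpy as np
import pytest

from elasmoavm.phylo import (
    CorrMatrix,
    TreeError,
    brownian_correlation,
    count_trees,
    parse_tree,
    parse_tree_string,
    prune_to_species,
    select_tree,
    write_newick,
)
from elasmoavm.synthetic import simulate_tree


def brute_force_correlation(newick: str, species: list[str]) -> np.ndarray:
    """Independent oracle: per-pair MRCA depth via explicit ancestor sets."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True

    def ancestor_path(label):
        leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    def depth_of(node):
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    n = len(species)
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = ancestor_path(species[i]), ancestor_path(species[j])
            mrca = next(a for a in pi if a in set(pj))
            di, dj = depth_of(pi[0]), depth_of(pj[0])
            c[i, j] = c[j, i] = depth_of(mrca) / np.sqrt(di * dj)
    return c


class TestParse:
    def test_newick_three_tips(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        t = parse_tree(p, "newick")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.depths() == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_nexus_equivalent_topology(self, tmp_path):
        nwk = "((A:1,B:1):1,C:2);"
        t1 = parse_tree_string(nwk)
        nexus = tmp_path / "t.nex"
        dendropy.TreeList([t1.tree]).write(path=str(nexus), schema="nexus")
        t2 = parse_tree(nexus, "nexus")
        c1 = brownian_correlation(t1, ["A", "B", "C"]).values
        c2 = brownian_correlation(t2, ["A", "B", "C"]).values
        np.testing.assert_allclose(c1, c2)

    def test_multi_tree_file_selection(self, tmp_path):
        trees = [simulate_tree(4, "yule", seed=s) for s in range(5)]
        path = tmp_path / "many.nex"
        dendropy.TreeList([t.tree for t in trees]).write(path=str(path), schema="nexus")
        assert count_trees(path, "nexus") == 5
        for i in (0, 2, 4):
            got = select_tree(path, i, schema="nexus")
            want = brownian_correlation(trees[i], sorted(trees[i].tip_labels)).values
            np.testing.assert_allclose(
                brownian_correlation(got, sorted(got.tip_labels)).values, want, atol=1e-9
            )

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1:2;")
        with pytest.raises(TreeError):
            parse_tree(p, "newick")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_tree_string("((A:1,A:1):1,C:2);")


class TestPrune:
    def test_pairwise_path_length_preserved(self):
        t = parse_tree_string("((A:1,B:1):1,C:2);")
        p = prune_to_species(t, ["A", "C"])
        assert sorted(p.tip_labels) == ["A", "C"]
        assert p.depths()["A"] + p.depths()["C"] == pytest.approx(4.0)

    def test_prune_to_all_tips_is_identity(self):
        t = simulate_tree(8, "yule", seed=1)
        p = prune_to_species(t, sorted(t.tip_labels))
        c0 = brownian_correlation(t, sorted(t.tip_labels)).values
        c1 = brownian_correlation(p, sorted(p.tip_labels)).values
        np.testing.assert_allclose(c0, c1, atol=1e-12)

    def test_patristic_distances_conserved_on_random_subset(self):
        t = simulate_tree(10, "yule", seed=3)
        keep = sorted(t.tip_labels)[:4]
        parent = dendropy.PhylogeneticDistanceMatrix.from_tree(t.tree)

        def dist(tree, a, b):
            pdm = dendropy.PhylogeneticDistanceMatrix.from_tree(tree.tree)
            taxa = {tx.label: tx for tx in tree.tree.taxon_namespace if tx.label}
            return pdm.patristic_distance(taxa[a], taxa[b])

        pruned = prune_to_species(t, keep)
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                assert dist(pruned, keep[i], keep[j]) == pytest.approx(
                    dist(t, keep[i], keep[j]), rel=1e-9
                )

    def test_missing_species_listed(self):
        t = parse_tree_string("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="Zed"):
            prune_to_species(t, ["A", "Zed"])


class TestBrownianCorrelation:
    def test_star_tree_gives_identity(self):
        t = simulate_tree(5, "star", seed=0)
        np.testing.assert_allclose(
            brownian_correlation(t).values, np.eye(5), atol=1e-12
        )

    def test_three_taxon_shared_history(self):
        t = parse_tree_string("((A:1,B:1):1,C:2);")
        c = brownian_correlation(t, ["A", "B", "C"]).values
        assert c[0, 1] == pytest.approx(0.5)
        assert c[0, 2] == pytest.approx(0.0)
        assert c[1, 2] == pytest.approx(0.0)

    def test_matches_brute_force_ancestor_oracle(self):
        t = simulate_tree(20, "yule", seed=11)
        species = sorted(t.tip_labels)
        got = brownian_correlation(t, species).values
        want = brute_force_correlation(t.as_newick(), species)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_permutation_invariance(self):
        t = simulate_tree(7, "yule", seed=5)
        sp = sorted(t.tip_labels)
        c1 = brownian_correlation(t, sp).values
        perm = list(reversed(range(len(sp))))
        c2 = brownian_correlation(t, [sp[i] for i in perm]).values
        np.testing.assert_allclose(c2, c1[np.ix_(perm, perm)], atol=1e-12)

    def test_branch_length_scale_invariance(self):
        t = simulate_tree(6, "yule", seed=9)
        c1 = brownian_correlation(t, sorted(t.tip_labels)).values
        for edge in t.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 7.5
        c2 = brownian_correlation(t, sorted(t.tip_labels)).values
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_ultrametric_tree_matrix_is_psd(self):
        for seed in range(4):
            t = simulate_tree(12, "yule", seed=seed)
            c = brownian_correlation(t, sorted(t.tip_labels)).values
            assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_zero_depth_tip_rejected(self):
        with pytest.raises(TreeError, match="zero"):
            brownian_correlation(parse_tree_string("((A:0,B:1):0,C:2);"))


class TestCorrMatrix:
    def test_validation_rejects_asymmetry(self):
        bad = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CorrMatrix(bad, ["A", "B"])

    def test_reorder_permutes_consistently(self):
        c = CorrMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ["A", "B"])
        r = c.reorder(["B", "A"])
        assert r.species == ["B", "A"]
        np.testing.assert_allclose(r.values, c.values)

    def test_cholesky_reconstructs_with_jitter(self):
        t = simulate_tree(6, "yule", seed=2)
        c = brownian_correlation(t, sorted(t.tip_labels))
        L = c.cholesky()
        np.testing.assert_allclose(L @ L.T, c.values + 1e-8 * np.eye(6), atol=1e-12)

    def test_csv_round_trip(self, tmp_path):
        t = simulate_tree(4, "yule", seed=8)
        c = brownian_correlation(t, sorted(t.tip_labels))
        path = tmp_path / "corr.csv"
        c.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.to_numpy(), c.values, atol=1e-12)
        assert list(back.columns) == c.species


def test_write_newick_round_trip(tmp_path):
    t = simulate_tree(5, "yule", seed=4)
    path = tmp_path / "t.nwk"
    write_newick(t, path)
    back = parse_tree(path, "newick")
    np.testing.assert_allclose(
        brownian_correlation(back, sorted(back.tip_labels)).values,
        brownian_correlation(t, sorted(t.tip_labels)).values,
        atol=1e-9,
    )
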