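"""Distance trees: NJ, least-squares branch lengths, rooting, bootstrap."""

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avbd import (
    CodonAlignment,
    EvolConfig,
    bootstrap_support,
    linearize,
    ls_branch_lengths,
    midpoint_root,
    neighbor_joining,
    simulate_codon_alignment,
)
from avbd.trees import DistanceMatrix, ls_objective

from conftest import leaf_depths, tree_distance_matrix


def leaf_edge_lengths(tree):
    return {lf.taxon.label: float(lf.edge.length) for lf in tree.leaf_node_iter()}


def split_set(tree):
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    out = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def random_tree_newick(rng, n_leaves):
    """Random topology with strictly positive branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    parts = {n: f"{n}:{rng.uniform(0.5, 3.0):.3f}" for n in nodes}
    items = list(nodes)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[j], items[i]
        items.remove(a)
        items.remove(b)
        name = f"({parts[b]},{parts[a]})"
        key = f"I{len(items)}"
        parts[key] = f"{name}:{rng.uniform(0.5, 3.0):.3f}"
        items.append(key)
    return "(" + ",".join(parts[k] for k in items) + ");"


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(ids=list("ABC"), values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(d)
        assert leaf_edge_lengths(tree) == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrix_recovered_exactly(self):
        newick = "((A:1,B:2):1,(C:3,D:4):0);"
        dm = tree_distance_matrix(newick)
        tree = neighbor_joining(dm)
        want = split_set(dendropy.Tree.get(data=newick, schema="newick"))
        assert split_set(tree) == want
        # all pairwise path lengths reproduce the input distances
        rebuilt = tree_distance_matrix(tree.as_string(schema="newick"))
        assert np.allclose(rebuilt.values, dm.values, atol=1e-9)

    @given(st.integers(0, 1000), st.integers(4, 8))
    def test_additive_recovery_property(self, seed, n_leaves):
        rng = np.random.default_rng(seed)
        newick = random_tree_newick(rng, n_leaves)
        dm = tree_distance_matrix(newick)
        tree = neighbor_joining(dm)
        rebuilt = tree_distance_matrix(tree.as_string(schema="newick"))
        assert rebuilt.ids == dm.ids
        assert np.allclose(rebuilt.values, dm.values, atol=1e-6)

    def test_zero_matrix_gives_star_tree(self):
        d = DistanceMatrix(ids=list("ABCD"), values=np.zeros((4, 4)))
        tree = neighbor_joining(d)
        total = sum(float(e.length or 0.0) for e in tree.preorder_edge_iter() if e.length)
        assert total == pytest.approx(0.0)

    def test_agrees_with_scikit_bio(self):
        rng = np.random.default_rng(8)
        newick = random_tree_newick(rng, 6)
        dm = tree_distance_matrix(newick)
        import skbio

        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.ids))
        sk_dendropy = dendropy.Tree.get(data=str(sk_tree), schema="newick")
        assert split_set(neighbor_joining(dm)) == split_set(sk_dendropy)

    def test_undefined_entries_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        d = DistanceMatrix(ids=list("ABC"), values=vals)
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(d)

    def test_fewer_than_three_taxa_rejected(self):
        d = DistanceMatrix(ids=list("AB"), values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            neighbor_joining(d)


class TestLeastSquaresBranchLengths:
    def test_exact_fit_on_additive_input(self):
        newick = "((A:1,B:2):1,(C:3,D:4):0.5);"
        dm = tree_distance_matrix(newick)
        topo = dendropy.Tree.get(data=newick, schema="newick")
        fitted = ls_branch_lengths(topo, dm)
        assert ls_objective(fitted, dm) == pytest.approx(0.0, abs=1e-16)
        rebuilt = tree_distance_matrix(fitted.as_string(schema="newick"))
        assert np.allclose(rebuilt.values, dm.values, atol=1e-9)

    def test_beats_random_length_assignments(self):
        rng = np.random.default_rng(21)
        newick = "((A:1,B:2):1,(C:3,D:4):0.5);"
        dm = tree_distance_matrix(newick)
        vals = np.clip(dm.values + rng.normal(0, 0.3, dm.values.shape), 0.05, None)
        vals = (vals + vals.T) / 2 * (1 - np.eye(dm.n))
        noisy = DistanceMatrix(ids=dm.ids, values=vals)
        topo = dendropy.Tree.get(data=newick, schema="newick")
        fitted = ls_branch_lengths(topo, noisy)
        best = ls_objective(fitted, noisy)
        trial = topo.clone(depth=1)
        trial.deroot()
        edges = [nd for nd in trial.postorder_node_iter() if nd is not trial.seed_node]
        for _ in range(1000):
            for nd in edges:
                nd.edge.length = rng.uniform(0, 5)
            assert ls_objective(trial, noisy) >= best - 1e-12

    def test_power_zero_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        newick = "((A:1,B:2):1,(C:3,D:4):0.5);"
        dm = tree_distance_matrix(newick)
        noisy_vals = dm.values + rng.normal(0, 0.05, dm.values.shape)
        noisy_vals = (noisy_vals + noisy_vals.T) / 2 * (1 - np.eye(4))
        noisy = DistanceMatrix(ids=dm.ids, values=np.abs(noisy_vals))
        topo = dendropy.Tree.get(data=newick, schema="newick")
        fitted = ls_branch_lengths(topo, noisy, power=0.0)
        # OLS via explicit normal equations on the unrooted 4-taxon design
        ids = noisy.ids
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        pdm = fitted.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in fitted.taxon_namespace}
        # design matrix: per pair, which of the 5 edges lie on its path
        edges = [nd for nd in fitted.postorder_node_iter() if nd is not fitted.seed_node]
        sides = []
        for nd in edges:
            sides.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
        A = np.array(
            [
                [1.0 if (ids[i] in s) != (ids[j] in s) else 0.0 for s in sides]
                for i, j in pairs
            ]
        )
        y = np.array([noisy.values[i, j] for i, j in pairs])
        direct, *_ = np.linalg.lstsq(A, y, rcond=None)
        if (direct >= -1e-9).all():
            got = np.array([float(nd.edge.length) for nd in edges])
            assert np.allclose(got, np.clip(direct, 0, None), atol=1e-6)

    def test_undefined_pairs_omitted(self):
        newick = "((A:1,B:2):1,(C:3,D:4):0.5);"
        dm = tree_distance_matrix(newick)
        vals = dm.values.copy()
        vals[0, 3] = vals[3, 0] = np.nan
        partial = DistanceMatrix(ids=dm.ids, values=vals)
        topo = dendropy.Tree.get(data=newick, schema="newick")
        fitted = ls_branch_lengths(topo, partial)
        assert ls_objective(fitted, partial) == pytest.approx(0.0, abs=1e-14)

    def test_leaf_with_no_data_rejected(self):
        newick = "((A:1,B:2):1,(C:3,D:4):0.5);"
        dm = tree_distance_matrix(newick)
        vals = dm.values.copy()
        vals[0, 1:] = np.nan
        vals[1:, 0] = np.nan
        bad = DistanceMatrix(ids=dm.ids, values=vals)
        with pytest.raises(ValueError, match="undefined for taxa"):
            ls_branch_lengths(dendropy.Tree.get(data=newick, schema="newick"), bad)


class TestMidpointRoot:
    def test_two_leaf_halfway(self):
        tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_root_side_depths_balanced(self):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.4):0.2,(C:1.2,D:0.3):0.1,E:0.5);", schema="newick"
        )
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        diameter = max(depths.values()) * 2
        # the two deepest leaves on opposite root sides sit at half the diameter
        assert max(depths.values()) == pytest.approx(diameter / 2)
        per_child = [
            max(leaf_depths_subtree(ch)) for ch in rooted.seed_node.child_nodes()
        ]
        assert abs(per_child[0] - per_child[1]) <= 1e-9

    def test_topology_preserved(self):
        rng = np.random.default_rng(77)
        newick = random_tree_newick(rng, 7)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rooted = midpoint_root(tree)
        assert split_set(rooted) >= split_set(tree)
        assert tree_distance_matrix(rooted.as_string(schema="newick")).values == pytest.approx(
            tree_distance_matrix(newick).values
        )


def leaf_depths_subtree(node):
    out = []
    base_edge = float(node.edge.length or 0.0)
    for lf in node.leaf_iter():
        d, cur = 0.0, lf
        while cur is not node:
            d += float(cur.edge.length or 0.0)
            cur = cur.parent_node
        out.append(d + base_edge)
    return out


class TestLinearize:
    def test_ultrametric_fixed_point(self):
        newick = "((A:1,B:1):2,(C:2.5,D:2.5):0.5);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lin = linearize(tree)
        orig = {lf.taxon.label: d for lf, d in zip(tree.leaf_node_iter(), [3, 3, 3, 3])}
        assert leaf_depths(lin) == pytest.approx(orig)

    def test_all_leaves_equidistant(self):
        rng = np.random.default_rng(3)
        newick = random_tree_newick(rng, 8)
        lin = linearize(midpoint_root(dendropy.Tree.get(data=newick, schema="newick")))
        depths = list(leaf_depths(lin).values())
        assert np.ptp(depths) <= 1e-9

    def test_clock_simulation_heights_recovered(self):
        """Linearized NJ trees put node heights near the generating clock."""
        true_height = 0.4
        ok = 0
        for seed in range(20):
            cfg = EvolConfig(
                tree="((a:0.2,b:0.2):0.2,(c:0.2,d:0.2):0.2);",
                n_codons=400,
                kappa=2.0,
                class_probs=(1.0,),
                class_omegas=(0.5,),
                seed=seed,
            )
            sim = simulate_codon_alignment(cfg)
            from avbd.trees import p_distance_matrix

            # p-distances compress relative to substitutions; compare shape only
            nj = neighbor_joining(tree_distance_matrix_from_rates(sim.alignment))
            lin = linearize(midpoint_root(nj))
            depth = np.mean(list(leaf_depths(lin).values()))
            if abs(depth - true_height) / true_height <= 0.10:
                ok += 1
        assert ok >= 16

    def test_preserves_leaf_set_and_topology(self):
        rng = np.random.default_rng(11)
        newick = random_tree_newick(rng, 6)
        rooted = midpoint_root(dendropy.Tree.get(data=newick, schema="newick"))
        lin = linearize(rooted)
        assert split_set(lin) == split_set(rooted)


def tree_distance_matrix_from_rates(aln: CodonAlignment) -> DistanceMatrix:
    """Total substitutions per codon per pair via pairwise ML (clock check)."""
    from avbd import PairwiseCodonML

    n = aln.n_seqs
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sub = aln.subset([aln.ids[i], aln.ids[j]])
            vals[i, j] = vals[j, i] = PairwiseCodonML(sub).fit(n_restarts=1).rates.t
    return DistanceMatrix(ids=list(aln.ids), values=vals)


class TestBootstrap:
    def test_identical_columns_full_support(self):
        # every column identical: resampling cannot change the tree
        aln = CodonAlignment.from_sequences(
            ["A", "B", "C", "D"],
            ["TTT" * 50, "TTT" * 50, "GGA" * 50, "GGA" * 50],
        )
        tree = bootstrap_support(aln, n_reps=20, seed=1)
        labels = [
            nd.label
            for nd in tree.postorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        assert labels and all(lab == "100" for lab in labels)

    def test_same_seed_identical_supports(self):
        cfg = EvolConfig(
            tree="((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.4,E:0.4);",
            n_codons=150,
            kappa=2.0,
            seed=5,
        )
        aln = simulate_codon_alignment(cfg).alignment

        def labels(t):
            return sorted(
                nd.label for nd in t.postorder_node_iter() if not nd.is_leaf() and nd.label
            )

        assert labels(bootstrap_support(aln, 30, seed=9)) == labels(
            bootstrap_support(aln, 30, seed=9)
        )

    def test_deep_split_strongly_supported(self):
        cfg = EvolConfig(
            tree="((A:0.05,B:0.05,C:0.05):0.8,(D:0.05,E:0.05,F:0.05):0.8);",
            n_codons=300,
            kappa=2.0,
            seed=2,
        )
        aln = simulate_codon_alignment(cfg).alignment
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        for nd in tree.postorder_node_iter():
            if nd.is_leaf() or nd is tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if side in (frozenset("ABC"), frozenset("DEF")):
                assert float(nd.label) >= 95.0

    def test_too_few_sequences_rejected(self):
        cfg = EvolConfig(tree="(A:0.1,B:0.1);", n_codons=10, seed=0)
        aln = simulate_codon_alignment(cfg).alignment
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=10, seed=0)
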