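import numpy as np
import pytest

import dendropy

from barcodeval.distances import DistanceMatrix, pairwise_matrix
from barcodeval.errors import TreeError
from barcodeval.io import write_newick
from barcodeval.simulate import MarkerSpec, simulate_dataset
from barcodeval.trees import (
    bootstrap_support,
    is_species_monophyletic,
    leaf_path_lengths,
    neighbor_joining,
    to_newick,
)

from conftest import two_species_aln


def _dm(ids, pairs):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(ids), d, np.ones((n, n), dtype=bool))


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        dm = _dm(["a", "b", "c"], {("a", "b"): 2, ("a", "c"): 3, ("b", "c"): 4})
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_four_taxa_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)): split ab|cd, internal branch 1
        dm = _dm(
            ["a", "b", "c", "d"],
            {
                ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
                ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
            },
        )
        tree = neighbor_joining(dm)
        bips = tree.bipartitions()
        assert frozenset({"a", "b"}) in bips
        internal = bips[frozenset({"a", "b"})]
        assert internal.length == pytest.approx(1.0)
        paths = leaf_path_lengths(tree)
        for (x, y), v in paths.items():
            assert v == pytest.approx(dm.get(x, y)[0])

    def test_equal_distances_star_like(self):
        ids = ["a", "b", "c", "d"]
        dm = _dm(ids, {(x, y): 1.0 for i, x in enumerate(ids) for y in ids[i + 1:]})
        tree = neighbor_joining(dm)
        for bip, clade in tree.bipartitions().items():
            assert clade.length == pytest.approx(0.0)

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            neighbor_joining(_dm(["a", "b"], {("a", "b"): 1}))

    def test_invalid_pairs_rejected(self):
        dm = _dm(["a", "b", "c"], {("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1})
        dm.valid[0, 1] = dm.valid[1, 0] = False
        with pytest.raises(TreeError):
            neighbor_joining(dm)

    def test_taxon_order_invariance(self, rng):
        for _ in range(10):
            n = 6
            # random additive-ish symmetric matrix
            m = rng.random((n, n))
            m = (m + m.T) / 2 + 1.0
            np.fill_diagonal(m, 0.0)
            ids = [f"t{i}" for i in range(n)]
            base = neighbor_joining(
                DistanceMatrix(ids, m, np.ones((n, n), bool))
            )
            perm = rng.permutation(n)
            m2 = m[np.ix_(perm, perm)]
            ids2 = [ids[i] for i in perm]
            other = neighbor_joining(
                DistanceMatrix(ids2, m2, np.ones((n, n), bool))
            )
            assert set(base.bipartitions()) == set(other.bipartitions())

    def test_additive_matrices_up_to_8_taxa(self, rng):
        # random additive matrices from random topologies; NJ path lengths
        # must reproduce the inputs exactly
        for n_leaves in (4, 5, 6, 7, 8):
            for _ in range(10):
                dist = _random_additive(rng, n_leaves)
                ids = sorted({a for a, _ in dist} | {b for _, b in dist})
                m = np.zeros((len(ids), len(ids)))
                for (a, b), v in dist.items():
                    i, j = ids.index(a), ids.index(b)
                    m[i, j] = m[j, i] = v
                tree = neighbor_joining(
                    DistanceMatrix(ids, m, np.ones_like(m, dtype=bool))
                )
                paths = leaf_path_lengths(tree)
                for key, v in dist.items():
                    assert paths[key] == pytest.approx(v, abs=1e-9)


def _random_additive(rng, n_leaves):
    """Leaf-to-leaf distances of a random tree, built edge-list style
    (independent of the package's tree code)."""
    # graph: adjacency {node: {neighbor: weight}}
    adj = {0: {}, 1: {}}
    w01 = rng.uniform(0.1, 2.0)
    adj[0][1] = adj[1][0] = w01
    leaves = [0, 1]
    next_node = 2
    edges = [(0, 1)]
    while len(leaves) < n_leaves:
        a, b = edges[rng.integers(len(edges))]
        mid, leaf = next_node, next_node + 1
        next_node += 2
        w = adj[a].pop(b)
        adj[b].pop(a)
        edges.remove((a, b))
        f = rng.uniform(0.2, 0.8)
        adj.setdefault(mid, {})
        adj[a][mid] = adj[mid][a] = w * f
        adj[b][mid] = adj[mid][b] = w * (1 - f)
        wl = rng.uniform(0.1, 2.0)
        adj.setdefault(leaf, {})
        adj[mid][leaf] = adj[leaf][mid] = wl
        edges += [(a, mid), (mid, b), (mid, leaf)]
        leaves.append(leaf)
    # all-pairs shortest paths by BFS accumulation (tree: unique path)
    names = {leaf: f"t{idx}" for idx, leaf in enumerate(sorted(leaves))}
    out = {}
    for leaf in leaves:
        seen = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for other in leaves:
            if other > leaf:
                key = tuple(sorted((names[leaf], names[other])))
                out[key] = seen[other]
    return out


class TestNewick:
    def test_roundtrip_through_dendropy(self):
        dm = _dm(["a", "b", "c"], {("a", "b"): 2, ("a", "c"): 3, ("b", "c"): 4})
        tree = neighbor_joining(dm)
        text = to_newick(tree)
        assert text.endswith(";")
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"a", "b", "c"}
        lengths = {
            l.taxon.label: l.edge.length for l in parsed.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_support_in_internal_label(self, tmp_path):
        aln = two_species_aln("ACGT" * 30, "ACTT" * 30, 3, 3)
        tree = bootstrap_support(aln, n_replicates=20, seed=1)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text()
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert "100" in text  # clean split: full support

    def test_empty_tree_error(self):
        from barcodeval.trees import Clade, PhyloTree

        with pytest.raises(TreeError):
            to_newick(PhyloTree(root=Clade(name="only")))


class TestBootstrap:
    def _diverged(self, seed=0):
        specs = [MarkerSpec("m", 500, 0.05, 0.001)]
        alns, _, _ = simulate_dataset(specs, n_per_species=6, seed=seed)
        return alns["m"]

    def test_clear_split_high_support(self):
        aln = self._diverged()
        tree = bootstrap_support(aln, n_replicates=200, seed=3)
        labels = aln.species_map()
        split = frozenset(
            sid for sid in aln.sample_ids if labels[sid] == "species_one"
        )
        bips = tree.bipartitions()
        assert split in bips or (frozenset(aln.sample_ids) - split) in bips
        support = bips[split if split in bips else frozenset(aln.sample_ids) - split].support
        assert support >= 99.0

    def test_single_replicate_support_binary(self):
        aln = self._diverged()
        tree = bootstrap_support(aln, n_replicates=1, seed=9)
        for clade in tree.bipartitions().values():
            assert clade.support in (0.0, 100.0)

    def test_seed_determinism(self):
        aln = self._diverged()
        t1 = bootstrap_support(aln, n_replicates=50, seed=11)
        t2 = bootstrap_support(aln, n_replicates=50, seed=11)
        s1 = sorted(c.support for c in t1.bipartitions().values())
        s2 = sorted(c.support for c in t2.bipartitions().values())
        assert s1 == s2
        assert to_newick(t1) == to_newick(t2)

    def test_supports_in_range(self):
        aln = self._diverged(seed=4)
        tree = bootstrap_support(aln, n_replicates=30, seed=2)
        for clade in tree.bipartitions().values():
            assert 0.0 <= clade.support <= 100.0


class TestMonophyly:
    def test_both_monophyletic(self):
        aln = two_species_aln("ACGT" * 30, "ACTT" * 30, 2, 2)
        dm = pairwise_matrix(aln)
        tree = neighbor_joining(dm)
        labels = aln.species_map()
        assert is_species_monophyletic(tree, labels, "sp1")
        assert is_species_monophyletic(tree, labels, "sp2")

    def test_interleaved_not_monophyletic(self):
        # two haplotype groups crossing the species labels
        seqs = {
            "h1": "ACGT" * 30, "y1": "ACGT" * 30,
            "h2": "ACTT" * 30, "y2": "ACTT" * 30,
        }
        labels = {"h1": "spH", "h2": "spH", "y1": "spY", "y2": "spY"}
        from conftest import make_aln

        aln = make_aln(seqs, labels)
        tree = neighbor_joining(pairwise_matrix(aln))
        assert not is_species_monophyletic(tree, labels, "spH")
        assert not is_species_monophyletic(tree, labels, "spY")

    def test_single_sample_species_trivially_monophyletic(self):
        seqs = {"a": "ACGT" * 30, "b": "ACTT" * 30, "c": "ACGT" * 15 + "ACTT" * 15}
        labels = {"a": "sp1", "b": "sp2", "c": "sp3"}
        from conftest import make_aln

        tree = neighbor_joining(pairwise_matrix(make_aln(seqs, labels)))
        assert is_species_monophyletic(tree, labels, "sp3")

    def test_absent_species_error(self):
        aln = two_species_aln("ACGT" * 30, "ACTT" * 30, 2, 2)
        tree = neighbor_joining(pairwise_matrix(aln))
        with pytest.raises(TreeError):
            is_species_monophyletic(tree, aln.species_map(), "nope")
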