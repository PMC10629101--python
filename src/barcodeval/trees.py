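"""Neighbor-joining trees, column bootstrap, and species monophyly.

Trees are unrooted, represented with an arbitrary trifurcating root node.
Neighbor joining follows Saitou-Nei agglomeration with the Studier-Keppler
Q-criterion and a deterministic tie-break on the lowest (i, j) index pair.
Negative branch lengths are clamped to zero with the excess transferred to
the sibling branch of the same join, preserving the joined pair's path
length.

Bootstrap support resamples alignment columns with replacement, rebuilds the
K2P/NJ tree per replicate, and scores each internal bipartition of the
original tree by the percentage of (retained) replicates containing it.
Monophyly is a bipartition property of the unrooted tree, so no rooting
choice is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TreeError
from .distances import DistanceMatrix, _k2p_from_counts, _pair_count_matrices
from .io import LabeledAlignment


@dataclass
class Clade:
    """Tree node; ``name`` is set on leaves only."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree held at a trifurcating (or star) root."""

    root: Clade
    n_dropped_replicates: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def edges(self) -> list[tuple[Clade, frozenset[str]]]:
        """(clade, leaf set below its parent edge) for every non-root node."""
        out: list[tuple[Clade, frozenset[str]]] = []

        def walk(node: Clade) -> None:
            for child in node.children:
                out.append((child, frozenset(child.leaves())))
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], Clade]:
        """Internal bipartitions keyed by a canonical side."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset[str], Clade] = {}
        for clade, below in self.edges():
            if clade.is_leaf:
                continue
            comp = all_leaves - below
            if len(below) < 2 or len(comp) < 2:
                continue
            out[_canonical(below, comp)] = clade
        return out


def _canonical(side: frozenset[str], comp: frozenset[str]) -> frozenset[str]:
    ka = (len(side), tuple(sorted(side)))
    kb = (len(comp), tuple(sorted(comp)))
    return side if ka <= kb else comp


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def to_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths; integer support as internal label."""

    def fmt(node: Clade) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{int(round(node.support))}"
        return f"({inner}){label}:{node.length:.6f}"

    if tree.root.is_leaf:
        raise TreeError("cannot serialise a single-leaf tree")
    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """NJ tree from a fully valid distance matrix."""
    if dm.n < 3:
        raise TreeError("neighbor joining needs >= 3 samples")
    iu = np.triu_indices(dm.n, k=1)
    if not dm.valid[iu].all():
        raise TreeError(
            "distance matrix contains invalid pairs; prune the affected "
            "samples before tree construction"
        )
    d = dm.d.astype(float).copy()
    nodes: list[Clade] = [Clade(name=sid) for sid in dm.sample_ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among exact minima: row-major scan of argwhere
        qmin = q.min()
        i, j = map(int, np.argwhere(q == qmin)[0])
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the excess to the sibling branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = Clade(children=[nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        new_d = np.empty((n - 1, n - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        new_d[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(root=Clade(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _nj_from_counts(sample_ids, n_mat, ts_mat, tv_mat, min_overlap):
    m = len(sample_ids)
    d = np.zeros((m, m))
    valid = np.ones((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            dij, ok = _k2p_from_counts(
                n_mat[i, j], ts_mat[i, j], tv_mat[i, j], min_overlap
            )
            d[i, j] = d[j, i] = 0.0 if not ok else dij
            valid[i, j] = valid[j, i] = ok
    dm = DistanceMatrix(list(sample_ids), d, valid, min_overlap)
    iu = np.triu_indices(m, k=1)
    if not valid[iu].all():
        return None
    return neighbor_joining(dm)


def bootstrap_support(
    aln: LabeledAlignment,
    n_replicates: int = 1000,
    seed: int | None = None,
    min_overlap: int = 50,
) -> PhyloTree:
    """NJ tree of ``aln`` with column-bootstrap support on internal edges.

    Replicates whose resampled matrix contains an invalid pair are dropped
    and counted in ``n_dropped_replicates``; support is the percentage of
    retained replicates containing each original bipartition.
    """
    if n_replicates < 1:
        raise TreeError("need at least one bootstrap replicate")
    enc = aln.encoded()
    ids = aln.sample_ids
    tree = _nj_from_counts(
        ids, *_pair_count_matrices(enc), min_overlap
    )
    if tree is None:
        raise TreeError(
            "distance matrix contains invalid pairs; prune the affected "
            "samples before tree construction"
        )
    target = tree.bipartitions()
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    kept = 0
    dropped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = _nj_from_counts(
            ids, *_pair_count_matrices(enc[:, cols]), min_overlap
        )
        if rep is None:
            dropped += 1
            continue
        kept += 1
        rep_bips = set(rep.bipartitions())
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    if kept == 0:
        raise TreeError("every bootstrap replicate was invalid")
    for key, clade in target.items():
        clade.support = 100.0 * counts[key] / kept
    tree.n_dropped_replicates = dropped
    return tree


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def is_species_monophyletic(
    tree: PhyloTree, labels, species: str
) -> bool:
    """True iff the species' leaves form one side of some bipartition."""
    leaves = frozenset(tree.leaf_names())
    members = frozenset(l for l in leaves if labels[l] == species)
    if not members:
        raise TreeError(f"species {species!r} absent from tree")
    if len(members) == 1 or members == leaves:
        return True
    for _, below in tree.edges():
        if below == members or (leaves - below) == members:
            return True
    return False


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Sum of branch lengths along the path between every leaf pair."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: Clade) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}  # type: ignore[dict-item]
        sub = [walk(c) for c in node.children]
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = (
                            da
                            + node.children[a].length
                            + db
                            + node.children[b].length
                        )
        merged: dict[str, float] = {}
        for i, s in enumerate(sub):
            for leaf, dist in s.items():
                merged[leaf] = dist + node.children[i].length
        return merged

    walk(tree.root)
    return dists
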