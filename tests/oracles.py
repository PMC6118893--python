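"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately simple, slow re-derivation of a quantity the
package computes by its production path: a quadratic-space Gotoh local
aligner, least-squares quartet enumeration, exhaustive single-gain event
minimisation, and random additive trees with known topology.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(query: str, target: str, gap_open: float = 10.0,
                      gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; a gap of length k costs open + k*ext."""
    n, m = len(query), len(target)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (consuming query)
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consuming target)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            s = _BLOSUM62[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return float(best)


def quartet_ls_topology(d: np.ndarray) -> frozenset:
    """Best of the three quartet topologies by least-squares branch fit.

    Taxa indexed 0..3; returns the cherry containing taxon 0 as a frozenset.
    Each topology has 5 branches; pair distances are sums of branch lengths,
    fitted by non-negative-free least squares on the 6 equations.
    """
    pairs = list(itertools.combinations(range(4), 2))
    topologies = {
        frozenset((0, 1)): ((0, 1), (2, 3)),
        frozenset((0, 2)): ((0, 2), (1, 3)),
        frozenset((0, 3)): ((0, 3), (1, 2)),
    }
    best = None
    for key in (frozenset((0, 1)), frozenset((0, 2)), frozenset((0, 3))):
        cherry_a, cherry_b = topologies[key]
        # branches: 4 pendant + 1 internal
        A = np.zeros((6, 5))
        y = np.zeros(6)
        for r, (i, j) in enumerate(pairs):
            A[r, i] = 1
            A[r, j] = 1
            same_cherry = ({i, j} == set(cherry_a)) or ({i, j} == set(cherry_b))
            if not same_cherry:
                A[r, 4] = 1
            y[r] = d[i, j]
        x, residuals, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, key)
    return best[1]


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary unrooted tree with branch lengths in [0.1, 1].

    Returns (labels, distance matrix, set of canonical nontrivial splits).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining taxa to random edges
    nodes = {0: None}
    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    center = tree.seed_node
    for i in range(3):
        child = dendropy.Node(taxon=tns.new_taxon(labels[i]))
        child.edge.length = float(rng.uniform(0.1, 1.0))
        center.add_child(child)
    for i in range(3, n_taxa):
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
        edge = edges[int(rng.integers(len(edges)))]
        head = edge.head_node
        parent = head.parent_node
        split = dendropy.Node()
        old_len = edge.length
        parent.remove_child(head)
        parent.add_child(split)
        split.edge.length = old_len * 0.5
        split.add_child(head)
        head.edge.length = old_len * 0.5
        leaf = dendropy.Node(taxon=tns.new_taxon(labels[i]))
        leaf.edge.length = float(rng.uniform(0.1, 1.0))
        split.add_child(leaf)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tns}
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    from homeoscan.njtree import tree_bipartitions

    return labels, D, tree_bipartitions(tree), tree


def random_rooted_tree(n_taxa: int, rng: np.random.Generator) -> str:
    """Random rooted binary tree as a Newick string with leaf names t0.."""
    items = [f"t{i}" for i in range(n_taxa)]
    while len(items) > 1:
        i = int(rng.integers(len(items)))
        a = items.pop(i)
        j = int(rng.integers(len(items)))
        b = items.pop(j)
        items.append(f"({a},{b})")
    return items[0] + ";"


def dollo_min_events(newick: str, presence: dict[str, bool]) -> int:
    """Exhaustive minimum events over internal 0/1 states with at most one gain.

    Events: a 0->1 transition along an edge (or a present root) is a gain;
    a 1->0 transition is a loss.  States at leaves are fixed by ``presence``.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for states in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(map(id, internal), states))

        def state(node):
            if node.is_leaf():
                return int(presence[node.taxon.label])
            return st[id(node)]

        gains = int(state(tree.seed_node) == 1)
        losses = 0
        ok = True
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p, c = state(node.parent_node), state(node)
            if p == 0 and c == 1:
                gains += 1
            elif p == 1 and c == 0:
                losses += 1
        if gains > 1:
            continue
        total = gains + losses
        if best is None or total < best:
            best = total
    return best
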