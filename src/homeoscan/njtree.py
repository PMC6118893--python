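"""Neighbor-joining phylogenies with nonparametric bootstrap.

The in-house member of the three-analysis ensemble (the maximum-likelihood
and Bayesian trees are external Newick inputs downstream): amino-acid
distances under pairwise deletion (p-distance or its Poisson correction),
canonical Saitou-Nei agglomeration with deterministic tie-breaking, column
bootstrap with bipartition counting, and outgroup rooting.

No rate-heterogeneity correction is applied to distances; the distance model
is therefore always recorded explicitly alongside outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

from .io import SequenceRecord, FormatError


class DistanceError(ValueError):
    pass


@dataclass
class Alignment:
    """Ordered aligned rows; all rows equal length, ids unique."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"alignment rows have unequal lengths {sorted(lengths)}")

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Alignment":
        recs = list(records)
        return cls([r.id for r in recs], [r.residues.upper() for r in recs])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from .io import read_fasta

        return cls.from_records(read_fasta(path))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """Integer-encode residues; gaps ('-', '.', 'X') become -1."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        arr = arr.reshape(len(self.rows), self.n_columns).astype(np.int16)
        out = arr.copy()
        for gap in b"-.X*":
            out[arr == gap] = -1
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray
    model: str  # "p" or "poisson"

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise DistanceError("distance matrix is not symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise DistanceError("distances must be >= 0 with zero diagonal")


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _pairwise_counts(enc: np.ndarray, columns: np.ndarray | None = None):
    sub = enc if columns is None else enc[:, columns]
    valid = sub >= 0
    comp = valid[:, None, :] & valid[None, :, :]
    diff = (sub[:, None, :] != sub[None, :, :]) & comp
    return comp.sum(axis=2), diff.sum(axis=2)


def aa_distance(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise amino-acid distances with pairwise deletion of gap columns.

    ``p`` is the proportion of mismatches over compared sites; ``poisson`` is
    -ln(1 - p).  A pair with no comparable columns, or p >= 1 under the
    Poisson model, raises a DistanceError naming the pair.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(alignment) < 2:
        raise DistanceError("need at least two rows")
    enc = alignment.encoded()
    comp, diff = _pairwise_counts(enc)
    np.fill_diagonal(comp, 1)
    bad = np.argwhere(comp == 0)
    if len(bad):
        i, j = bad[0]
        raise DistanceError(
            f"no comparable columns between {alignment.ids[i]!r} and {alignment.ids[j]!r}")
    p = diff / comp
    if model == "p":
        d = p
    else:
        if (p >= 1).any():
            i, j = np.argwhere(p >= 1)[0]
            raise DistanceError(
                f"saturated pair under poisson model: {alignment.ids[i]!r}, {alignment.ids[j]!r}")
        d = -np.log1p(-p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(alignment.ids), d, model)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Deterministic: Q-matrix ties are broken by the smallest lexicographic pair
    of cluster representatives (the smallest leaf id in each cluster).
    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch, the usual practical convention.
    """
    n = len(dm.ids)
    if n < 3:
        raise DistanceError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    reps = []  # lexicographic representative per active cluster
    for label in dm.ids:
        taxon = taxa.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        reps.append(label)
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[ai].edge.length = li
        nodes[aj].edge.length = lj
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        # distances from the new node to the remaining clusters
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = new_d
        D[:, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = parent
        reps[ai] = min(reps[ai], reps[aj])
        active.pop(j)

    ai, aj = active
    root = dendropy.Node()
    half = D[ai, aj]
    nodes[ai].edge.length = half / 2 if nodes[ai].is_leaf() else half / 2
    nodes[aj].edge.length = half - nodes[ai].edge.length
    root.add_child(nodes[ai])
    root.add_child(nodes[aj])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    # suppress the degree-2 root so the tree is genuinely unrooted
    tree.collapse_basal_bifurcation()
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def _bipartition_key(leaf_labels: frozenset, all_labels: frozenset) -> frozenset:
    """Canonical side of a split: the side not containing the smallest id."""
    smallest = min(all_labels)
    side = frozenset(leaf_labels)
    if smallest in side:
        side = all_labels - side
    return side


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions of a tree, treated as unrooted."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _bipartition_key(clade, all_labels)
        if 2 <= len(key) <= len(all_labels) - 2:
            out.add(key)
    return out


def _distance_from_encoded(enc: np.ndarray, ids, model: str) -> DistanceMatrix:
    comp, diff = _pairwise_counts(enc)
    np.fill_diagonal(comp, 1)
    comp = np.maximum(comp, 1)
    p = diff / comp
    if model == "poisson":
        p = np.minimum(p, 0.999999)
        d = -np.log1p(-p)
    else:
        d = p
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(tuple(ids), d, model)


def bootstrap_support(alignment: Alignment, model: str = "p",
                      config: BootstrapConfig | None = None) -> dict[frozenset, int]:
    """Column bootstrap: counts, out of ``replicates``, of each bipartition.

    Columns are resampled with replacement, a NJ tree is built per replicate,
    and bipartition occurrences are tallied.  Seed-deterministic and invariant
    to row order (rows are sorted internally by id before resampling).
    """
    if len(alignment) < 4:
        raise DistanceError("bootstrap needs >= 4 rows")
    config = config or BootstrapConfig()
    order = np.argsort(alignment.ids)
    ids = [alignment.ids[i] for i in order]
    enc = alignment.encoded()[order]
    rng = np.random.default_rng(config.seed)
    counts: dict[frozenset, int] = {}
    ncol = enc.shape[1]
    for _ in range(config.replicates):
        cols = rng.integers(ncol, size=ncol)
        dm = _distance_from_encoded(enc[:, cols], ids, model)
        tree = neighbor_joining(dm)
        for bip in tree_bipartitions(tree):
            counts[bip] = counts.get(bip, 0) + 1
    return counts


def annotate_bootstrap(tree: dendropy.Tree, counts: dict[frozenset, int]) -> None:
    """Attach bootstrap counts as integer labels on matching internal nodes."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _bipartition_key(clade, all_labels)
        if 2 <= len(key) <= len(all_labels) - 2:
            node.label = str(counts.get(key, 0))


# ---------------------------------------------------------------------------
# rooting


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge at its midpoint."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    length = leaf.edge.length or 0.0
    tree.is_rooted = True
    tree.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False)
    return tree
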