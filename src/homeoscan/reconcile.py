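"""Transfer of support values between phylogenies of the same leaf set.

A target tree (in the original analyses, the Bayesian tree) receives, on each
internal node, the native support of the equivalent node in each source tree:
the neighbor-joining bootstrap count, the maximum-likelihood bootstrap
percentage, and the Bayesian posterior probability.  Node equivalence is
identical unrooted bipartition, which makes the mapping independent of each
source's rooting and leaf rotation.  A node with no equivalent in a source is
explicitly marked absent and rendered as a dash.

The annotation dialect is ``nj|ml|pp`` stored as a quoted internal-node label:
nj as an integer count, ml as an integer percentage, pp to two decimals,
absent slots as ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy

from .io import FormatError, read_newick
from .njtree import _bipartition_key, tree_bipartitions

ABSENT = None

SLOTS = ("nj", "ml", "bayes")


@dataclass(frozen=True)
class SupportTriplet:
    """(NJ bootstrap count, ML bootstrap %, Bayesian pp), each possibly absent."""

    nj: float | None = ABSENT
    ml: float | None = ABSENT
    bayes: float | None = ABSENT

    def validate(self, nj_replicates: int = 1000) -> None:
        if self.nj is not ABSENT and not 0 <= self.nj <= nj_replicates:
            raise ValueError(f"nj count {self.nj} outside [0, {nj_replicates}]")
        if self.ml is not ABSENT and not 0 <= self.ml <= 100:
            raise ValueError(f"ml percentage {self.ml} outside [0, 100]")
        if self.bayes is not ABSENT and not 0 <= self.bayes <= 1:
            raise ValueError(f"posterior {self.bayes} outside [0, 1]")

    def normalized(self, nj_replicates: int = 1000) -> dict[str, float | None]:
        """All three supports on a common percentage scale (absent stays None)."""
        return {
            "nj": ABSENT if self.nj is ABSENT else 100.0 * self.nj / nj_replicates,
            "ml": self.ml,
            "bayes": ABSENT if self.bayes is ABSENT else 100.0 * self.bayes,
        }

    @property
    def n_absent(self) -> int:
        return sum(v is ABSENT for v in (self.nj, self.ml, self.bayes))


def format_support(triplet: SupportTriplet) -> str:
    """Render as ``nj|ml|pp`` with ``-`` for absent slots."""
    nj = "-" if triplet.nj is ABSENT else str(int(round(triplet.nj)))
    ml = "-" if triplet.ml is ABSENT else str(int(round(triplet.ml)))
    pp = "-" if triplet.bayes is ABSENT else f"{triplet.bayes:.2f}"
    return f"{nj}|{ml}|{pp}"


def parse_support(label: str) -> SupportTriplet:
    parts = label.split("|")
    if len(parts) != 3:
        raise FormatError(f"support label {label!r} is not 'nj|ml|pp'")
    nj, ml, pp = parts
    return SupportTriplet(
        nj=ABSENT if nj == "-" else float(nj),
        ml=ABSENT if ml == "-" else float(ml),
        bayes=ABSENT if pp == "-" else float(pp),
    )


# ---------------------------------------------------------------------------
# bipartitions


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical nontrivial bipartitions of a (rooted or unrooted) tree.

    Rooted trees are treated as unrooted for extraction, so trees differing
    only in root placement or child order yield identical sets.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        dup = sorted({l for l in leaves if leaves.count(l) > 1})
        raise FormatError(f"duplicate leaf ids: {dup}")
    if len(leaves) < 4:
        raise ValueError("bipartitions need >= 4 leaves")
    return tree_bipartitions(tree)


def _support_by_bipartition(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Native support per bipartition, read from internal-node labels.

    In source trees the internal-node label (or, failing that, dendropy's
    parsed ``support`` attribute) carries the analysis's own support value.
    Polytomies simply contribute fewer bipartitions (strict equality means a
    polytomy matches no resolved edge within it).
    """
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _bipartition_key(clade, all_labels)
        if not (2 <= len(key) <= len(all_labels) - 2):
            continue
        value = None
        if node.label not in (None, ""):
            try:
                value = float(node.label)
            except ValueError:
                value = None
        if value is None:
            continue
        # in a rooted source the two root-adjacent nodes describe the same
        # unrooted bipartition; keep the better-supported label
        out[key] = value if key not in out else max(out[key], value)
    return out


@dataclass
class AnnotatedTree:
    """A rooted target tree whose internal nodes carry SupportTriplets."""

    tree: dendropy.Tree
    triplets: dict[str, SupportTriplet]  # node id -> triplet
    nj_replicates: int = 1000

    def node_ids(self) -> list[str]:
        return list(self.triplets)

    def members(self, node_id: str) -> tuple[str, ...]:
        for node in self.tree.preorder_node_iter():
            if getattr(node, "hs_id", None) == node_id:
                return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        raise KeyError(node_id)


def _assign_node_ids(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.hs_id = f"leaf:{node.taxon.label}"
        else:
            node.hs_id = f"n{i}"
            i += 1


def transfer_support(target: dendropy.Tree,
                     nj: dendropy.Tree | None = None,
                     ml: dendropy.Tree | None = None,
                     bayes: dendropy.Tree | None = None,
                     prune_to_common: bool = False,
                     nj_replicates: int = 1000) -> AnnotatedTree:
    """Map each source's native supports onto equivalent target nodes.

    All trees must share the target's leaf set; a mismatch is an error listing
    the symmetric difference unless ``prune_to_common`` is set, in which case
    every tree is pruned to the common leaf intersection first.  For each
    internal target edge and each source, the support is copied when the
    source contains the same canonical bipartition, else marked absent.
    """
    target = target.clone(depth=1)
    sources = {"nj": nj, "ml": ml, "bayes": bayes}
    target_leaves = {lf.taxon.label for lf in target.leaf_node_iter()}
    common = set(target_leaves)
    for name, src in sources.items():
        if src is None:
            continue
        src_leaves = {lf.taxon.label for lf in src.leaf_node_iter()}
        if src_leaves != target_leaves and not prune_to_common:
            diff = sorted(src_leaves.symmetric_difference(target_leaves))
            raise ValueError(
                f"leaf sets of target and {name} source differ: {diff}")
        common &= src_leaves

    if prune_to_common:
        def pruned(tree):
            tree = tree.clone(depth=1)
            keep = [t for t in tree.taxon_namespace if t.label in common]
            tree.retain_taxa(keep)
            return tree

        target = pruned(target)
        sources = {k: (pruned(v) if v is not None else None) for k, v in sources.items()}

    support_maps = {
        name: (_support_by_bipartition(src) if src is not None else {})
        for name, src in sources.items()
    }
    have_source = {name: src is not None for name, src in sources.items()}

    all_labels = frozenset(lf.taxon.label for lf in target.leaf_node_iter())
    _assign_node_ids(target)
    triplets: dict[str, SupportTriplet] = {}
    for node in target.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _bipartition_key(clade, all_labels)
        if not (2 <= len(key) <= len(all_labels) - 2):
            continue
        values = {}
        for name in SLOTS:
            if have_source[name]:
                values[name] = support_maps[name].get(key, ABSENT)
            else:
                values[name] = ABSENT
        triplet = SupportTriplet(values["nj"], values["ml"], values["bayes"])
        triplets[node.hs_id] = triplet
        node.label = format_support(triplet)
    return AnnotatedTree(target, triplets, nj_replicates)


# ---------------------------------------------------------------------------
# annotated-newick I/O


def write_annotated_newick(annotated: AnnotatedTree, path=None) -> str:
    """Serialize with the triplet string as a quoted internal-node label."""

    def fmt(node) -> str:
        if node.is_leaf():
            s = node.taxon.label
            if any(c in s for c in "()[]{}|,;: '\""):
                s = "'" + s.replace("'", "''") + "'"
        else:
            s = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")"
            if node.label:
                s += f"'{node.label}'"
        if node.edge.length is not None:
            s += f":{node.edge.length:g}"
        return s

    out = fmt(annotated.tree.seed_node) + ";"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(out + "\n")
    return out


def read_annotated_newick(path_or_string) -> AnnotatedTree:
    tree = read_newick(path_or_string, rooting="force-rooted")
    _assign_node_ids(tree)
    triplets: dict[str, SupportTriplet] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label not in (None, ""):
            triplets[node.hs_id] = parse_support(node.label)
    return AnnotatedTree(tree, triplets)
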