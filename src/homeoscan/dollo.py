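"""Minimum gene-family gain/loss reconstruction on a fixed species cladogram.

Under Dollo parsimony a gene family is gained exactly once and subsequently
only lost, matching figures that mark a single origin per family.  For a
presence/absence row the unique minimum-event reconstruction places the gain
on the edge above the most recent common ancestor of the present taxa (the
rootward-most placement among minima) and one loss on the edge above each
maximal subtree containing no present taxon.

Multi-species taxon groups follow the any-gain / all-loss convention: a group
is scored present when any member species has the family, and absent only
when no member does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .io import read_newick


class PresenceError(ValueError):
    pass


def validate_presence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Boolean families x taxa frame; all-absent rows are an input error."""
    m = matrix.astype(bool)
    empty = m.index[~m.any(axis=1)].tolist()
    if empty:
        raise PresenceError(f"families absent everywhere: {empty}")
    return m


def collapse_taxa(matrix: pd.DataFrame, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Collapse taxa into groups: presence = OR over member taxa.

    Gains are therefore marked if found in any member species, and losses
    only when absent from every member.  ``grouping`` must cover all matrix
    taxa; taxa may map to themselves (singleton groups leave the row as is).
    """
    m = matrix.astype(bool)
    missing = [t for t in m.columns if t not in grouping]
    if missing:
        raise PresenceError(f"grouping does not cover taxa: {missing}")
    groups: dict[str, list[str]] = {}
    for taxon in m.columns:
        groups.setdefault(grouping[taxon], []).append(taxon)
    empty = [g for g, members in groups.items() if not members]
    if empty:
        raise PresenceError(f"groups with zero members: {empty}")
    out = pd.DataFrame({g: m[members].any(axis=1) for g, members in groups.items()},
                       index=m.index)
    return out


@dataclass(frozen=True)
class GainLossEvent:
    family_id: str
    edge: str  # id of the child node below the edge
    event: str  # "gain" or "loss"


def _node_ids(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    ids: dict[dendropy.Node, str] = {}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        elif node.label:
            ids[node] = node.label
        else:
            ids[node] = f"node{i}"
        i += 1
    return ids


def dollo_events(matrix: pd.DataFrame, cladogram: dendropy.Tree | str,
                 ) -> tuple[list[GainLossEvent], pd.DataFrame]:
    """Minimum single-gain events per family on the cladogram.

    Returns the event list and a per-edge summary (edge id, gains, losses,
    and the family names involved).  Matrix taxa must equal the cladogram's
    leaves.  Lineages present in the cladogram but absent from the matrix are
    allowed only if pruned by the caller; they are an error here, so that
    unsampled lineages cannot silently absorb events.
    """
    if isinstance(cladogram, str):
        cladogram = read_newick(cladogram, rooting="force-rooted")
    m = validate_presence(matrix)
    leaves = {lf.taxon.label for lf in cladogram.leaf_node_iter()}
    if set(m.columns) != leaves:
        diff = sorted(set(m.columns).symmetric_difference(leaves))
        raise PresenceError(f"matrix taxa and cladogram leaves differ: {diff}")

    ids = _node_ids(cladogram)
    events: list[GainLossEvent] = []
    for family, row in m.iterrows():
        present = {t for t, v in row.items() if v}
        gain_node = cladogram.mrca(taxon_labels=sorted(present))
        events.append(GainLossEvent(family, ids[gain_node], "gain"))

        def losses(node):
            sub = {lf.taxon.label for lf in node.leaf_iter()}
            if not sub & present:
                events.append(GainLossEvent(family, ids[node], "loss"))
                return
            for child in node.child_nodes():
                losses(child)

        for child in gain_node.child_nodes():
            losses(child)
    summary = summarize_by_node(events)
    return events, summary


def summarize_by_node(events: Sequence[GainLossEvent]) -> pd.DataFrame:
    """Group events per edge and type; totals are conserved."""
    rows: dict[tuple[str, str], list[str]] = {}
    for ev in events:
        rows.setdefault((ev.edge, ev.event), []).append(ev.family_id)
    out = [{"edge": edge, "event": kind, "count": len(fams),
            "families": ",".join(sorted(fams))}
           for (edge, kind), fams in sorted(rows.items())]
    return pd.DataFrame(out, columns=["edge", "event", "count", "families"])


def implied_states(events: Sequence[GainLossEvent], cladogram: dendropy.Tree,
                   family_id: str) -> dict[str, bool]:
    """Leaf states implied by a family's events (for verification)."""
    ids = _node_ids(cladogram)
    by_id = {v: k for k, v in ids.items()}
    gain = [e for e in events if e.family_id == family_id and e.event == "gain"]
    losses = {e.edge for e in events if e.family_id == family_id and e.event == "loss"}
    states: dict[str, bool] = {lf.taxon.label: False for lf in cladogram.leaf_node_iter()}
    if not gain:
        return states
    (gain,) = gain

    def walk(node, state):
        nid = ids[node]
        if nid in losses:
            state = False
        if nid == gain.edge:
            state = True
        if node.is_leaf():
            states[node.taxon.label] = state
        for child in node.child_nodes():
            walk(child, state)

    walk(by_id[gain.edge], True)
    return states
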