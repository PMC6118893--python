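"""Clade calling, nomenclature reconciliation and paralogue lettering.

A node of an annotated tree is called a clade when any of its support values
(all normalized to a percentage scale) exceeds the threshold, when the node
was reconstructed in all three analyses, or when independent structural
evidence (for example a shared two-homeodomain architecture) is supplied for
it.  Called clades are reconciled against a prior registry of named clades
(Roman-numeral series per class prefix, e.g. TALE-I ... TALE-XIX) by
membership overlap: sequences can be confirmed, added as new orthologues,
reclassified from another clade, or grouped into newly erected clades that
continue the numeral series.  Within a clade, same-species paralogues are
distinguished by letters that carry no orthology claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .io import FormatError, read_tsv, write_tsv
from .reconcile import ABSENT, AnnotatedTree

# ---------------------------------------------------------------------------
# roman numerals

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
)


def to_roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def from_roman(s: str) -> int:
    values = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
    total = 0
    prev = 0
    for c in reversed(s.upper()):
        if c not in values:
            raise ValueError(f"invalid roman numeral {s!r}")
        v = values[c]
        total += v if v >= prev else -v
        prev = max(prev, v)
    if to_roman(total) != s.upper():
        raise ValueError(f"non-canonical roman numeral {s!r}")
    return total


# ---------------------------------------------------------------------------
# clade calling


@dataclass(frozen=True)
class CladeCriteria:
    """Clade definition: any support above the threshold, or presence in all
    three analyses, or structural evidence for the node."""

    supportThresholdPercent: float = 70.0
    requireStrict: bool = True  # strictly greater than the threshold
    structureEvidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.supportThresholdPercent < 100:
            raise ValueError("threshold must be in (0, 100)")

    def exceeds(self, value: float) -> bool:
        t = self.supportThresholdPercent
        return value > t if self.requireStrict else value >= t


@dataclass(frozen=True)
class CladeCall:
    node_id: str
    members: tuple[str, ...]
    justification: str  # support | all-three | structure | canonical | prior
    supports: Mapping[str, float | None]


def call_clades(annotated: AnnotatedTree, criteria: CladeCriteria | None = None
                ) -> list[CladeCall]:
    """Apply the clade criteria to every internal node of the annotated tree.

    The justification records the first satisfied criterion in the order
    support > all-three > structure.  Nested calls are allowed.
    """
    criteria = criteria or CladeCriteria()
    calls: list[CladeCall] = []
    for node_id in annotated.node_ids():
        triplet = annotated.triplets[node_id]
        norm = triplet.normalized(annotated.nj_replicates)
        present = [v for v in norm.values() if v is not ABSENT]
        justification = None
        if any(criteria.exceeds(v) for v in present):
            justification = "support"
        elif triplet.n_absent == 0:
            justification = "all-three"
        elif node_id in criteria.structureEvidence:
            justification = "structure"
        if justification is None:
            continue
        calls.append(CladeCall(node_id, annotated.members(node_id),
                               justification, norm))
    return sorted(calls, key=lambda c: c.members)


# ---------------------------------------------------------------------------
# registry


def split_member(member: str) -> tuple[str, str]:
    """Split a ``species|sequence`` member id."""
    if "|" in member:
        sp, _, rest = member.partition("|")
        return sp, rest
    return "", member


_UNCLASSIFIED = ("", "NONE", "-", "—")


def _is_classified(name: str) -> bool:
    return bool(name) and name not in _UNCLASSIFIED and not name.endswith("?")


@dataclass
class CladeRegistry:
    """Persistent clade nomenclature: one row per classified sequence.

    Columns: clade, species, sequence, letter, origin (N = newly discovered
    here, P / M = described by one of the two prior analyses), prior (the
    previous classification, or NONE).
    """

    frame: pd.DataFrame

    COLUMNS = ("clade", "species", "sequence", "letter", "origin", "prior")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"registry is missing columns {missing}")
        dup = self.frame.duplicated(subset=["species", "sequence"])
        if dup.any():
            rows = self.frame[dup][["species", "sequence"]].values.tolist()
            raise FormatError(f"duplicate (species, sequence) rows: {rows}")

    @classmethod
    def from_tsv(cls, path) -> "CladeRegistry":
        return cls(read_tsv(path))

    def to_tsv(self, path, comment: str | None = None) -> None:
        write_tsv(self.frame[list(self.COLUMNS)], path, comment=comment)

    @classmethod
    def empty(cls) -> "CladeRegistry":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))

    def members_of(self, clade: str) -> set[str]:
        sel = self.frame[self.frame["clade"] == clade]
        return {f"{r.species}|{r.sequence}" for r in sel.itertuples()}

    def clades(self) -> list[str]:
        return sorted(self.frame["clade"].unique())

    def classification_of(self) -> dict[str, str]:
        return {f"{r.species}|{r.sequence}": r.clade for r in self.frame.itertuples()}

    def max_numeral(self, prefix: str) -> int:
        best = 0
        for clade in self.frame["clade"].unique():
            if clade.startswith(prefix + "-"):
                suffix = clade[len(prefix) + 1 :]
                try:
                    best = max(best, from_roman(suffix))
                except ValueError:
                    continue
        return best


@dataclass
class RevisionReport:
    """Tallies and per-sequence outcomes of a registry reconciliation."""

    outcomes: pd.DataFrame  # member, species, sequence, clade, outcome, prior
    new_clades: list[str]
    clades_with_additions: list[str]
    clades_losing_members: list[str]

    @property
    def n_new_clades(self) -> int:
        return len(self.new_clades)

    @property
    def n_clades_with_additions(self) -> int:
        return len(self.clades_with_additions)

    @property
    def n_clades_losing_members(self) -> int:
        return len(self.clades_losing_members)

    def to_tsv(self, path) -> None:
        write_tsv(self.outcomes, path, comment=(
            f"new clades: {', '.join(self.new_clades) or 'none'}\n"
            f"clades with additions: {', '.join(self.clades_with_additions) or 'none'}\n"
            f"clades losing members: {', '.join(self.clades_losing_members) or 'none'}"))


class AmbiguousMatchError(ValueError):
    pass


def reconcile_registry(calls: Sequence[Sequence[str] | CladeCall],
                       prior: CladeRegistry,
                       prefix: str = "TALE",
                       match_threshold: float = 0.5,
                       ) -> tuple[CladeRegistry, RevisionReport]:
    """Reconcile called clades against a prior registry.

    Each call (a set of ``species|sequence`` members) is matched to at most
    one prior clade by Jaccard overlap over previously classified members
    (> ``match_threshold``); a call matching two prior clades is an
    ambiguity error.  Per sequence the outcome is ``unchanged``,
    ``added`` (origin N, a sequence the prior registry did not classify),
    ``reclassified`` (moved between clades, prior classification recorded) or
    ``new-clade`` membership; unmatched calls receive the next unused Roman
    numerals of the series.
    """
    prior_class = prior.classification_of()
    member_sets = []
    for call in calls:
        members = tuple(call.members) if isinstance(call, CladeCall) else tuple(call)
        member_sets.append(members)

    prior_clades = {c: prior.members_of(c) for c in prior.clades()
                    if _is_classified(c)}

    assigned: dict[int, str] = {}
    for idx, members in enumerate(member_sets):
        classified = {m for m in members if m in prior_class}
        matches = []
        for clade, prior_members in prior_clades.items():
            if not prior_members:
                continue
            inter = len(classified & prior_members)
            union = len(classified | prior_members)
            if union and inter / union > match_threshold:
                matches.append(clade)
        if len(matches) > 1:
            raise AmbiguousMatchError(
                f"call {idx} matches multiple prior clades: {sorted(matches)}")
        if matches:
            assigned[idx] = matches[0]

    next_numeral = prior.max_numeral(prefix) + 1
    new_clades: list[str] = []
    for idx, members in enumerate(member_sets):
        if idx not in assigned:
            name = f"{prefix}-{to_roman(next_numeral)}"
            next_numeral += 1
            assigned[idx] = name
            new_clades.append(name)

    rows = []
    outcome_rows = []
    additions: set[str] = set()
    losing: set[str] = set()
    placed: set[str] = set()
    for idx, members in enumerate(member_sets):
        clade = assigned[idx]
        is_new = clade in new_clades
        for m in sorted(members):
            sp, seq = split_member(m)
            placed.add(m)
            was = prior_class.get(m)
            if was == clade:
                outcome, origin, prior_name = "unchanged", "P", was
            elif was is not None and _is_classified(was):
                outcome, origin, prior_name = "reclassified", "P", was
                losing.add(was)
            else:
                outcome = "new-clade" if is_new else "added"
                origin, prior_name = "N", "NONE"
                if not is_new:
                    additions.add(clade)
            rows.append({"clade": clade, "species": sp, "sequence": seq,
                         "letter": "", "origin": origin, "prior": prior_name or "NONE"})
            outcome_rows.append({"member": m, "species": sp, "sequence": seq,
                                 "clade": clade, "outcome": outcome,
                                 "prior": prior_name or "NONE"})
    # prior members present in no call lose their placement
    for m, clade in prior_class.items():
        if m not in placed and _is_classified(clade):
            losing.add(clade)
            sp, seq = split_member(m)
            outcome_rows.append({"member": m, "species": sp, "sequence": seq,
                                 "clade": "NONE", "outcome": "unplaced",
                                 "prior": clade})

    registry = CladeRegistry(pd.DataFrame(rows, columns=list(CladeRegistry.COLUMNS)))
    registry = assign_letters(registry)
    report = RevisionReport(
        outcomes=pd.DataFrame(outcome_rows,
                              columns=["member", "species", "sequence", "clade",
                                       "outcome", "prior"]),
        new_clades=new_clades,
        clades_with_additions=sorted(additions),
        clades_losing_members=sorted(losing),
    )
    return registry, report


def assign_letters(registry: CladeRegistry) -> CladeRegistry:
    """Fill paralogue letters within each (clade, species) group.

    Members are lettered A, B, C, ... in sequence-name order; a species with
    a single member in the clade keeps an empty letter.  Letters already
    present are preserved, and new members receive the first unused letters,
    so lettering is stable across re-runs.  Beyond Z, double letters follow.
    """

    def letter(i: int) -> str:
        out = ""
        i += 1
        while i:
            i, r = divmod(i - 1, 26)
            out = chr(ord("A") + r) + out
        return out

    frame = registry.frame.copy()
    for (_, _), idx in frame.groupby(["clade", "species"]).groups.items():
        group = frame.loc[idx].sort_values("sequence")
        existing = {l for l in group["letter"] if l}
        if len(group) == 1 and not existing:
            continue
        used = set(existing)
        counter = 0
        for row_idx in group.index:
            if frame.at[row_idx, "letter"]:
                continue
            while letter(counter) in used:
                counter += 1
            frame.at[row_idx, "letter"] = letter(counter)
            used.add(letter(counter))
    return CladeRegistry(frame)


# ---------------------------------------------------------------------------
# the shipped TALE revision table


def load_revision_table(path=None) -> pd.DataFrame:
    """Load the revised TALE-class registry shipped with the package."""
    if path is None:
        from importlib.resources import files

        path = files("homeoscan.data").joinpath("tale_registry_revised.tsv")
    return read_tsv(str(path))


def revision_inputs(table: pd.DataFrame, prefix: str = "TALE"):
    """Split a revised registry table into reconciliation inputs.

    Returns ``(prior, calls)``: the prior registry reconstructed from the
    rows carried over from the earlier classification (origin P, placed at
    their previous clade), and the called clades (current membership of every
    named clade, ordered by numeral; the unclassified group is not a call).
    """
    prior_rows = table[table["origin"] == "P"].copy()
    prior_rows["clade"] = prior_rows["prior"]
    prior_rows = prior_rows.assign(letter="", origin="P", prior="NONE")
    prior = CladeRegistry(prior_rows[list(CladeRegistry.COLUMNS)].reset_index(drop=True))

    def numeral(clade: str) -> int:
        try:
            return from_roman(clade[len(prefix) + 1 :])
        except ValueError:
            return 10**6

    named = table[table["clade"] != "unclassified"]
    calls = [
        tuple(sorted(f"{r.species}|{r.sequence}" for r in grp.itertuples()))
        for _, grp in sorted(named.groupby("clade"), key=lambda kv: numeral(kv[0]))
    ]
    return prior, calls


# ---------------------------------------------------------------------------
# collapsing


def collapse_clades(tree: dendropy.Tree,
                    calls: Mapping[str, Sequence[str]],
                    ) -> dendropy.Tree:
    """Replace each named clade by a single labeled tip.

    ``calls`` maps the collapsed tip label to the clade's leaf members; the
    selected clades must be non-overlapping, and each must be an exact clade
    of the (rooted) tree.  Supports on collapsed internal nodes are discarded
    with the nodes themselves.
    """
    tree = tree.clone(depth=1)
    seen: set[str] = set()
    for name, members in calls.items():
        overlap = seen.intersection(members)
        if overlap:
            raise ValueError(f"collapse targets overlap on {sorted(overlap)}")
        seen.update(members)
    for name, members in calls.items():
        member_set = set(members)
        node = None
        for cand in tree.preorder_internal_node_iter():
            clade = {lf.taxon.label for lf in cand.leaf_iter()}
            if clade == member_set:
                node = cand
                break
        if node is None:
            if len(member_set) == 1:
                continue  # single leaf: just relabel below
            raise ValueError(f"{name}: members are not an exact clade of the tree")
        for child in list(node.child_nodes()):
            node.remove_child(child)
        node.taxon = tree.taxon_namespace.new_taxon(name)
        node.label = None
    # relabel single-leaf "clades"
    for name, members in calls.items():
        if len(set(members)) == 1:
            (only,) = set(members)
            for lf in tree.leaf_node_iter():
                if lf.taxon is not None and lf.taxon.label == only:
                    lf.taxon = tree.taxon_namespace.new_taxon(name)
    return tree
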