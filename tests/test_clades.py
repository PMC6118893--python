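import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from homeoscan.clades import (AmbiguousMatchError, CladeCriteria, CladeRegistry,
                              assign_letters, call_clades, collapse_clades,
                              from_roman, reconcile_registry, to_roman)
from homeoscan.io import read_newick
from homeoscan.reconcile import SupportTriplet, transfer_support


# ---------------------------------------------------------------------------
# roman numerals


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(1, 500))
def test_roman_roundtrip(n):
    assert from_roman(to_roman(n)) == n


def test_series_continues_after_xix():
    assert to_roman(from_roman("XIX") + 1) == "XX"


# ---------------------------------------------------------------------------
# calling


def _annotated(newick_target, nj=None):
    target = read_newick(newick_target, rooting="force-rooted")
    return transfer_support(target, nj=nj, bayes=target)


def _tree_with_triplets(triplets):
    """A star-free 6-leaf tree whose cherry nodes carry the given triplets."""
    target = read_newick("(((A,B),(C,D)),(E,F));", rooting="force-rooted")
    at = transfer_support(target)
    wanted = {("A", "B"): 0, ("C", "D"): 1, ("E", "F"): 2}
    for nid in list(at.triplets):
        key = at.members(nid)
        if key in wanted and wanted[key] < len(triplets):
            at.triplets[nid] = triplets[wanted[key]]
    return at


def test_below_threshold_with_absent_slot_is_not_a_clade():
    at = _tree_with_triplets([SupportTriplet(None, 65.0, 0.60)])
    calls = call_clades(at, CladeCriteria())
    assert ("A", "B") not in {c.members for c in calls}


def test_all_three_analyses_qualify_despite_low_support():
    at = _tree_with_triplets([SupportTriplet(500.0, 60.0, 0.65)])
    calls = {c.members: c for c in call_clades(at, CladeCriteria())}
    assert calls[("A", "B")].justification == "all-three"


def test_structure_evidence_qualifies_a_weak_node():
    at = _tree_with_triplets([SupportTriplet(None, 40.0, 0.50)])
    node_id = [n for n in at.triplets if at.members(n) == ("A", "B")][0]
    crit = CladeCriteria(structureEvidence={node_id: "two-homeodomain architecture"})
    calls = {c.members: c for c in call_clades(at, crit)}
    assert calls[("A", "B")].justification == "structure"


def test_support_takes_precedence_and_strictness():
    at = _tree_with_triplets([SupportTriplet(710.0, 60.0, 0.60)])
    calls = {c.members: c for c in call_clades(at, CladeCriteria())}
    assert calls[("A", "B")].justification == "support"
    # exactly 70% with strict threshold does not qualify on support
    at = _tree_with_triplets([SupportTriplet(700.0, None, 0.60)])
    calls = {c.members: c for c in call_clades(at, CladeCriteria())}
    assert ("A", "B") not in calls
    at = _tree_with_triplets([SupportTriplet(700.0, None, 0.60)])
    calls = {c.members: c for c in
             call_clades(at, CladeCriteria(requireStrict=False))}
    assert calls[("A", "B")].justification == "support"


# ---------------------------------------------------------------------------
# registry reconciliation


def _registry(rows):
    return CladeRegistry(pd.DataFrame(
        rows, columns=["clade", "species", "sequence", "letter", "origin", "prior"]))


def _prior_six():
    return _registry([
        ("TALE-VI", "C.gigas", f"g{i}", "", "P", "NONE") for i in range(3)
    ])


def test_fixed_point_no_changes():
    prior = _prior_six()
    calls = [tuple(sorted(prior.members_of("TALE-VI")))]
    registry, report = reconcile_registry(calls, prior)
    assert report.n_new_clades == 0
    assert report.n_clades_with_additions == 0
    assert report.n_clades_losing_members == 0
    assert set(registry.members_of("TALE-VI")) == prior.members_of("TALE-VI")


def test_new_members_become_origin_n_additions():
    prior = _prior_six()
    call = tuple(sorted(prior.members_of("TALE-VI")) + ["S.lamarcki|newA",
                                                        "S.lamarcki|newB"])
    registry, report = reconcile_registry([call], prior)
    assert report.clades_with_additions == ["TALE-VI"]
    added = registry.frame[registry.frame.origin == "N"]
    assert sorted(added.sequence) == ["newA", "newB"]
    assert set(added.clade) == {"TALE-VI"}


def test_unmatched_call_erects_next_numeral():
    prior = _registry([("TALE-XIX", "H.robusta", "a", "", "P", "NONE"),
                       ("TALE-XIX", "H.robusta", "b", "", "P", "NONE")])
    registry, report = reconcile_registry(
        [("X.species|n1", "X.species|n2")], prior)
    assert report.new_clades == ["TALE-XX"]


def test_reclassification_recorded_with_prior():
    prior = _registry([("TALE-IV", "C.teleta", "x", "", "P", "NONE"),
                       ("TALE-VIII", "C.teleta", "y1", "", "P", "NONE"),
                       ("TALE-VIII", "C.teleta", "y2", "", "P", "NONE")])
    call = ("C.teleta|x", "C.teleta|y1", "C.teleta|y2")
    registry, report = reconcile_registry([call], prior)
    moved = report.outcomes[report.outcomes.outcome == "reclassified"]
    assert list(moved.member) == ["C.teleta|x"]
    assert list(moved.prior) == ["TALE-IV"]
    assert report.clades_losing_members == ["TALE-IV"]


def test_ambiguous_match_raises_listing_both():
    prior = _registry([("TALE-I", "s", "a1", "", "P", "NONE"),
                       ("TALE-I", "s", "a2", "", "P", "NONE"),
                       ("TALE-II", "s", "b1", "", "P", "NONE"),
                       ("TALE-II", "s", "b2", "", "P", "NONE")])
    call = ("s|a1", "s|a2", "s|b1", "s|b2")
    with pytest.raises(AmbiguousMatchError, match="TALE-I.*TALE-II"):
        reconcile_registry([call], prior, match_threshold=0.4)


def test_reconciliation_idempotent():
    prior = _prior_six()
    call = tuple(sorted(prior.members_of("TALE-VI")) + ["S.lamarcki|new"])
    registry1, _ = reconcile_registry([call], prior)
    registry2, report2 = reconcile_registry([call], registry1)
    assert report2.n_new_clades == 0 and report2.n_clades_with_additions == 0
    assert report2.n_clades_losing_members == 0
    # membership, naming and lettering are stable (the origin flag is always
    # relative to the prior registry, so a round-1 addition reads P in round 2)
    cols = ["clade", "species", "sequence", "letter"]
    pd.testing.assert_frame_equal(
        registry1.frame[cols].reset_index(drop=True),
        registry2.frame[cols].reset_index(drop=True))


# ---------------------------------------------------------------------------
# lettering


def test_eight_same_species_members_letter_a_to_h():
    reg = _registry([("TALE-VIII", "S.lamarcki", f"seq{i}", "", "N", "NONE")
                     for i in range(8)])
    out = assign_letters(reg)
    assert sorted(out.frame.letter) == list("ABCDEFGH")


def test_single_member_clade_gets_no_letter():
    reg = _registry([("TALE-XIV", "S.lamarcki", "only", "", "N", "NONE")])
    assert assign_letters(reg).frame.letter.tolist() == [""]


def test_letters_fill_from_b_when_a_is_occupied():
    rows = [("TALE-XIX", "H.robusta", "anchor", "A", "N", "NONE")]
    rows += [("TALE-XIX", "H.robusta", f"m{i:02d}", "", "N", "NONE")
             for i in range(15)]
    out = assign_letters(_registry(rows))
    new_letters = out.frame[out.frame.sequence != "anchor"].letter.tolist()
    assert new_letters == list("BCDEFGHIJKLMNOP")


def test_double_letters_beyond_z():
    rows = [("TALE-I", "s", f"q{i:03d}", "", "N", "NONE") for i in range(28)]
    out = assign_letters(_registry(rows))
    assert out.frame.letter.tolist()[-2:] == ["AA", "AB"]
    assert len(set(out.frame.letter)) == 28


# ---------------------------------------------------------------------------
# collapsing


def test_collapse_nothing_is_identity():
    tree = read_newick("((A,B),((C,D),(E,F)));", rooting="force-rooted")
    out = collapse_clades(tree, {})
    assert sorted(l.taxon.label for l in out.leaf_node_iter()) == \
        ["A", "B", "C", "D", "E", "F"]


def test_collapse_reduces_leaf_count_arithmetically():
    newick = "((((A,B),(C,D)),((E,F),(G,H))),(I,J));"
    tree = read_newick(newick, rooting="force-rooted")
    out = collapse_clades(tree, {"cladeX": ["A", "B", "C", "D"]})
    labels = sorted(l.taxon.label for l in out.leaf_node_iter())
    assert len(labels) == 7 and "cladeX" in labels


def test_collapsed_tip_labels_reproduce_call_names():
    tree = read_newick("((((A,B),(C,D)),((E,F),(G,H))),(I,J));",
                       rooting="force-rooted")
    calls = {"left": ["A", "B"], "right": ["E", "F", "G", "H"]}
    out = collapse_clades(tree, calls)
    labels = {l.taxon.label for l in out.leaf_node_iter()}
    assert {"left", "right"} <= labels


def test_overlapping_collapse_targets_rejected():
    tree = read_newick("((A,B),((C,D),(E,F)));", rooting="force-rooted")
    with pytest.raises(ValueError, match="overlap"):
        collapse_clades(tree, {"x": ["A", "B"], "y": ["B", "C"]})


def test_non_clade_members_rejected():
    tree = read_newick("((A,B),((C,D),(E,F)));", rooting="force-rooted")
    with pytest.raises(ValueError, match="exact clade"):
        collapse_clades(tree, {"x": ["A", "C"]})
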