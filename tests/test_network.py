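"""Network construction: threshold strictness, membership edges, subnetworks."""

import numpy as np
import pytest

from herbnet.core import HerbnetError, PathwayGeneSet
from herbnet.network import (
    build_network,
    extract_effector_subnetwork,
    filter_interactions,
    restrict_to_effectors,
)
from tests.conftest import interactions_frame, random_instance


def test_filter_is_strictly_greater_than():
    raw = interactions_frame([("c", "a", 40.0), ("c", "b", 40.1), ("c", "d", 95.0)])
    kept = filter_interactions(raw, 40.0)
    assert set(kept["target_id"]) == {"b", "d"}
    assert len(filter_interactions(raw, 0.0)) == 3  # all-positive identity


def test_filter_matches_linear_scan_oracle():
    rng = np.random.default_rng(11)
    raw, _ = random_instance(rng, n_edges=120, score_lo=0, score_hi=80)
    kept = filter_interactions(raw, 40.0)
    oracle = {(r.compound_id, r.target_id) for r in raw.itertuples() if r.score > 40.0}
    assert {(r.compound_id, r.target_id) for r in kept.itertuples()} == oracle


def test_restrict_to_effectors_selects_warns_and_errors():
    sets = [PathwayGeneSet(f"p{i}", "", frozenset({"x"})) for i in range(5)]
    out = restrict_to_effectors(sets, {"p1", "p3"})
    assert [s.pathway_id for s in out] == ["p1", "p3"]
    out = restrict_to_effectors(sets, {"p2", "nope"})  # absent id: warn + omit
    assert [s.pathway_id for s in out] == ["p2"]
    with pytest.raises(HerbnetError):
        restrict_to_effectors(sets, {"nope"})


def test_build_network_hand_case(hand_network):
    net = hand_network
    assert net.targets == {"A"}
    assert net.compounds == {"c1", "c2"}
    assert net.tp_edges == {("A", "P1")}
    assert len(net.ct_edges) == 2


def test_target_in_no_gene_set_kept_without_membership_edge():
    raw = interactions_frame([("c1", "A", 50.0), ("c1", "Z", 70.0)])
    net = build_network(raw, [PathwayGeneSet("P1", "", frozenset({"A"}))], 40.0)
    assert "Z" in net.targets
    assert all(t != "Z" for t, _ in net.tp_edges)


def test_build_network_matches_set_comprehension_oracle():
    rng = np.random.default_rng(3)
    raw, sets = random_instance(rng, n_compounds=30, n_edges=150)
    net = build_network(raw, sets, threshold=40.0)
    kept = raw.loc[raw["score"] > 40.0]
    targets = set(kept["target_id"])
    assert net.targets == targets
    assert net.compounds == set(kept["compound_id"])
    want_tp = {(t, s.pathway_id) for s in sets for t in s.members & targets}
    assert net.tp_edges == want_tp
    assert {p.pathway_id for p in net.pathways} == {pid for _, pid in want_tp}


def test_build_network_idempotent_and_threshold_monotone():
    rng = np.random.default_rng(9)
    raw, sets = random_instance(rng, n_edges=100)
    net = build_network(raw, sets, threshold=40.0)
    again = build_network(net.ct_edges, sets, threshold=40.0)
    assert again.targets == net.targets and again.tp_edges == net.tp_edges
    assert len(again.ct_edges) == len(net.ct_edges)
    higher = build_network(raw, sets, threshold=60.0)
    assert higher.targets <= net.targets
    assert higher.compounds <= net.compounds
    assert higher.tp_edges <= net.tp_edges


def test_empty_result_is_hard_error():
    raw = interactions_frame([("c1", "A", 10.0)])
    with pytest.raises(HerbnetError):
        build_network(raw, [PathwayGeneSet("P1", "", frozenset({"A"}))], 40.0)


def test_effector_subnetwork_hand_and_disjoint(hand_network):
    sub = extract_effector_subnetwork(
        hand_network, PathwayGeneSet("eff", "", frozenset({"A"}))
    )
    assert len(sub.ct_edges) == 2 and sub.targets == {"A"}
    empty = extract_effector_subnetwork(
        hand_network, PathwayGeneSet("eff2", "", frozenset({"Z"}))
    )
    assert not empty.targets and len(empty.ct_edges) == 0


def test_effector_subnetwork_matches_induced_subgraph_oracle():
    rng = np.random.default_rng(21)
    raw, sets = random_instance(rng, n_edges=120)
    net = build_network(raw, sets, threshold=30.0)
    eff = sets[0]
    sub = extract_effector_subnetwork(net, eff)
    want_targets = net.targets & eff.members
    want_edges = {
        (r.compound_id, r.target_id)
        for r in net.ct_edges.itertuples()
        if r.target_id in want_targets
    }
    assert sub.targets == want_targets
    assert {(r.compound_id, r.target_id) for r in sub.ct_edges.itertuples()} == want_edges
    assert sub.compounds == {c for c, _ in want_edges}
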