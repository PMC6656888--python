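"""RCN/BS arithmetic, min-max adjustment, ranking and reference validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.core import PathwayGeneSet, UsageError
from herbnet.network import build_network
from herbnet.scoring import (
    compute_bs,
    compute_rcn,
    minmax_adjust,
    score_pathways,
    validate_against_reference,
)
from tests.conftest import interactions_frame, random_instance


def _net(rows, sets, threshold=0.0):
    return build_network(interactions_frame(rows), sets, threshold)


def test_rcn_and_bs_hand_cases():
    # T1: compounds c1,c2,c3 (max 80); T2: c1 only (score 60)
    net = _net(
        [("c1", "T1", 55.0), ("c2", "T1", 80.0), ("c3", "T1", 70.0), ("c1", "T2", 60.0)],
        [PathwayGeneSet("P", "", frozenset({"T1", "T2"}))],
    )
    assert compute_rcn(net, "P") == pytest.approx((3 + 1) / 2)
    assert compute_bs(net, "P") == pytest.approx((80 + 60) / 2)


def test_single_target_pathway():
    net = _net(
        [(f"c{i}", "T", 42.0) for i in range(5)],
        [PathwayGeneSet("P", "", frozenset({"T"}))],
    )
    assert compute_rcn(net, "P") == 5.0
    assert compute_bs(net, "P") == 42.0


def test_pathway_lookup_error(hand_network):
    with pytest.raises(KeyError):
        compute_rcn(hand_network, "nope")


def brute_force_scores(net, pathway_id):
    """Exhaustive per-target scan over the raw edge tuples."""
    edges = list(net.ct_edges.itertuples(index=False))
    targets = sorted(net.pathway_targets(pathway_id))
    rcn_terms, bs_terms = [], []
    for t in targets:
        comps = {c for c, tt, s in edges if tt == t}
        scores = [s for c, tt, s in edges if tt == t]
        rcn_terms.append(len(comps))
        bs_terms.append(max(scores))
    return sum(rcn_terms) / len(targets), sum(bs_terms) / len(targets)


def test_scores_match_bruteforce_on_random_networks():
    rng = np.random.default_rng(17)
    for _ in range(20):
        raw, sets = random_instance(rng, n_edges=100)
        net = build_network(raw, sets, threshold=30.0)
        for p in net.pathways:
            rcn_o, bs_o = brute_force_scores(net, p.pathway_id)
            assert compute_rcn(net, p.pathway_id) == pytest.approx(rcn_o, abs=1e-12)
            assert compute_bs(net, p.pathway_id) == pytest.approx(bs_o, abs=1e-12)


def test_minmax_endpoints_and_degenerate():
    assert minmax_adjust([2, 5, 8]) == [0.0, 0.5, 1.0]
    assert minmax_adjust([3, 3]) == [0.5, 0.5]
    with pytest.raises(UsageError):
        minmax_adjust([])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
def test_minmax_order_preserved_and_bounded(values):
    out = minmax_adjust(values)
    assert all(0.0 <= v <= 1.0 for v in out)
    order = np.argsort(values, kind="stable")
    assert all(out[order[i]] <= out[order[i + 1]] + 1e-12 for i in range(len(out) - 1))
    if max(values) > min(values):
        assert out[int(np.argmin(values))] == 0.0
        assert out[int(np.argmax(values))] == 1.0


def test_score_pathways_dominant_and_degenerate():
    rows = [("c1", "A", 90.0), ("c2", "A", 95.0), ("c3", "A", 85.0), ("c1", "B", 50.0)]
    sets = [
        PathwayGeneSet("big", "", frozenset({"A"})),
        PathwayGeneSet("small", "", frozenset({"B"})),
    ]
    df = score_pathways(_net(rows, sets)).set_index("pathway_id")
    assert df.loc["big", "aggregate"] == 1.0 and df.loc["big", "rank"] == 1
    assert df.loc["small", "aggregate"] == 0.0 and df.loc["small", "rank"] == 2
    one = score_pathways(_net(rows, sets[:1]))
    assert one.loc[0, "aggregate"] == 0.5 and one.loc[0, "rank"] == 1


def test_score_pathways_edge_order_invariance():
    rng = np.random.default_rng(4)
    raw, sets = random_instance(rng, n_edges=90)
    net1 = build_network(raw, sets, 30.0)
    shuffled = raw.sample(frac=1.0, random_state=1).reset_index(drop=True)
    net2 = build_network(shuffled, sets, 30.0)
    a = score_pathways(net1)
    b = score_pathways(net2)
    assert a.drop(columns=["name"]).to_dict("records") == \
        b.drop(columns=["name"]).to_dict("records")


def hypergeom_tail_oracle(k, N, K, n):
    denom = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / denom


def test_reference_validation_identity_and_disjoint():
    pred = interactions_frame([("c1", "A", 50.0), ("c2", "B", 60.0)])
    report = validate_against_reference(pred, pred, universe_size=10)
    assert report["precision"] == 1.0 and report["recall"] == 1.0
    other = interactions_frame([("c9", "Z", 70.0)])
    report = validate_against_reference(pred, other, universe_size=10)
    assert report["precision"] == 0.0 and report["recall"] == 0.0
    assert report["p_value"] == pytest.approx(1.0)


def test_reference_validation_p_matches_enumeration():
    rng = np.random.default_rng(2)
    universe = [(f"c{i}", f"t{j}") for i in range(5) for j in range(6)]  # N = 30
    pred_pairs = [universe[i] for i in rng.choice(30, size=8, replace=False)]
    ref_pairs = [universe[i] for i in rng.choice(30, size=10, replace=False)]
    pred = interactions_frame([(c, t, 50.0) for c, t in pred_pairs])
    ref = interactions_frame([(c, t, 50.0) for c, t in ref_pairs])
    rep = validate_against_reference(pred, ref, universe_size=30)
    want = hypergeom_tail_oracle(rep["overlap"], 30, 10, 8)
    assert rep["p_value"] == pytest.approx(want, rel=1e-10)
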