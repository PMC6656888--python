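"""Pathway relevance scoring: RCN, BS, min-max adjustment and ranking.

For a pathway P_j with n drug-targeted members T_1..T_n,

    RCN_Pj = (sum_i C_Ti) / n      C_Ti = number of distinct compounds
                                          with a retained edge to T_i
    BS_Pj  = (sum_i max S_Ti) / n  max over T_i's retained edge scores

Both columns are min-max adjusted across the m scored pathways and
combined into an aggregate relevance index (default: their unweighted
mean), which ranks pathways by relevance to the drug.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TripartiteNetwork, UsageError

#: Output of all-equal min-max adjustment: mid-scale, asserting no extremity.
DEGENERATE_ADJUSTED = 0.5


def compute_rcn(net: TripartiteNetwork, pathway_id: str) -> float:
    """Mean, over the pathway's targeted members, of distinct compound count."""
    targets = net.pathway_targets(pathway_id)
    if not targets:
        raise KeyError(f"pathway {pathway_id!r} has no targeted member")
    counts = net.ct_edges.groupby("target_id")["compound_id"].nunique()
    return float(sum(counts[t] for t in targets) / len(targets))


def compute_bs(net: TripartiteNetwork, pathway_id: str) -> float:
    """Mean, over the pathway's targeted members, of the max edge score."""
    targets = net.pathway_targets(pathway_id)
    if not targets:
        raise KeyError(f"pathway {pathway_id!r} has no targeted member")
    maxima = net.ct_edges.groupby("target_id")["score"].max()
    return float(sum(maxima[t] for t in targets) / len(targets))


def minmax_adjust(values: Sequence[float]) -> list[float]:
    """Min-max adjust a list to [0, 1]; all-equal lists map to 0.5.

    The degenerate all-equal case carries no discriminating information,
    so every value maps to mid-scale rather than to an arbitrary extreme.
    """
    if len(values) == 0:
        raise UsageError("minmax_adjust: empty list")
    arr = np.asarray(values, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return [DEGENERATE_ADJUSTED] * len(arr)
    return [float(v) for v in (arr - lo) / (hi - lo)]


def score_pathways(net: TripartiteNetwork, weight: float = 0.5) -> pd.DataFrame:
    """Score and rank every pathway in the network.

    aggregate = weight * adj_rcn + (1 - weight) * adj_bs.  Ranks descend
    by aggregate with deterministic tie-breaking (raw BS desc, raw RCN
    desc, pathway_id asc), so output is byte-reproducible.

    Returns a frame with columns pathway_id, name, n, rcn, bs, adj_rcn,
    adj_bs, aggregate, rank — sorted by rank.
    """
    if not 0.0 <= weight <= 1.0:
        raise UsageError("aggregate weight must lie in [0, 1]")
    if not net.pathways:
        raise UsageError("network has no scorable pathway")
    rows = []
    for p in net.pathways:
        n = len(net.pathway_targets(p.pathway_id))
        rows.append({
            "pathway_id": p.pathway_id,
            "name": p.name,
            "n": n,
            "rcn": compute_rcn(net, p.pathway_id),
            "bs": compute_bs(net, p.pathway_id),
        })
    df = pd.DataFrame(rows)
    df["adj_rcn"] = minmax_adjust(df["rcn"].tolist())
    df["adj_bs"] = minmax_adjust(df["bs"].tolist())
    df["aggregate"] = weight * df["adj_rcn"] + (1.0 - weight) * df["adj_bs"]
    df = df.sort_values(
        by=["aggregate", "bs", "rcn", "pathway_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def validate_against_reference(
    predicted: pd.DataFrame, reference: pd.DataFrame, universe_size: int
) -> dict:
    """Compare predicted interactions against a high-confidence reference set.

    Both tables follow the interaction-frame contract; pairs are compared
    as (compound_id, target_id) sets.  The enrichment p-value is the
    one-sided hypergeometric tail: the probability that a random draw of
    |predicted| pairs from a universe of ``universe_size`` possible pairs
    containing |reference| true pairs hits at least |overlap| of them.
    """
    pred = set(zip(predicted["compound_id"], predicted["target_id"]))
    ref = set(zip(reference["compound_id"], reference["target_id"]))
    if not ref:
        raise UsageError("reference interaction set is empty")
    union = pred | ref
    if universe_size < len(union):
        raise UsageError(
            f"universe_size {universe_size} smaller than |predicted ∪ reference| = {len(union)}"
        )
    k = len(pred & ref)
    precision = k / len(pred) if pred else 0.0
    recall = k / len(ref)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(ref), len(pred)))
    return {
        "n_predicted": len(pred),
        "n_reference": len(ref),
        "overlap": k,
        "precision": precision,
        "recall": recall,
        "p_value": min(p, 1.0),
        "universe_size": universe_size,
    }
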