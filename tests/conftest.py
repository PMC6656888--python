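import numpy as np
import pandas as pd
import pytest

from herbnet.core import PathwayGeneSet
from herbnet.network import build_network


def interactions_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "score"])


@pytest.fixture
def hand_network():
    """Two compounds, targets A/B, one gene set; threshold 40 drops c2-B."""
    raw = interactions_frame(
        [("c1", "A", 50.0), ("c2", "A", 60.0), ("c2", "B", 30.0)]
    )
    sets = [PathwayGeneSet("P1", "set one", frozenset({"A", "B"}))]
    return build_network(raw, sets, threshold=40.0)


def random_instance(rng, n_compounds=15, n_targets=12, n_pathways=4,
                    pathway_size=4, n_edges=60, score_lo=0.0, score_hi=100.0):
    """Small random interaction table + gene sets for oracle comparisons."""
    compounds = [f"c{i}" for i in range(n_compounds)]
    targets = [f"t{i}" for i in range(n_targets)]
    n_edges = min(n_edges, n_compounds * n_targets)
    pairs = set()
    while len(pairs) < n_edges:
        pairs.add((compounds[rng.integers(n_compounds)], targets[rng.integers(n_targets)]))
    rows = [(c, t, float(rng.uniform(score_lo, score_hi))) for c, t in sorted(pairs)]
    sets = [
        PathwayGeneSet(
            f"pw{j}", f"pw{j}",
            frozenset(rng.choice(targets, size=pathway_size, replace=False).tolist()),
        )
        for j in range(n_pathways)
    ]
    return interactions_frame(rows), sets
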