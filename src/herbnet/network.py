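"""Construction of the effector-restricted compound-target-function network.

The network has three node layers: drug compounds, predicted protein
targets, and pathway/function gene sets.  Compound-target edges carry the
external predictor's confidence score and are kept only when that score
strictly exceeds a threshold (default 40); target-pathway edges record
gene-set membership of retained targets.  Gene sets are first restricted
to literature-curated, disease-relevant effector processes so that
downstream pathway scores reflect the disease context.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    HerbnetError,
    PathwayGeneSet,
    TripartiteNetwork,
    UsageError,
    as_interaction_frame,
)

logger = logging.getLogger("herbnet")

DEFAULT_THRESHOLD = 40.0


def filter_interactions(raw: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Retain interactions with score strictly greater than ``threshold``."""
    if threshold < 0:
        raise UsageError("threshold must be >= 0")
    raw = as_interaction_frame(raw)
    kept = raw.loc[raw["score"] > threshold].reset_index(drop=True)
    logger.info("filter_interactions: retained %d of %d rows at threshold %g",
                len(kept), len(raw), threshold)
    return kept


def restrict_to_effectors(
    gene_sets: Sequence[PathwayGeneSet], effector_processes: Iterable[str]
) -> list[PathwayGeneSet]:
    """Keep only gene sets whose id is in the effector-process list.

    Requested ids absent from ``gene_sets`` produce a warning; an empty
    result is a hard error because nothing downstream could be scored.
    """
    wanted = set(effector_processes)
    if not wanted:
        raise UsageError("effector_processes must be non-empty")
    present = {s.pathway_id for s in gene_sets}
    for missing in sorted(wanted - present):
        logger.warning("restrict_to_effectors: requested set %r not found", missing)
    out = [s for s in gene_sets if s.pathway_id in wanted]
    if not out:
        raise HerbnetError("no requested effector gene set found; nothing to score")
    return out


def build_network(
    interactions: pd.DataFrame,
    gene_sets: Sequence[PathwayGeneSet],
    threshold: float = DEFAULT_THRESHOLD,
) -> TripartiteNetwork:
    """Build the tripartite network from thresholded interactions.

    Targets enter the network only if they keep at least one edge;
    compounds only if they keep at least one edge; pathways only if at
    least one retained target belongs to them (a pathway with no targeted
    member cannot be scored).  Gene-set members that are not network
    targets simply contribute no membership edge (their count is logged).
    """
    kept = filter_interactions(interactions, threshold)
    if kept.empty:
        raise HerbnetError(f"no interaction survives threshold {threshold}")
    targets = frozenset(kept["target_id"])
    compounds = frozenset(kept["compound_id"])
    tp_edges = set()
    kept_sets = []
    n_unknown = 0
    for s in gene_sets:
        hits = s.members & targets
        n_unknown += len(s.members) - len(hits)
        if not hits:
            continue
        kept_sets.append(s)
        tp_edges.update((t, s.pathway_id) for t in hits)
    logger.info("build_network: %d compounds, %d targets, %d/%d pathways; "
                "%d gene-set members outside the network",
                len(compounds), len(targets), len(kept_sets), len(gene_sets), n_unknown)
    return TripartiteNetwork(
        compounds=compounds,
        targets=targets,
        pathways=tuple(kept_sets),
        ct_edges=kept,
        tp_edges=frozenset(tp_edges),
        threshold=float(threshold),
    )


def extract_effector_subnetwork(
    net: TripartiteNetwork, effector_gene_set: PathwayGeneSet
) -> TripartiteNetwork:
    """Induced subnetwork over one effector's member targets.

    Keeps the targets of ``net`` that belong to the effector gene set,
    every compound incident to them, and their compound-target edges.  An
    empty intersection yields an empty subnetwork with a warning, not an
    error (some effectors simply have no predicted target).
    """
    hit_targets = net.targets & effector_gene_set.members
    if not hit_targets:
        logger.warning("effector %r shares no target with the network",
                       effector_gene_set.pathway_id)
    e = net.ct_edges
    sub_edges = e.loc[e["target_id"].isin(hit_targets)].reset_index(drop=True)
    sub_compounds = frozenset(sub_edges["compound_id"])
    pathways = (effector_gene_set,) if hit_targets else ()
    tp = frozenset((t, effector_gene_set.pathway_id) for t in hit_targets)
    logger.info("effector %s: %d targets, %d compounds",
                effector_gene_set.pathway_id, len(hit_targets), len(sub_compounds))
    return TripartiteNetwork(
        compounds=sub_compounds,
        targets=frozenset(hit_targets),
        pathways=pathways,
        ct_edges=sub_edges,
        tp_edges=tp,
        threshold=net.threshold,
    )
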