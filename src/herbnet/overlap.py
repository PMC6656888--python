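"""Reconciling predicted network targets with proteomically identified proteins.

Predicted targets live in a gene-symbol namespace; identified proteins are
accessions.  A many-to-many mapping table bridges the two: a target counts
as identified if *any* of its mapped accessions (isoforms collapse to the
gene-level target) was identified, and as changed if any such accession
passes the differential test.  Targets with no mapping row are reported as
unmapped, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import replace as dc_replace

import pandas as pd

from .core import TripartiteNetwork


@dataclass(frozen=True)
class CoverageReport:
    """Predicted-vs-identified tally for one effector subnetwork."""

    label: str
    n_predicted: int
    n_identified: int
    identified_changed: int
    unmapped: int

    def as_ratio(self) -> str:
        return f"{self.n_identified}/{self.n_predicted}"


def _target_status(
    subnet: TripartiteNetwork,
    identified: set[str],
    mapping: pd.DataFrame,
    changed_accessions: set[str],
) -> dict[str, str]:
    by_target = mapping.groupby("target_id")["accession"].agg(set)
    status: dict[str, str] = {}
    for t in subnet.targets:
        accs = by_target.get(t, set())
        hit = accs & identified
        if not hit:
            status[t] = "predicted_only"
        elif hit & changed_accessions:
            status[t] = "identified_changed"
        else:
            status[t] = "identified_unchanged"
    return status


def coverage(
    subnet: TripartiteNetwork,
    identified: set[str],
    mapping: pd.DataFrame,
    diff: pd.DataFrame | None = None,
    label: str = "",
    alpha: float = 0.05,
) -> CoverageReport:
    """Coverage report for an effector subnetwork.

    ``identified`` is the set of accessions seen in the proteome; ``diff``
    is a differential frame (columns accession, p); a target is counted
    changed when a mapped, identified accession has p < ``alpha``.
    """
    changed = set()
    if diff is not None and len(diff):
        changed = set(diff.loc[diff["p"] < alpha, "accession"])
    status = _target_status(subnet, identified, mapping, changed)
    mapped_targets = set(mapping["target_id"])
    unmapped = sum(1 for t in subnet.targets if t not in mapped_targets)
    n_ident = sum(1 for s in status.values() if s != "predicted_only")
    n_changed = sum(1 for s in status.values() if s == "identified_changed")
    return CoverageReport(
        label=label or (subnet.pathways[0].pathway_id if subnet.pathways else ""),
        n_predicted=len(subnet.targets),
        n_identified=n_ident,
        identified_changed=n_changed,
        unmapped=unmapped,
    )


def annotate_network(
    subnet: TripartiteNetwork,
    identified: set[str],
    mapping: pd.DataFrame,
    diff: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> TripartiteNetwork:
    """Copy of the subnetwork with a status attribute on every target node.

    status ∈ {predicted_only, identified_unchanged, identified_changed};
    the attribute survives GraphML round trips via ``write_network``.
    """
    changed = set()
    if diff is not None and len(diff):
        changed = set(diff.loc[diff["p"] < alpha, "accession"])
    status = _target_status(subnet, identified, mapping, changed)
    return dc_replace(subnet, node_status=status)
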