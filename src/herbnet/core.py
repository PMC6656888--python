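"""Shared domain types and exceptions.

Tabular data (interaction tables, intensity matrices, mapping tables,
differential results) are plain :class:`pandas.DataFrame` objects with
documented column contracts; the classes here cover the structured objects
that a bare frame represents poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


class HerbnetError(Exception):
    """Base class for all package errors."""


class ParseError(HerbnetError):
    """A file does not conform to its declared dialect (carries location)."""


class ValidationError(HerbnetError):
    """Parsed data violates a domain invariant."""


class UsageError(HerbnetError):
    """The caller supplied inconsistent arguments or configuration."""


#: Column contract for interaction tables.
INTERACTION_COLUMNS = ["compound_id", "target_id", "score"]


@dataclass(frozen=True)
class Compound:
    """One chemical component of the drug, labelled with its herb of origin."""

    compound_id: str
    herb: str

    def __post_init__(self) -> None:
        if not self.herb:
            raise ValidationError(f"compound {self.compound_id!r}: empty herb label")


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence record (accession plus amino-acid string).

    The standard 20 residues plus the ambiguity codes X/B/Z and
    selenocysteine U are tolerated.
    """

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r}: empty sequence")


@dataclass(frozen=True)
class PathwayGeneSet:
    """A pathway / biological-process gene set (GMT line).

    ``members`` holds target identifiers; identifiers are opaque,
    case-sensitive strings (no symbol normalisation is attempted).
    """

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.pathway_id!r}: empty member list")


@dataclass
class GroupDesign:
    """Sample-to-group assignment plus the ordered exposure ladder.

    Parameters
    ----------
    groups
        Mapping ``sample_id -> group label``.
    ladder
        Group labels ordered from lowest to highest exposure, e.g.
        ``["control", "model", "low", "medium", "high"]``.  Arms that do
        not belong on the ladder (a positive-control drug arm, say) are
        listed in ``groups`` but omitted here.
    """

    groups: dict[str, str]
    ladder: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        present = set(self.groups.values())
        missing = [g for g in self.ladder if g not in present]
        if missing:
            raise ValidationError(f"ladder groups absent from design: {missing}")

    def samples(self, group: str) -> list[str]:
        """Sample ids assigned to ``group``, in insertion order."""
        return [s for s, g in self.groups.items() if g == group]

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g)
        return list(seen)

    def require_groups(self, labels: Iterable[str], min_n: int = 2) -> None:
        for g in labels:
            n = len(self.samples(g))
            if n == 0:
                raise UsageError(f"group {g!r} absent from design")
            if n < min_n:
                raise UsageError(f"group {g!r} has {n} sample(s); need >= {min_n}")


@dataclass
class TripartiteNetwork:
    """Compound-target-pathway network after score thresholding.

    ``ct_edges`` is an interaction frame (columns ``compound_id``,
    ``target_id``, ``score``) whose scores all strictly exceed the
    construction threshold; ``tp_edges`` are ``(target_id, pathway_id)``
    membership edges restricted to targets that survived thresholding.
    """

    compounds: frozenset[str]
    targets: frozenset[str]
    pathways: tuple[PathwayGeneSet, ...]
    ct_edges: pd.DataFrame
    tp_edges: frozenset[tuple[str, str]]
    threshold: float = 0.0
    node_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad_c = set(self.ct_edges["compound_id"]) - self.compounds
        bad_t = set(self.ct_edges["target_id"]) - self.targets
        if bad_c or bad_t:
            raise ValidationError(f"edge endpoints outside node sets: {bad_c | bad_t}")
        by_id = {p.pathway_id: p for p in self.pathways}
        for t, pid in self.tp_edges:
            if pid not in by_id or t not in by_id[pid].members:
                raise ValidationError(f"tp edge ({t!r}, {pid!r}) not backed by gene set")

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def pathway(self, pathway_id: str) -> PathwayGeneSet:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def pathway_targets(self, pathway_id: str) -> set[str]:
        """Targets participating in a pathway (the *n* of RCN/BS)."""
        self.pathway(pathway_id)  # raise KeyError if absent
        return {t for t, pid in self.tp_edges if pid == pathway_id}

    def compounds_of(self, target_id: str) -> set[str]:
        """Distinct compounds with a retained edge to ``target_id`` (C_Ti)."""
        e = self.ct_edges
        return set(e.loc[e["target_id"] == target_id, "compound_id"])

    def max_score(self, target_id: str) -> float:
        """Maximum retained prediction score incident to ``target_id``."""
        e = self.ct_edges
        return float(e.loc[e["target_id"] == target_id, "score"].max())


@dataclass
class IBAQTable:
    """Raw and total-normalised iBAQ values, proteins x samples.

    ``raw`` holds intensity / theoretical-peptide-count; ``norm`` divides
    each sample (column) by its raw-iBAQ total so that every column of
    ``norm`` sums to one.  Proteins with a zero theoretical-peptide count
    are excluded before either table is formed; their accessions are kept
    in ``excluded``.
    """

    raw: pd.DataFrame
    norm: pd.DataFrame
    excluded: tuple[str, ...] = ()

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def accessions(self) -> list[str]:
        return list(self.raw.index)


def as_interaction_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a frame to the interaction-table contract."""
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"interaction table missing columns: {missing}")
    out = df.loc[:, INTERACTION_COLUMNS].copy()
    out["score"] = pd.to_numeric(out["score"], errors="raise")
    if (out["score"] < 0).any():
        bad = out.loc[out["score"] < 0]
        raise ValidationError(f"negative interaction scores: {bad.to_dict('records')}")
    return out


def validate_intensity_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        raise ValidationError("duplicate protein accessions in intensity matrix")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in intensity matrix")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative intensities in matrix")
    return df
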