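"""Readers and writers for every external format the pipeline touches.

Formats: TSV (interactions, intensity matrix, mapping, group design),
GMT (gene sets), FASTA (protein sequences), GraphML and SIF (network
export).  All text is UTF-8, tab-separated where columnar, decimal point
".".  Lines starting with ``#`` in TSV inputs are treated as comments
(every table the pipeline writes carries a version/config header comment).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .core import (
    GroupDesign,
    IBAQTable,
    ParseError,
    PathwayGeneSet,
    ProteinSeq,
    TripartiteNetwork,
    UsageError,
    ValidationError,
    as_interaction_frame,
    validate_intensity_matrix,
)

logger = logging.getLogger("herbnet")


def read_interactions(path: str | Path, dedup_rule: str = "max") -> pd.DataFrame:
    """Read a compound-target interaction table.

    The file is tab-separated with header columns ``compound_id``,
    ``target_id``, ``score``.  Duplicate (compound, target) pairs are
    collapsed to their maximum score under ``dedup_rule="max"`` —
    consistent with using the maximum binding score per target downstream —
    or rejected under ``dedup_rule="error"``.
    """
    if dedup_rule not in {"max", "error"}:
        raise UsageError(f"unknown dedup_rule {dedup_rule!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("compound_id", "target_id", "score") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["compound_id"].isna().any() or df["target_id"].isna().any() or df["score"].isna().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +1 header, +1 zero-base
        raise ParseError(f"{path}: malformed row at line {bad}")
    try:
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric score: {exc}") from exc
    df = as_interaction_frame(df)
    n_raw = len(df)
    dup_mask = df.duplicated(subset=["compound_id", "target_id"], keep=False)
    n_dup_rows = int(dup_mask.sum())
    if n_dup_rows:
        if dedup_rule == "error":
            pairs = df.loc[dup_mask, ["compound_id", "target_id"]].drop_duplicates()
            raise ValidationError(
                f"{path}: duplicate interaction pairs: {pairs.to_records(index=False).tolist()}"
            )
        df = (
            df.groupby(["compound_id", "target_id"], as_index=False, sort=False)["score"].max()
        )
    logger.info(
        "read_interactions: %d rows read, %d after collapsing %d duplicate rows",
        n_raw, len(df), n_dup_rows - (n_raw - len(df)) if n_dup_rows else 0,
    )
    return df.reset_index(drop=True)


def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read gene sets in GMT dialect: ``id <tab> description <tab> member...``

    Duplicate members within a line are deduplicated with a warning; empty
    sets are dropped with a warning.
    """
    sets: list[PathwayGeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            pid, name, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning("%s:%d: %d duplicate member(s) in set %s dropped",
                               path, lineno, len(members) - len(uniq), pid)
            if not uniq:
                logger.warning("%s:%d: empty set %s dropped", path, lineno, pid)
                continue
            sets.append(PathwayGeneSet(pid, name, frozenset(uniq)))
    return sets


def write_gmt(sets: Iterable[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.pathway_id, s.name, *sorted(s.members)]) + "\n")


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    """Read protein FASTA; accession = first whitespace token after ``>``.

    Sequences are uppercased and wrapped lines concatenated.  Duplicate
    accessions and empty sequences are validation errors.
    """
    records: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValidationError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {acc!r}")
        records.append(ProteinSeq(acc, seq))
    return records


def write_fasta(records: Iterable[ProteinSeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein x sample intensity matrix (first column = accession)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return validate_intensity_matrix(df)


def read_design(path: str | Path, ladder: list[str] | None = None) -> GroupDesign:
    """Read a two-column design table: ``sample_id <tab> group``.

    An optional third column ``ladder_rank`` (integer, empty for off-ladder
    arms) encodes the exposure ladder; an explicit ``ladder`` argument
    overrides it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    groups = dict(zip(df["sample_id"], df["group"]))
    if ladder is None and "ladder_rank" in df.columns:
        ranked = df.dropna(subset=["ladder_rank"]).copy()
        ranked["ladder_rank"] = ranked["ladder_rank"].astype(int)
        ladder = list(
            ranked.sort_values("ladder_rank")["group"].drop_duplicates()
        )
    return GroupDesign(groups=groups, ladder=ladder or [])


def write_design(design: GroupDesign, path: str | Path) -> None:
    rank = {g: i for i, g in enumerate(design.ladder)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tladder_rank\n")
        for s, g in design.groups.items():
            r = rank.get(g, "")
            fh.write(f"{s}\t{g}\t{r}\n")


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a target-to-accession mapping table (many-to-many allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("target_id", "accession"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    n = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n:
        logger.warning("%s: %d duplicate mapping rows dropped", path, n - len(df))
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
                index: bool = False) -> None:
    """Write a TSV with an optional ``#`` header comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_ibaq(table: IBAQTable, path: str | Path, header_comment: str | None = None) -> None:
    """Write normalised iBAQ values (proteins x samples) as TSV."""
    df = table.norm.copy()
    df.index.name = "accession"
    write_table(df, path, header_comment=header_comment, index=True)


def read_ibaq(path: str | Path) -> IBAQTable:
    """Read a normalised-iBAQ TSV back into an :class:`IBAQTable`.

    The raw slot of the returned table holds the same values as the norm
    slot: downstream statistics operate on normalised values only.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return IBAQTable(raw=df, norm=df)


def _to_graph(net: TripartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    for c in sorted(net.compounds):
        g.add_node(c, node_type="compound")
    for t in sorted(net.targets):
        attrs = {"node_type": "target"}
        if t in net.node_status:
            attrs["status"] = net.node_status[t]
        g.add_node(t, **attrs)
    for p in net.pathways:
        g.add_node(p.pathway_id, node_type="pathway", name=p.name)
    for row in net.ct_edges.sort_values(["compound_id", "target_id"]).itertuples():
        g.add_edge(row.compound_id, row.target_id, relation="binds", score=float(row.score))
    for t, pid in sorted(net.tp_edges):
        g.add_edge(t, pid, relation="member_of")
    g.graph["threshold"] = float(net.threshold)
    return g


def write_network(net: TripartiteNetwork, path: str | Path,
                  format: Literal["graphml", "sif"] = "graphml") -> None:
    """Serialise a tripartite network.

    GraphML carries ``node_type`` on nodes and ``score`` on compound-target
    edges (plus ``status`` on annotated targets); SIF uses the relation
    labels ``binds`` and ``member_of``.
    """
    if format == "graphml":
        nx.write_graphml(_to_graph(net), str(path))
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for row in net.ct_edges.sort_values(["compound_id", "target_id"]).itertuples():
                fh.write(f"{row.compound_id}\tbinds\t{row.target_id}\n")
            for t, pid in sorted(net.tp_edges):
                fh.write(f"{t}\tmember_of\t{pid}\n")
    else:
        raise UsageError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> TripartiteNetwork:
    """Read a GraphML network written by :func:`write_network`.

    Pathway gene-set members are recovered from membership edges, so the
    round trip reproduces node and edge sets exactly (members that never
    entered the network are not serialised and cannot be recovered).
    """
    g = nx.read_graphml(str(path))
    compounds, targets, pathways = set(), set(), {}
    status: dict[str, str] = {}
    for node, attrs in g.nodes(data=True):
        kind = attrs.get("node_type")
        if kind == "compound":
            compounds.add(node)
        elif kind == "target":
            targets.add(node)
            if "status" in attrs:
                status[node] = attrs["status"]
        elif kind == "pathway":
            pathways[node] = attrs.get("name", node)
        else:
            raise ParseError(f"{path}: node {node!r} lacks a valid node_type")
    ct_rows, tp_edges = [], set()
    members: dict[str, set[str]] = {pid: set() for pid in pathways}
    for u, v, attrs in g.edges(data=True):
        rel = attrs.get("relation")
        if rel == "binds":
            c, t = (u, v) if u in compounds else (v, u)
            ct_rows.append((c, t, float(attrs["score"])))
        elif rel == "member_of":
            t, pid = (u, v) if v in pathways else (v, u)
            tp_edges.add((t, pid))
            members[pid].add(t)
        else:
            raise ParseError(f"{path}: edge ({u!r},{v!r}) lacks a valid relation")
    ct = pd.DataFrame(ct_rows, columns=["compound_id", "target_id", "score"])
    psets = tuple(
        PathwayGeneSet(pid, pathways[pid], frozenset(members[pid]))
        for pid in sorted(pathways)
        if members[pid]
    )
    return TripartiteNetwork(
        compounds=frozenset(compounds),
        targets=frozenset(targets),
        pathways=psets,
        ct_edges=ct,
        tp_edges=frozenset(tp_edges),
        threshold=float(g.graph.get("threshold", 0.0)),
        node_status=status,
    )


def read_sif_sets(path: str | Path) -> tuple[set[str], set[tuple[str, str, str]]]:
    """Read a SIF file into (node set, {(source, relation, target)}) sets."""
    nodes: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: SIF line needs 3 fields")
            s, rel, t = parts
            nodes.update((s, t))
            edges.add((s, rel, t))
    return nodes, edges
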