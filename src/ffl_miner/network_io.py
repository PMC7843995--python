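"""Read/write node and edge tables and assemble the merged TMGN.

Node TSV: columns ``id``, ``roles`` (semicolon-separated).  Edge TSV per
relation: columns ``source``, ``target``.  Tab-delimited, UTF-8, header row
required.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import Edge, Relation, RegulatoryNetwork, canonical_edge, validate_roles


@dataclass
class RowError:
    table: str
    row: int
    reason: str


@dataclass
class AssemblyReport:
    """What went into the merged network and what was rejected."""

    raw_pair_counts: dict[str, int] = field(default_factory=dict)
    edge_counts: dict[str, int] = field(default_factory=dict)
    rejected: list[RowError] = field(default_factory=list)
    isolated_nodes: list[str] = field(default_factory=list)


def normalize_mirna_id(a: str, b: str) -> tuple[str, str]:
    """Case-insensitive miRNA matching; the ``hsa-`` prefix is stripped only
    when both operands carry it."""
    la, lb = a.lower(), b.lower()
    if la.startswith("hsa-") and lb.startswith("hsa-"):
        la, lb = la[4:], lb[4:]
    return la, lb


def mirna_ids_equal(a: str, b: str) -> bool:
    la, lb = normalize_mirna_id(a, b)
    return la == lb


def read_node_table(path: str | Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "roles"}
    if not required <= set(df.columns):
        raise ValueError(f"node table {path} must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"node table {path} is empty")
    roles: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        rs = validate_roles(r for r in str(row["roles"]).split(";") if r)
        nid = str(row["id"])
        if nid in roles and roles[nid] != rs:
            raise ValueError(f"conflicting role declarations for {nid!r}")
        roles[nid] = rs
    return roles


def read_edge_table(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "target"} <= set(df.columns):
        raise ValueError(f"edge table {path} must have columns source, target")
    return [(str(s), str(t)) for s, t in zip(df["source"], df["target"])]


def load_network_tables(
    node_path: str | Path,
    edge_paths: Mapping[Relation, str | Path],
) -> tuple[RegulatoryNetwork, AssemblyReport]:
    """Load a node table plus per-relation edge tables into a validated
    network.  Rows violating role consistency are rejected and reported;
    duplicates collapse."""
    roles = read_node_table(node_path)
    pair_sets = [
        (rel, read_edge_table(path)) for rel, path in edge_paths.items()
    ]
    return assemble_tmgn(pair_sets, declared_roles=roles, drop_isolated=False)


def assemble_tmgn(
    pair_sets: Iterable[tuple[Relation, Sequence[tuple[str, str]]]],
    declared_roles: Mapping[str, frozenset[str]] | None = None,
    drop_isolated: bool = True,
) -> tuple[RegulatoryNetwork, AssemblyReport]:
    """Merge per-relation pair lists into one typed network.

    Node roles come from ``declared_roles`` when given, otherwise they are
    inferred from the relation endpoints (a node that is both a TF-slot and a
    gene-slot endpoint becomes a dual-role TF&gene node).  Isolated declared
    nodes are dropped from the network view but listed in the report.
    """
    pair_sets = [(Relation(rel), list(pairs)) for rel, pairs in pair_sets]
    report = AssemblyReport()

    inferred: dict[str, set[str]] = {}
    if declared_roles is None:
        for rel, pairs in pair_sets:
            for s, t in pairs:
                inferred.setdefault(s, set()).add(rel.source_role)
                inferred.setdefault(t, set()).add(rel.target_role)
        conflicts = [n for n, rs in inferred.items() if "miRNA" in rs and len(rs) > 1]
        if conflicts:
            raise ValueError(
                f"conflicting role declarations (miRNA mixed with TF/gene) for: "
                f"{sorted(conflicts)}"
            )
        roles = {n: frozenset(rs) for n, rs in inferred.items()}
    else:
        roles = {n: frozenset(rs) for n, rs in declared_roles.items()}

    net = RegulatoryNetwork(provenance="assemble_tmgn")
    for n, rs in roles.items():
        net.add_node(n, rs)

    for rel, pairs in pair_sets:
        report.raw_pair_counts[rel.value] = (
            report.raw_pair_counts.get(rel.value, 0) + len(pairs)
        )
        for i, (s, t) in enumerate(pairs):
            try:
                net.add_edge(s, t, rel)
            except ValueError as exc:
                report.rejected.append(RowError(rel.value, i, str(exc)))

    if drop_isolated:
        net, report.isolated_nodes = net.drop_isolated()
    report.edge_counts = {
        rel.value: c for rel, c in net.edge_counts_by_relation().items()
    }
    return net, report


def derive_mirna_mirna_pairs(
    mirna_gene_edges: Sequence[tuple[str, str]],
    min_shared: int = 2,
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], list[str]]]:
    """miRNA-miRNA interaction pairs by the shared-target rule: every
    unordered miRNA pair whose target-gene sets overlap in at least
    ``min_shared`` genes.  Returns the pairs (lexicographic endpoint order)
    and the shared-gene list per pair."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    targets: dict[str, set[str]] = {}
    for m, g in mirna_gene_edges:
        targets.setdefault(m, set()).add(g)
    pairs: list[tuple[str, str]] = []
    shared: dict[tuple[str, str], list[str]] = {}
    for a, b in itertools.combinations(sorted(targets), 2):
        common = targets[a] & targets[b]
        if len(common) >= min_shared:
            pairs.append((a, b))
            shared[(a, b)] = sorted(common)
    return pairs, shared


def write_node_table(net: RegulatoryNetwork, path: str | Path) -> None:
    rows = [
        {"id": n, "roles": ";".join(sorted(rs))} for n, rs in sorted(net.roles.items())
    ]
    pd.DataFrame(rows, columns=["id", "roles"]).to_csv(path, sep="\t", index=False)


def write_edge_table(net: RegulatoryNetwork, path: str | Path) -> None:
    rows = [
        {"source": s, "target": t, "relation": rel.value}
        for s, t, rel in sorted(net.edges, key=lambda e: (e[2].value, e[0], e[1]))
    ]
    pd.DataFrame(rows, columns=["source", "target", "relation"]).to_csv(
        path, sep="\t", index=False
    )


def read_merged_edge_table(path: str | Path) -> list[tuple[Relation, list[tuple[str, str]]]]:
    """Inverse of write_edge_table: per-relation pair sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[Relation, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(Relation(row["relation"]), []).append(
            (str(row["source"]), str(row["target"]))
        )
    return list(out.items())
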