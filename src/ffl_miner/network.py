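"""Typed regulatory-network container.

The TF-miRNA-gene network (TMGN) is a heterogeneous graph with three node
roles (TF, miRNA, gene; a node may carry both TF and gene roles) and six
relation types, four directed (TF->miRNA, miRNA-|gene, TF->gene, miRNA-|TF)
and two undirected (gene-gene, miRNA-miRNA).  Undirected edges are stored
with lexicographically ordered endpoints so duplicates collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class Relation(str, Enum):
    """The six regulatory relation types."""

    TF_ACTIVATES_MIRNA = "TF_activates_miRNA"
    MIRNA_REPRESSES_GENE = "miRNA_represses_gene"
    TF_REGULATES_GENE = "TF_regulates_gene"
    MIRNA_REPRESSES_TF = "miRNA_represses_TF"
    GENE_GENE = "gene_gene_interaction"
    MIRNA_MIRNA = "miRNA_miRNA_interaction"

    @property
    def directed(self) -> bool:
        return self in _DIRECTED

    @property
    def source_role(self) -> str:
        return _ENDPOINT_ROLES[self][0]

    @property
    def target_role(self) -> str:
        return _ENDPOINT_ROLES[self][1]


_DIRECTED = {
    Relation.TF_ACTIVATES_MIRNA,
    Relation.MIRNA_REPRESSES_GENE,
    Relation.TF_REGULATES_GENE,
    Relation.MIRNA_REPRESSES_TF,
}

# role required of (source, target) for each relation
_ENDPOINT_ROLES = {
    Relation.TF_ACTIVATES_MIRNA: ("TF", "miRNA"),
    Relation.MIRNA_REPRESSES_GENE: ("miRNA", "gene"),
    Relation.TF_REGULATES_GENE: ("TF", "gene"),
    Relation.MIRNA_REPRESSES_TF: ("miRNA", "TF"),
    Relation.GENE_GENE: ("gene", "gene"),
    Relation.MIRNA_MIRNA: ("miRNA", "miRNA"),
}

VALID_ROLES = frozenset({"TF", "miRNA", "gene"})


def validate_roles(roles: Iterable[str]) -> frozenset[str]:
    """Validate a role set: non-empty subset of {TF, miRNA, gene}; the miRNA
    role is exclusive of the other two."""
    rs = frozenset(roles)
    if not rs:
        raise ValueError("role set may not be empty")
    bad = rs - VALID_ROLES
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}")
    if "miRNA" in rs and len(rs) > 1:
        raise ValueError("miRNA role is exclusive of TF and gene roles")
    return rs


Edge = tuple[str, str, Relation]


def canonical_edge(source: str, target: str, relation: Relation) -> Edge:
    """Canonical storage form: undirected endpoints in lexicographic order."""
    if not relation.directed and target < source:
        source, target = target, source
    return (source, target, relation)


@dataclass
class RegulatoryNetwork:
    """Typed node set plus six-relation edge set.

    Invariants: no self-loops, no duplicate (source, target, relation)
    triples, every edge endpoint declared, endpoint roles consistent with
    the relation type.
    """

    roles: dict[str, frozenset[str]] = field(default_factory=dict)
    edges: set[Edge] = field(default_factory=set)
    provenance: str = ""

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, roles: Iterable[str]) -> None:
        rs = validate_roles(roles)
        existing = self.roles.get(node_id)
        if existing is not None and existing != rs:
            raise ValueError(
                f"conflicting role declaration for {node_id!r}: "
                f"{sorted(existing)} vs {sorted(rs)}"
            )
        self.roles[node_id] = rs

    def add_edge(self, source: str, target: str, relation: Relation) -> None:
        relation = Relation(relation)
        if source == target:
            raise ValueError(f"self-loop on {source!r} not allowed")
        for end, role in ((source, relation.source_role), (target, relation.target_role)):
            declared = self.roles.get(end)
            if declared is None:
                raise ValueError(f"edge endpoint {end!r} is not a declared node")
            if role not in declared:
                raise ValueError(
                    f"{relation.value} requires {end!r} to have role {role}; "
                    f"it has {sorted(declared)}"
                )
        self.edges.add(canonical_edge(source, target, relation))

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, rs in self.roles.items() if role in rs)

    def edge_counts_by_relation(self) -> dict[Relation, int]:
        counts = {rel: 0 for rel in Relation}
        for _, _, rel in self.edges:
            counts[rel] += 1
        return counts

    def has_edge(self, source: str, target: str, relation: Relation) -> bool:
        return canonical_edge(source, target, relation) in self.edges

    def arc_map(self) -> dict[tuple[str, str], frozenset[Relation]]:
        """Ordered-pair -> relation set; undirected relations appear in both
        orientations.  The adjacency view the motif census runs on."""
        arcs: dict[tuple[str, str], set[Relation]] = {}
        for s, t, rel in self.edges:
            arcs.setdefault((s, t), set()).add(rel)
            if not rel.directed:
                arcs.setdefault((t, s), set()).add(rel)
        return {k: frozenset(v) for k, v in arcs.items()}

    def union_adjacency(self) -> dict[str, set[str]]:
        """Symmetric adjacency over all relations (connectivity view)."""
        adj: dict[str, set[str]] = {n: set() for n in self.roles}
        for s, t, _ in self.edges:
            adj[s].add(t)
            adj[t].add(s)
        return adj

    # -- derived networks --------------------------------------------------

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(dict(self.roles), set(self.edges), self.provenance)

    def subnetwork(self, nodes: Iterable[str], edges: Iterable[Edge] | None = None,
                   provenance: str = "") -> "RegulatoryNetwork":
        """Restriction to `nodes`; `edges` defaults to the induced edge set."""
        node_set = set(nodes)
        missing = node_set - self.roles.keys()
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)}")
        if edges is None:
            kept = {e for e in self.edges if e[0] in node_set and e[1] in node_set}
        else:
            kept = {canonical_edge(*e) for e in edges}
            if not kept <= self.edges:
                raise ValueError("subnetwork edges must be a subset of parent edges")
        return RegulatoryNetwork(
            {n: self.roles[n] for n in sorted(node_set)}, kept, provenance
        )

    def drop_isolated(self) -> tuple["RegulatoryNetwork", list[str]]:
        """Network view without isolated nodes, plus the dropped ids."""
        touched = {n for e in self.edges for n in e[:2]}
        dropped = sorted(self.roles.keys() - touched)
        return (
            RegulatoryNetwork(
                {n: r for n, r in self.roles.items() if n in touched},
                set(self.edges),
                self.provenance,
            ),
            dropped,
        )

    def summary(self) -> dict:
        """Headline counts: nodes by role, edges by relation."""
        by_role = {
            "TF": sum(1 for r in self.roles.values() if r == {"TF"}),
            "miRNA": sum(1 for r in self.roles.values() if "miRNA" in r),
            "gene": sum(1 for r in self.roles.values() if r == {"gene"}),
            "TF&gene": sum(1 for r in self.roles.values() if r == {"TF", "gene"}),
        }
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_by_role": by_role,
            "edges_by_relation": {
                rel.value: c for rel, c in self.edge_counts_by_relation().items()
            },
        }
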