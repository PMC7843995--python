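"""Composite feed-forward-loop definitions, class selection, and the CFMSN.

A 3-node composite FFL is a TF and a miRNA that mutually regulate each
other (TF->miRNA activation, miRNA-|TF repression) while both regulate a
common target gene (TF->gene, miRNA-|gene).  The 4-node variant adds a
second gene joined by a gene-gene interaction; the 5-node variant further
adds a second miRNA joined by a miRNA-miRNA interaction.  The 4/5-node
checks here follow the minimal reading: the exact role multiset, at least
one edge of each size-appropriate relation type, and an embedded 3-node
composite-FFL core.  ``strict=True`` additionally requires every gene to be
a common target of the TF and the core miRNA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .census import SubgraphPattern, parse_label
from .network import Relation, RegulatoryNetwork
from .significance import MotifStatistics

# role multisets per size: (n_TF, n_miRNA, n_gene)
_ROLE_COUNTS = {3: (1, 1, 1), 4: (1, 1, 2), 5: (1, 2, 2)}

_REQUIRED_RELATIONS = {
    3: {
        Relation.TF_ACTIVATES_MIRNA.value,
        Relation.MIRNA_REPRESSES_TF.value,
        Relation.TF_REGULATES_GENE.value,
        Relation.MIRNA_REPRESSES_GENE.value,
    },
}
_REQUIRED_RELATIONS[4] = _REQUIRED_RELATIONS[3] | {Relation.GENE_GENE.value}
_REQUIRED_RELATIONS[5] = _REQUIRED_RELATIONS[4] | {Relation.MIRNA_MIRNA.value}


@dataclass
class CompositeFFLCriteria:
    z_min: float = 2.0
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must lie in (0, 1]")


def _slot_assignments(colors: tuple[str, ...], k: int):
    """All ways to assign pattern nodes to the role slots of size k.

    Yields (tf, mirnas, genes) index tuples.  A dual-role TF&gene node may
    occupy either a TF or a gene slot, but one node fills only one slot.
    """
    n_tf, n_mirna, n_gene = _ROLE_COUNTS[k]
    idx = range(len(colors))
    tf_ok = [i for i in idx if "TF" in colors[i].split("&")]
    mir_ok = [i for i in idx if colors[i] == "miRNA"]
    gene_ok = [i for i in idx if "gene" in colors[i].split("&")]
    for tfs in itertools.combinations(tf_ok, n_tf):
        rest1 = set(idx) - set(tfs)
        for mirs in itertools.combinations([i for i in mir_ok if i in rest1], n_mirna):
            rest2 = rest1 - set(mirs)
            genes = tuple(i for i in gene_ok if i in rest2)
            if len(genes) == n_gene and len(rest2 - set(genes)) == 0:
                yield tfs, mirs, genes


def _has_core(arcs, tf: int, mir: int, gene: int) -> bool:
    return (
        Relation.TF_ACTIVATES_MIRNA.value in arcs.get((tf, mir), ())
        and Relation.MIRNA_REPRESSES_TF.value in arcs.get((mir, tf), ())
        and Relation.TF_REGULATES_GENE.value in arcs.get((tf, gene), ())
        and Relation.MIRNA_REPRESSES_GENE.value in arcs.get((mir, gene), ())
    )


def qualifies_as_composite_ffl(
    label: str | SubgraphPattern, k: int | None = None, strict: bool = False
) -> bool:
    """True iff the motif class is a k-node composite FFL."""
    pattern = parse_label(label) if isinstance(label, str) else label
    if k is None:
        k = pattern.k
    if k not in _ROLE_COUNTS:
        raise ValueError(f"k must be in {sorted(_ROLE_COUNTS)}, got {k}")
    if pattern.k != k:
        raise ValueError(f"label has size {pattern.k}, expected {k}")
    arcs = pattern.arc_map()
    present = set().union(*arcs.values()) if arcs else set()
    if not _REQUIRED_RELATIONS[k] <= present:
        return False
    for tfs, mirs, genes in _slot_assignments(pattern.colors, k):
        tf = tfs[0]
        core_found = any(
            _has_core(arcs, tf, m, g) for m in mirs for g in genes
        )
        if not core_found:
            continue
        if not strict:
            return True
        # strict reading: every gene is a common target of the TF and of a
        # core miRNA
        def common_target(g: int) -> bool:
            return Relation.TF_REGULATES_GENE.value in arcs.get((tf, g), ()) and any(
                Relation.MIRNA_REPRESSES_GENE.value in arcs.get((m, g), ())
                for m in mirs
            )

        if all(common_target(g) for g in genes):
            return True
    return False


@dataclass
class CFMSN:
    """Composite-FFL motif-specific subnetwork: union of all instances of
    the selected class per size."""

    network: RegulatoryNetwork
    winning_labels: dict[int, str] = field(default_factory=dict)
    instances: dict[int, list[tuple[str, ...]]] = field(default_factory=dict)

    def composition(self) -> dict[str, int]:
        roles = self.network.roles
        return {
            "miRNA": sum(1 for r in roles.values() if "miRNA" in r),
            "TF": sum(1 for r in roles.values() if "TF" in r),
            "gene": sum(1 for r in roles.values() if r == {"gene"}),
        }


@dataclass
class SelectionReport:
    per_k: dict[int, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def select_and_build_cfmsn(
    net: RegulatoryNetwork,
    stats_by_k: dict[int, MotifStatistics],
    criteria: CompositeFFLCriteria | None = None,
    strict: bool = False,
) -> tuple[CFMSN, SelectionReport]:
    """Per size, keep classes passing the Z/p criteria that are composite
    FFLs, pick the one with the highest Z (ties: lower p, then label), and
    union all its instances into one subnetwork."""
    criteria = criteria or CompositeFFLCriteria()
    report = SelectionReport()
    nodes: set[str] = set()
    edges: set = set()
    winners: dict[int, str] = {}
    instances: dict[int, list[tuple[str, ...]]] = {}
    arc_edges = _induced_edge_index(net)

    for k, stats in sorted(stats_by_k.items()):
        if stats.instances is None:
            raise ValueError(f"stats for k={k} lack instances; rerun with retention on")
        significant = [
            s
            for s in stats.per_class.values()
            if s.z_score > criteria.z_min and s.empirical_p < criteria.p_max
        ]
        qualifying = [
            s for s in significant if qualifies_as_composite_ffl(s.label, k, strict)
        ]
        report.per_k[k] = {
            "n_classes": len(stats.per_class),
            "n_significant": len(significant),
            "n_qualifying": len(qualifying),
        }
        if not qualifying:
            msg = f"no composite-FFL class passes criteria at k={k}"
            report.warnings.append(msg)
            warnings.warn(msg)
            continue
        winner = min(qualifying, key=lambda s: (-s.z_score, s.empirical_p, s.label))
        winners[k] = winner.label
        inst = stats.instances.get(winner.label, [])
        instances[k] = list(inst)
        report.per_k[k].update(
            {
                "winning_label": winner.label,
                "z": winner.z_score,
                "p": winner.empirical_p,
                "n_instances": len(inst),
            }
        )
        for node_tuple in inst:
            nodes.update(node_tuple)
            node_set = set(node_tuple)
            for e in arc_edges:
                if e[0] in node_set and e[1] in node_set:
                    edges.add(e)

    sub = net.subnetwork(nodes, edges, provenance="CFMSN") if nodes else RegulatoryNetwork(provenance="CFMSN")
    return CFMSN(sub, winners, instances), report


def _induced_edge_index(net: RegulatoryNetwork):
    return list(net.edges)
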