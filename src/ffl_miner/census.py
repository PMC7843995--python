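"""Colored-subgraph census for k in {3, 4, 5}.

Enumerates every connected induced k-node subgraph of the typed network
exactly once (ESU enumeration over the symmetrized connectivity graph) and
counts instances per canonical colored-isomorphism class.  Node colors are
role sets (a dual-role TF&gene node is its own color); edge colors are the
six relation types; an undirected relation contributes symmetric adjacency.

The canonical label is the lexicographic minimum, over all node
permutations, of a string serialization of (colors, typed adjacency).  With
k <= 5 this is exact and cheap (<= 120 permutations), and the label is a
self-describing serialization that :func:`parse_label` inverts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

from .network import Relation, RegulatoryNetwork

VALID_SIZES = (3, 4, 5)

Arcs = dict[tuple[int, int], frozenset[str]]


@dataclass(frozen=True)
class SubgraphPattern:
    """A small colored digraph: node colors in a fixed local order plus
    per-ordered-pair relation sets (undirected relations in both
    orientations)."""

    colors: tuple[str, ...]
    arcs: tuple[tuple[tuple[int, int], frozenset[str]], ...]

    @property
    def k(self) -> int:
        return len(self.colors)

    def arc_map(self) -> Arcs:
        return dict(self.arcs)


def role_color(roles: Iterable[str]) -> str:
    return "&".join(sorted(roles))


def make_pattern(colors: list[str], arcs: Arcs) -> SubgraphPattern:
    return SubgraphPattern(tuple(colors), tuple(sorted(arcs.items())))


def _is_connected(k: int, arcs: Arcs) -> bool:
    adj: dict[int, set[int]] = {i: set() for i in range(k)}
    for (i, j) in arcs:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == k


def _serialize(colors: tuple[str, ...], arcs: Arcs) -> str:
    edges = ";".join(
        f"{i}>{j}:{'+'.join(sorted(rels))}" for (i, j), rels in sorted(arcs.items())
    )
    return f"{len(colors)}|{'|'.join(colors)}||{edges}"


_PERMS = {k: list(itertools.permutations(range(k))) for k in VALID_SIZES}


def canonical_label(pattern: SubgraphPattern) -> str:
    """Permutation-invariant label of a connected colored pattern.

    The minimum is taken over comparable (colors, edges) tuples; only the
    winning permutation is serialized to the label string.
    """
    k = pattern.k
    if k not in VALID_SIZES:
        raise ValueError(f"pattern size {k} not in {VALID_SIZES}")
    arcs = pattern.arc_map()
    if not _is_connected(k, arcs):
        raise ValueError("pattern is disconnected")
    items = [((i, j), tuple(sorted(rels))) for (i, j), rels in arcs.items()]
    best = None
    for perm in _PERMS[k]:
        inv = [0] * k
        for new, old in enumerate(perm):
            inv[old] = new
        colors = tuple(pattern.colors[old] for old in perm)
        edges = tuple(sorted(((inv[i], inv[j]), rels) for (i, j), rels in items))
        key = (colors, edges)
        if best is None or key < best:
            best = key
    assert best is not None
    return _serialize(best[0], {pair: rels for pair, rels in best[1]})


def parse_label(label: str) -> SubgraphPattern:
    """Invert :func:`canonical_label`'s serialization."""
    head, edges = label.split("||")
    parts = head.split("|")
    k = int(parts[0])
    colors = tuple(parts[1 : 1 + k])
    arcs: Arcs = {}
    if edges:
        for item in edges.split(";"):
            pair, rels = item.split(":")
            i, j = pair.split(">")
            arcs[(int(i), int(j))] = frozenset(rels.split("+"))
    return SubgraphPattern(colors, tuple(sorted(arcs.items())))


@dataclass
class CensusResult:
    k: int
    counts: dict[str, int] = field(default_factory=dict)
    instances: dict[str, list[tuple[str, ...]]] | None = None

    @property
    def total_instances(self) -> int:
        return sum(self.counts.values())

    @property
    def n_classes(self) -> int:
        return len(self.counts)


class _IndexedNetwork:
    """Integer-indexed view used by the enumerators."""

    def __init__(self, net: RegulatoryNetwork):
        self.ids = sorted(net.roles)
        self.index = {n: i for i, n in enumerate(self.ids)}
        self.colors = [role_color(net.roles[n]) for n in self.ids]
        self.adj: list[set[int]] = [set() for _ in self.ids]
        self.arcs: dict[tuple[int, int], frozenset[str]] = {}
        arcs_raw: dict[tuple[int, int], set[str]] = {}
        for s, t, rel in net.edges:
            si, ti = self.index[s], self.index[t]
            self.adj[si].add(ti)
            self.adj[ti].add(si)
            arcs_raw.setdefault((si, ti), set()).add(rel.value)
            if not rel.directed:
                arcs_raw.setdefault((ti, si), set()).add(rel.value)
        self.arcs = {k: frozenset(v) for k, v in arcs_raw.items()}

    def pattern_key(self, subset: tuple[int, ...]):
        local = {v: i for i, v in enumerate(subset)}
        colors = tuple(self.colors[v] for v in subset)
        arcs = tuple(
            sorted(
                ((local[u], local[v]), rels)
                for (u, v), rels in (
                    ((u, v), self.arcs.get((u, v)))
                    for u in subset
                    for v in subset
                    if u != v
                )
                if rels is not None
            )
        )
        return colors, arcs


def _classify(idx: _IndexedNetwork, subset: tuple[int, ...], cache: dict) -> str:
    key = idx.pattern_key(subset)
    label = cache.get(key)
    if label is None:
        label = canonical_label(SubgraphPattern(key[0], key[1]))
        cache[key] = label
    return label


def census(
    net: RegulatoryNetwork, k: int, keep_instances: bool = False
) -> CensusResult:
    """ESU enumeration of all connected induced k-node subgraphs, counted
    per canonical class."""
    if k not in VALID_SIZES:
        raise ValueError(f"k must be in {VALID_SIZES}, got {k}")
    idx = _IndexedNetwork(net)
    result = CensusResult(k=k, counts={}, instances={} if keep_instances else None)
    cache: dict = {}
    adj = idx.adj

    def record(subset: tuple[int, ...]) -> None:
        label = _classify(idx, subset, cache)
        result.counts[label] = result.counts.get(label, 0) + 1
        if keep_instances:
            result.instances.setdefault(label, []).append(
                tuple(idx.ids[v] for v in subset)
            )

    n = len(idx.ids)

    def extend(sub: list[int], ext: set[int], sub_neigh: frozenset[int], v: int) -> None:
        if len(sub) == k:
            record(tuple(sorted(sub)))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u for u in adj[w] if u > v and u not in sub_neigh
            }
            sub.append(w)
            extend(sub, new_ext, sub_neigh | adj[w], v)
            sub.pop()

    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        extend([v], ext, frozenset(adj[v] | {v}), v)
    return result


def brute_force_census(
    net: RegulatoryNetwork, k: int, keep_instances: bool = False
) -> CensusResult:
    """Reference census: iterate all node subsets of size k, keep the
    connected induced subgraphs.  Guard-railed to small networks; this is
    the oracle the fast enumerator is checked against."""
    if k not in VALID_SIZES:
        raise ValueError(f"k must be in {VALID_SIZES}, got {k}")
    if net.n_nodes > 30:
        raise ValueError("brute_force_census is limited to networks of <= 30 nodes")
    idx = _IndexedNetwork(net)
    result = CensusResult(k=k, counts={}, instances={} if keep_instances else None)
    cache: dict = {}
    for subset in itertools.combinations(range(len(idx.ids)), k):
        in_set = set(subset)
        seen = {subset[0]}
        stack = [subset[0]]
        while stack:
            for u in idx.adj[stack.pop()]:
                if u in in_set and u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != k:
            continue
        label = _classify(idx, subset, cache)
        result.counts[label] = result.counts.get(label, 0) + 1
        if keep_instances:
            result.instances.setdefault(label, []).append(
                tuple(idx.ids[v] for v in subset)
            )
    return result
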