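"""Motif significance against a type-preserving edge-switch null model.

Replicate networks are produced by swapping endpoints between edges of the
same relation type only, which preserves per-relation edge counts, role
assignments and every node's per-relation in/out (or undirected) degree.
Each motif class is then scored with

    Z = (real_count - mean_random) / sd_random

(sample sd, n-1 denominator) and an empirical upper-tail p-value, the
fraction of replicates whose count reaches the real count.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .census import CensusResult, census
from .network import Relation, RegulatoryNetwork, canonical_edge


@dataclass
class RandomizationConfig:
    n_random: int = 1000
    exchanges_per_edge: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.exchanges_per_edge < 1:
            raise ValueError("exchanges_per_edge must be >= 1")


@dataclass
class ClassStatistics:
    label: str
    real_count: int
    random_mean: float
    random_sd: float
    z_score: float
    empirical_p: float
    n_random: int


@dataclass
class MotifStatistics:
    k: int
    n_random: int
    per_class: dict[str, ClassStatistics] = field(default_factory=dict)
    instances: dict[str, list[tuple[str, ...]]] | None = None

    def to_rows(self) -> list[dict]:
        return [
            {
                "class_label": s.label,
                "k": self.k,
                "real_count": s.real_count,
                "rand_mean": s.random_mean,
                "rand_sd": s.random_sd,
                "z": s.z_score,
                "p": s.empirical_p,
                "n_random": s.n_random,
            }
            for s in sorted(self.per_class.values(), key=lambda s: (-s.z_score, s.empirical_p, s.label))
        ]


_RETRY_FACTOR = 100  # cap on rejected proposals, per relation


def _swap_directed(edges: set[tuple[str, str]], budget: int, rng: random.Random) -> None:
    # sorted so replicate networks do not depend on set iteration order
    # (string hashing varies across processes)
    pool = sorted(edges)
    if len(pool) < 2:
        return
    successes = attempts = 0
    cap = budget * _RETRY_FACTOR
    while successes < budget and attempts < cap:
        attempts += 1
        i = rng.randrange(len(pool))
        j = rng.randrange(len(pool))
        if i == j:
            continue
        a, b = pool[i]
        c, d = pool[j]
        # swap targets: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b or (a, d) in edges or (c, b) in edges:
            continue
        edges.discard((a, b))
        edges.discard((c, d))
        edges.add((a, d))
        edges.add((c, b))
        pool[i] = (a, d)
        pool[j] = (c, b)
        successes += 1


def _swap_undirected(edges: set[tuple[str, str]], budget: int, rng: random.Random) -> None:
    pool = sorted(edges)
    if len(pool) < 2:
        return
    successes = attempts = 0
    cap = budget * _RETRY_FACTOR
    while successes < budget and attempts < cap:
        attempts += 1
        i = rng.randrange(len(pool))
        j = rng.randrange(len(pool))
        if i == j:
            continue
        a, b = pool[i]
        c, d = pool[j]
        if len({a, b, c, d}) < 4:
            continue
        if rng.random() < 0.5:
            e1, e2 = (a, d), (b, c)
        else:
            e1, e2 = (a, c), (b, d)
        e1 = tuple(sorted(e1))
        e2 = tuple(sorted(e2))
        if e1 in edges or e2 in edges:
            continue
        edges.discard((a, b))
        edges.discard((c, d))
        edges.add(e1)
        edges.add(e2)
        pool[i] = e1
        pool[j] = e2
        successes += 1


def switch_randomize(
    net: RegulatoryNetwork, config: RandomizationConfig
) -> RegulatoryNetwork:
    """One degree-preserving randomized replicate.

    Swaps happen only within a relation type; proposals creating self-loops
    or duplicate edges are rejected and retried (rejections do not consume
    the exchange budget; a retry cap prevents livelock on rigid relations).
    A relation with fewer than two edges is left unchanged.
    """
    rng = random.Random(config.seed)
    by_rel: dict[Relation, set[tuple[str, str]]] = {rel: set() for rel in Relation}
    for s, t, rel in net.edges:
        by_rel[rel].add((s, t))
    for rel in Relation:
        edges = by_rel[rel]
        budget = config.exchanges_per_edge * len(edges)
        if rel.directed:
            _swap_directed(edges, budget, rng)
        else:
            _swap_undirected(edges, budget, rng)
    new_edges = {
        canonical_edge(s, t, rel) for rel, pairs in by_rel.items() for s, t in pairs
    }
    return RegulatoryNetwork(dict(net.roles), new_edges, net.provenance)


def degree_fingerprint(net: RegulatoryNetwork) -> dict:
    """Per-node, per-relation (out-degree, in-degree) map; the invariant the
    randomizer must preserve exactly."""
    fp: dict[tuple[str, str], list[int]] = {}
    for s, t, rel in net.edges:
        if rel.directed:
            fp.setdefault((s, rel.value), [0, 0])[0] += 1
            fp.setdefault((t, rel.value), [0, 0])[1] += 1
        else:
            fp.setdefault((s, rel.value), [0, 0])[0] += 1
            fp.setdefault((t, rel.value), [0, 0])[0] += 1
    return {k: tuple(v) for k, v in fp.items()}


def motif_statistics(
    net: RegulatoryNetwork,
    k: int,
    config: RandomizationConfig,
    keep_instances: bool = True,
) -> MotifStatistics:
    """Census of the real network and of ``n_random`` switch-randomized
    replicates; per-class mean/sd/Z and empirical p.  Classes absent from a
    replicate contribute count 0; a reported p of 0 means < 1/n_random."""
    real = census(net, k, keep_instances=keep_instances)
    labels = set(real.counts)
    replicate_counts: list[dict[str, int]] = []
    for r in range(config.n_random):
        rep_cfg = RandomizationConfig(
            n_random=1,
            exchanges_per_edge=config.exchanges_per_edge,
            seed=(config.seed * 1_000_003 + r) % (2**31),
        )
        rep = switch_randomize(net, rep_cfg)
        c = census(rep, k)
        replicate_counts.append(c.counts)
        labels |= set(c.counts)

    out = MotifStatistics(
        k=k,
        n_random=config.n_random,
        instances=real.instances if keep_instances else None,
    )
    degenerate: list[str] = []
    for label in sorted(labels):
        real_count = real.counts.get(label, 0)
        counts = np.array(
            [rc.get(label, 0) for rc in replicate_counts], dtype=float
        )
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
        if sd > 0:
            z = (real_count - mean) / sd
        elif real_count == mean:
            z = 0.0
        else:
            z = math.inf if real_count > mean else -math.inf
            degenerate.append(label)
        p = float((counts >= real_count).mean())
        out.per_class[label] = ClassStatistics(
            label=label,
            real_count=real_count,
            random_mean=mean,
            random_sd=sd,
            z_score=z,
            empirical_p=p,
            n_random=config.n_random,
        )
    if degenerate:
        warnings.warn(
            f"degenerate null (sd=0, count differs from the null mean) for "
            f"{len(degenerate)} of {len(labels)} classes at k={k}; their Z "
            f"is reported as the +/-inf sentinel"
        )
    return out
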