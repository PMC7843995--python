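"""Synthetic fixtures: typed networks with planted composite FFLs, matched
two-group expression matrices, and drug-target tables.

The generators emulate the structure of the study system — a TF-miRNA-gene
network of a few hundred nodes and ~800 edges across six relation types
with an approximately power-law degree distribution, two-group expression
profiles, and a DrugBank-style drug-target table with curation flags — so
every downstream stage can be exercised against known ground truth.

All generators are deterministic given their seed; a single global seed can
derive per-component substreams via :func:`substream_seed`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .drugs import FLAG_COLUMNS, DrugRecord
from .network import Relation, RegulatoryNetwork


def substream_seed(global_seed: int, component: str) -> int:
    """Stable per-component substream seed derived from one global seed."""
    h = 0
    for ch in component:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (global_seed * 7_919 + h) % (2**31)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class NetworkGenConfig:
    n_tf: int = 16
    n_mirna: int = 76
    n_gene: int = 156
    edges_per_relation: dict[Relation, int] = field(default_factory=dict)
    degree_model: str = "uniform"  # or "preferential"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_mirna, self.n_gene) < 0:
            raise ValueError("node counts must be >= 0")
        if self.degree_model not in ("uniform", "preferential"):
            raise ValueError("degree_model must be 'uniform' or 'preferential'")
        self.edges_per_relation = {
            Relation(r): int(c) for r, c in self.edges_per_relation.items()
        }
        if any(c < 0 for c in self.edges_per_relation.values()):
            raise ValueError("edge counts must be >= 0")


#: Per-relation edge counts at the scale of the study's merged network
#: (248 nodes / 799 edges).
TMGN_SCALE_CONFIG = NetworkGenConfig(
    n_tf=16,
    n_mirna=76,
    n_gene=156,
    edges_per_relation={
        Relation.TF_ACTIVATES_MIRNA: 60,
        Relation.MIRNA_REPRESSES_GENE: 276,
        Relation.TF_REGULATES_GENE: 47,
        Relation.MIRNA_REPRESSES_TF: 39,
        Relation.GENE_GENE: 222,
        Relation.MIRNA_MIRNA: 194,
    },
    degree_model="preferential",
)


def _node_ids(config: NetworkGenConfig) -> dict[str, list[str]]:
    return {
        "TF": [f"TF{i:03d}" for i in range(config.n_tf)],
        "miRNA": [f"MIR{i:03d}" for i in range(config.n_mirna)],
        "gene": [f"G{i:03d}" for i in range(config.n_gene)],
    }


def _relation_slots(rel: Relation, ids: dict[str, list[str]]):
    src = ids[rel.source_role]
    tgt = ids[rel.target_role]
    if rel.directed:
        return src, tgt, False
    return src, src, True  # undirected: both endpoints from the same pool


def _max_edges(rel: Relation, ids: dict[str, list[str]]) -> int:
    src, tgt, undirected = _relation_slots(rel, ids)
    if undirected:
        n = len(src)
        return n * (n - 1) // 2
    return len(src) * len(tgt)


def generate_background_network(config: NetworkGenConfig) -> RegulatoryNetwork:
    """Role-consistent random network with exactly the requested
    per-relation edge counts.

    ``uniform`` draws each relation's edges uniformly without replacement
    from all feasible pairs; ``preferential`` grows each relation edge by
    edge with endpoint probability proportional to 1 + current degree,
    yielding right-skewed (approximately power-law) degree distributions.
    """
    rng = np.random.default_rng(config.seed)
    ids = _node_ids(config)
    net = RegulatoryNetwork(provenance=f"synthetic:{config.degree_model}:{config.seed}")
    for role, nodes in ids.items():
        for n in nodes:
            net.add_node(n, {role})

    for rel in Relation:
        count = config.edges_per_relation.get(rel, 0)
        if count == 0:
            continue
        limit = _max_edges(rel, ids)
        if count > limit:
            raise ValueError(
                f"requested {count} edges for {rel.value} but only {limit} "
                f"distinct pairs exist for the given node counts"
            )
        src, tgt, undirected = _relation_slots(rel, ids)
        if config.degree_model == "uniform":
            if undirected:
                pool = list(itertools.combinations(src, 2))
            else:
                pool = [(s, t) for s in src for t in tgt if s != t]
            chosen = rng.choice(len(pool), size=count, replace=False)
            for i in chosen:
                net.add_edge(*pool[i], rel)
        else:
            chosen_pairs: set[tuple[str, str]] = set()
            deg: dict[str, int] = {}
            attempts, cap = 0, count * 1000
            while len(chosen_pairs) < count and attempts < cap:
                attempts += 1
                s = _weighted_pick(src, deg, rng)
                t = _weighted_pick(tgt, deg, rng)
                if s == t:
                    continue
                pair = tuple(sorted((s, t))) if undirected else (s, t)
                if pair in chosen_pairs:
                    continue
                chosen_pairs.add(pair)
                deg[s] = deg.get(s, 0) + 1
                deg[t] = deg.get(t, 0) + 1
            if len(chosen_pairs) < count:
                raise RuntimeError(
                    f"could not place {count} {rel.value} edges "
                    f"(preferential sampler saturated)"
                )
            for s, t in chosen_pairs:
                net.add_edge(s, t, rel)
    return net


def _weighted_pick(pool: Sequence[str], deg: dict[str, int], rng) -> str:
    weights = np.array([1 + deg.get(n, 0) for n in pool], dtype=float)
    return pool[rng.choice(len(pool), p=weights / weights.sum())]


# ---------------------------------------------------------------------------
# planted composite FFLs
# ---------------------------------------------------------------------------

_ROLE_NEEDS = {3: ("TF", "miRNA", "gene"), 4: ("TF", "miRNA", "gene", "gene"),
               5: ("TF", "miRNA", "miRNA", "gene", "gene")}


@dataclass
class PlantedInstance:
    k: int
    nodes: tuple[str, ...]
    edges: list[tuple[str, str, Relation]]


def _instance_edges(k: int, nodes: Sequence[str]) -> list[tuple[str, str, Relation]]:
    """The composite-FFL edge set on an ordered role tuple (see
    _ROLE_NEEDS for the role order)."""
    if k == 3:
        tf, m, g = nodes
        return [
            (tf, m, Relation.TF_ACTIVATES_MIRNA),
            (m, tf, Relation.MIRNA_REPRESSES_TF),
            (tf, g, Relation.TF_REGULATES_GENE),
            (m, g, Relation.MIRNA_REPRESSES_GENE),
        ]
    if k == 4:
        tf, m, g1, g2 = nodes
        return _instance_edges(3, (tf, m, g1)) + [(g1, g2, Relation.GENE_GENE)]
    if k == 5:
        tf, m1, m2, g1, g2 = nodes
        return _instance_edges(4, (tf, m1, g1, g2)) + [
            (m1, m2, Relation.MIRNA_MIRNA)
        ]
    raise ValueError(f"k must be 3, 4 or 5, got {k}")


def plant_composite_ffls(
    net: RegulatoryNetwork, k: int, n_instances: int, seed: int = 0
) -> tuple[RegulatoryNetwork, list[PlantedInstance]]:
    """Add ``n_instances`` node-disjoint k-node composite-FFL instances.

    Node tuples are drawn at random but, when possible, chosen free of
    pre-existing internal edges so the planted class is unambiguous and
    ground-truth counts are exact.  Fatal if the network lacks enough
    disjoint nodes of the required roles.
    """
    if k not in _ROLE_NEEDS:
        raise ValueError(f"k must be 3, 4 or 5, got {k}")
    rng = np.random.default_rng(seed)
    out = net.copy()
    needs = _ROLE_NEEDS[k]
    pools = {
        role: [n for n in sorted(net.roles) if role in net.roles[n]]
        for role in set(needs)
    }
    required = {role: needs.count(role) * n_instances for role in set(needs)}
    for role, cnt in required.items():
        if len(pools[role]) < cnt:
            raise ValueError(
                f"insufficient disjoint nodes: need {cnt} with role {role}, "
                f"have {len(pools[role])}"
            )
    adj = net.union_adjacency()
    used: set[str] = set()
    instances: list[PlantedInstance] = []
    for _ in range(n_instances):
        tup = _pick_clean_tuple(needs, pools, used, adj, rng)
        used.update(tup)
        edges = _instance_edges(k, tup)
        for s, t, rel in edges:
            out.add_edge(s, t, rel)
        instances.append(PlantedInstance(k=k, nodes=tuple(sorted(tup)), edges=edges))
    return out, instances


def _pick_clean_tuple(needs, pools, used, adj, rng, tries: int = 300):
    fallback = None
    for _ in range(tries):
        tup: list[str] = []
        ok = True
        for role in needs:
            candidates = [n for n in pools[role] if n not in used and n not in tup]
            if not candidates:
                ok = False
                break
            tup.append(candidates[rng.integers(len(candidates))])
        if not ok:
            raise ValueError("insufficient disjoint nodes while planting")
        if fallback is None:
            fallback = list(tup)
        internal = any(b in adj.get(a, ()) for a, b in itertools.combinations(tup, 2))
        if not internal:
            return tuple(tup)
    return tuple(fallback)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionGenConfig:
    n_samples_per_group: int = 8
    planted_logfc: dict[str, float] = field(default_factory=dict)
    pair_rho: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 3:
            raise ValueError("n_samples_per_group must be >= 3")
        if not -1 < self.pair_rho < 1:
            raise ValueError("pair_rho must lie in (-1, 1)")


@dataclass
class SyntheticExpression:
    matrix: ExpressionMatrix
    truth: dict

    def split(self, features_a: Sequence[str]) -> tuple[ExpressionMatrix, ExpressionMatrix]:
        """Two matrices over the same samples (e.g. miRNA vs gene panel)."""
        fa = [f for f in self.matrix.values.index if f in set(features_a)]
        fb = [f for f in self.matrix.values.index if f not in set(features_a)]
        return (
            ExpressionMatrix(self.matrix.values.loc[fa], self.matrix.groups),
            ExpressionMatrix(self.matrix.values.loc[fb], self.matrix.groups),
        )


def generate_expression_profiles(
    features: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    config: ExpressionGenConfig,
) -> SyntheticExpression:
    """Two-group log2-scale expression with planted group differences and
    planted pairwise Pearson correlations.

    Values are baseline + logFC (case group only) + noise_sd * z, where the
    z of the two members of a designated pair are bivariate normal with the
    target correlation and all other z are independent.  A feature may
    belong to at most one pair.
    """
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature ids")
    feat_set = set(features)
    seen: set[str] = set()
    for a, b in pairs:
        if a not in feat_set or b not in feat_set:
            raise ValueError(f"pair ({a}, {b}) references undeclared features")
        if a in seen or b in seen or a == b:
            raise ValueError("each feature may appear in at most one pair")
        seen.update((a, b))

    rng = np.random.default_rng(config.seed)
    n = config.n_samples_per_group
    samples = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["ctrl"] * n, index=samples)

    z = rng.standard_normal((len(features), 2 * n))
    index = {f: i for i, f in enumerate(features)}
    rho = config.pair_rho
    for a, b in pairs:
        za = z[index[a]]
        z[index[b]] = rho * za + np.sqrt(1 - rho**2) * z[index[b]]

    baseline = rng.uniform(6.0, 10.0, size=len(features))
    values = baseline[:, None] + config.noise_sd * z
    for f, lfc in config.planted_logfc.items():
        if f not in index:
            raise ValueError(f"planted_logfc feature {f!r} not declared")
        values[index[f], :n] += lfc

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(features), columns=samples), groups
    )
    truth = {
        "planted_logfc": dict(config.planted_logfc),
        "pairs": [{"features": [a, b], "rho": rho} for a, b in pairs],
        "case_samples": samples[:n],
        "control_samples": samples[n:],
    }
    return SyntheticExpression(matrix=matrix, truth=truth)


# ---------------------------------------------------------------------------
# drugs
# ---------------------------------------------------------------------------

DEFAULT_FLAG_RATES = {
    "approved": 0.8,
    "marketed": 0.9,
    "carcinogenic": 0.08,
    "illegal": 0.04,
    "mixture_only": 0.1,
    "vaginal_route": 0.05,
    "has_aprd": 0.85,
}

PASS_EVERYTHING_RATES = {
    "approved": 1.0,
    "marketed": 1.0,
    "carcinogenic": 0.0,
    "illegal": 0.0,
    "mixture_only": 0.0,
    "vaginal_route": 0.0,
    "has_aprd": 1.0,
}


@dataclass
class DrugFixture:
    records: list[DrugRecord]
    target_table: pd.DataFrame
    metadata_table: pd.DataFrame


def generate_drug_fixture(
    genes: Sequence[str],
    n_drugs: int,
    targets_per_drug: tuple[int, int] = (1, 6),
    flag_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> DrugFixture:
    """DrugBank-style fixture: per-drug target gene sets drawn from the
    supplied gene list plus Bernoulli curation flags."""
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if not genes:
        raise ValueError("gene list may not be empty")
    lo, hi = targets_per_drug
    if not (1 <= lo <= hi):
        raise ValueError("targets_per_drug must be a range with 1 <= lo <= hi")
    rates = dict(DEFAULT_FLAG_RATES)
    if flag_rates:
        rates.update(flag_rates)
    rng = np.random.default_rng(seed)
    records: list[DrugRecord] = []
    target_rows = []
    meta_rows = []
    genes = list(genes)
    for i in range(n_drugs):
        drug_id = f"DB{i:04d}"
        name = f"drug_{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        targets = sorted(
            np.array(genes)[rng.choice(len(genes), size=size, replace=False)]
        )
        flags = {f: bool(rng.random() < rates[f]) for f in FLAG_COLUMNS}
        records.append(
            DrugRecord(drug_id=drug_id, name=name, targets=frozenset(targets), **flags)
        )
        target_rows.extend(
            {"drug_id": drug_id, "name": name, "gene": g} for g in targets
        )
        meta_rows.append({"drug_id": drug_id, "name": name, **flags})
    return DrugFixture(
        records=records,
        target_table=pd.DataFrame(target_rows, columns=["drug_id", "name", "gene"]),
        metadata_table=pd.DataFrame(
            meta_rows, columns=["drug_id", "name", *FLAG_COLUMNS]
        ),
    )
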