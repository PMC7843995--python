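import numpy as np
import pytest

from ffl_miner.network import Relation, RegulatoryNetwork
from ffl_miner.synthetic import NetworkGenConfig, generate_background_network


@pytest.fixture
def chain_net() -> RegulatoryNetwork:
    """t:TF, m:miRNA, g1,g2:gene with a composite-FFL core on (t, m, g1)
    and a gene-gene edge g1-g2."""
    net = RegulatoryNetwork()
    net.add_node("t", {"TF"})
    net.add_node("m", {"miRNA"})
    net.add_node("g1", {"gene"})
    net.add_node("g2", {"gene"})
    net.add_edge("t", "m", Relation.TF_ACTIVATES_MIRNA)
    net.add_edge("m", "t", Relation.MIRNA_REPRESSES_TF)
    net.add_edge("t", "g1", Relation.TF_REGULATES_GENE)
    net.add_edge("m", "g1", Relation.MIRNA_REPRESSES_GENE)
    net.add_edge("g1", "g2", Relation.GENE_GENE)
    return net


def random_typed_network(seed: int, scale: str = "small") -> RegulatoryNetwork:
    """Random role-consistent network; 'small' stays within the brute-force
    oracle's 30-node guard rail."""
    rng = np.random.default_rng(seed)
    if scale == "small":
        n_tf = int(rng.integers(2, 4))
        n_mirna = int(rng.integers(3, 7))
        n_gene = int(rng.integers(5, 12))
    else:
        n_tf, n_mirna, n_gene = 10, 30, 60
    counts = {
        Relation.TF_ACTIVATES_MIRNA: int(rng.integers(2, n_tf * n_mirna // 2 + 2)),
        Relation.MIRNA_REPRESSES_GENE: int(rng.integers(3, n_mirna * n_gene // 3 + 2)),
        Relation.TF_REGULATES_GENE: int(rng.integers(2, n_tf * n_gene // 2 + 2)),
        Relation.MIRNA_REPRESSES_TF: int(rng.integers(2, n_tf * n_mirna // 2 + 2)),
        Relation.GENE_GENE: int(rng.integers(2, n_gene)),
        Relation.MIRNA_MIRNA: int(rng.integers(1, n_mirna)),
    }
    cfg = NetworkGenConfig(
        n_tf=n_tf,
        n_mirna=n_mirna,
        n_gene=n_gene,
        edges_per_relation=counts,
        seed=seed,
    )
    return generate_background_network(cfg)


# study conditions for the small null-calibration background: dense enough
# in reciprocal TF-miRNA regulation that the composite-FFL class occurs
# with nonzero count variance
def null_background_config(seed: int) -> NetworkGenConfig:
    return NetworkGenConfig(
        n_tf=4,
        n_mirna=8,
        n_gene=20,
        edges_per_relation={
            Relation.TF_ACTIVATES_MIRNA: 16,
            Relation.MIRNA_REPRESSES_GENE: 40,
            Relation.TF_REGULATES_GENE: 24,
            Relation.MIRNA_REPRESSES_TF: 16,
            Relation.GENE_GENE: 12,
            Relation.MIRNA_MIRNA: 8,
        },
        seed=seed,
    )


# 100-node background used for planted-motif recovery
def planting_background_config(seed: int) -> NetworkGenConfig:
    return NetworkGenConfig(
        n_tf=10,
        n_mirna=30,
        n_gene=60,
        edges_per_relation={
            Relation.TF_ACTIVATES_MIRNA: 25,
            Relation.MIRNA_REPRESSES_GENE: 90,
            Relation.TF_REGULATES_GENE: 30,
            Relation.MIRNA_REPRESSES_TF: 20,
            Relation.GENE_GENE: 60,
            Relation.MIRNA_MIRNA: 40,
        },
        seed=seed,
    )
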