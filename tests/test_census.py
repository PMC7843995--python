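"""Canonical labeling and the connected-induced-subgraph census."""

import itertools

import pytest

from conftest import random_typed_network
from ffl_miner.census import (
    SubgraphPattern,
    brute_force_census,
    canonical_label,
    census,
    make_pattern,
    parse_label,
)
from ffl_miner.network import Relation, RegulatoryNetwork

TFM = Relation.TF_ACTIVATES_MIRNA.value
MRT = Relation.MIRNA_REPRESSES_TF.value
TFG = Relation.TF_REGULATES_GENE.value
MRG = Relation.MIRNA_REPRESSES_GENE.value
GG = Relation.GENE_GENE.value


def ffl_pattern(order=("TF", "miRNA", "gene")):
    idx = {r: i for i, r in enumerate(order)}
    t, m, g = idx["TF"], idx["miRNA"], idx["gene"]
    arcs = {
        (t, m): frozenset({TFM}),
        (m, t): frozenset({MRT}),
        (t, g): frozenset({TFG}),
        (m, g): frozenset({MRG}),
    }
    return make_pattern(list(order), arcs)


class TestCanonicalLabel:
    def test_permutation_invariance(self):
        labels = {
            canonical_label(ffl_pattern(order))
            for order in itertools.permutations(("TF", "miRNA", "gene"))
        }
        assert len(labels) == 1

    def test_color_sensitivity(self):
        chain_tf = make_pattern(
            ["TF", "gene", "gene"],
            {(0, 1): frozenset({TFG}), (1, 2): frozenset({GG}), (2, 1): frozenset({GG})},
        )
        chain_mir = make_pattern(
            ["miRNA", "gene", "gene"],
            {(0, 1): frozenset({MRG}), (1, 2): frozenset({GG}), (2, 1): frozenset({GG})},
        )
        assert canonical_label(chain_tf) != canonical_label(chain_mir)

    def test_disconnected_pattern_fatal(self):
        pat = make_pattern(["gene", "gene", "gene"], {(0, 1): frozenset({GG}), (1, 0): frozenset({GG})})
        with pytest.raises(ValueError, match="disconnected"):
            canonical_label(pat)

    def test_label_roundtrips_through_parse(self):
        label = canonical_label(ffl_pattern())
        assert canonical_label(parse_label(label)) == label

    def test_equality_matches_brute_force_isomorphism(self):
        """On all connected 3-node colored patterns over a small alphabet,
        labels agree iff an explicit bijection search succeeds."""
        colors = ("TF", "miRNA", "gene")
        rels = (TFM, GG)
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        patterns = []
        for color_choice in itertools.product(colors, repeat=3):
            for arc_mask in range(2 ** len(pairs)):
                arcs = {
                    pairs[b]: frozenset({rels[b % 2]})
                    for b in range(len(pairs))
                    if arc_mask >> b & 1
                }
                pat = make_pattern(list(color_choice), arcs)
                try:
                    patterns.append((pat, canonical_label(pat)))
                except ValueError:
                    continue
                if len(patterns) >= 120:
                    break
            if len(patterns) >= 120:
                break

        def isomorphic(p1, p2):
            a1, a2 = p1.arc_map(), p2.arc_map()
            for perm in itertools.permutations(range(3)):
                if all(p1.colors[i] == p2.colors[perm[i]] for i in range(3)) and {
                    (perm[i], perm[j]): r for (i, j), r in a1.items()
                } == a2:
                    return True
            return False

        import random

        rng = random.Random(0)
        for p1, l1 in rng.sample(patterns, 40):
            for p2, l2 in rng.sample(patterns, 10):
                assert (l1 == l2) == isomorphic(p1, p2)


class TestCensus:
    def test_empty_network(self):
        assert census(RegulatoryNetwork(), 3).counts == {}

    def test_chain_example(self, chain_net):
        c3 = census(chain_net, 3, keep_instances=True)
        assert c3.total_instances == 3 and c3.n_classes == 3
        instance_sets = {
            frozenset(t) for insts in c3.instances.values() for t in insts
        }
        assert instance_sets == {
            frozenset({"t", "m", "g1"}),
            frozenset({"t", "g1", "g2"}),
            frozenset({"m", "g1", "g2"}),
        }
        assert census(chain_net, 4).total_instances == 1

    def test_invalid_k_fatal(self, chain_net):
        with pytest.raises(ValueError):
            census(chain_net, 6)

    def test_instance_node_sets_unique(self):
        net = random_typed_network(11)
        c = census(net, 4, keep_instances=True)
        all_sets = [frozenset(t) for insts in c.instances.values() for t in insts]
        assert len(all_sets) == len(set(all_sets))

    def test_label_stable_under_node_renaming(self, chain_net):
        renamed = RegulatoryNetwork()
        mapping = {"t": "zz_t", "m": "aa_m", "g1": "qq_g1", "g2": "bb_g2"}
        for n, roles in chain_net.roles.items():
            renamed.add_node(mapping[n], roles)
        for s, t, rel in chain_net.edges:
            renamed.add_edge(mapping[s], mapping[t], rel)
        assert census(chain_net, 3).counts == census(renamed, 3).counts


class TestBruteForceOracle:
    def test_complete_gene_graph(self):
        net = RegulatoryNetwork()
        for i in range(4):
            net.add_node(f"g{i}", {"gene"})
        for a, b in itertools.combinations(range(4), 2):
            net.add_edge(f"g{a}", f"g{b}", Relation.GENE_GENE)
        c = brute_force_census(net, 3)
        assert c.total_instances == 4 and c.n_classes == 1

    def test_single_planted_ffl(self):
        net = RegulatoryNetwork()
        net.add_node("t", {"TF"})
        net.add_node("m", {"miRNA"})
        net.add_node("g", {"gene"})
        net.add_edge("t", "m", Relation.TF_ACTIVATES_MIRNA)
        net.add_edge("m", "t", Relation.MIRNA_REPRESSES_TF)
        net.add_edge("t", "g", Relation.TF_REGULATES_GENE)
        net.add_edge("m", "g", Relation.MIRNA_REPRESSES_GENE)
        c = brute_force_census(net, 3)
        assert c.total_instances == 1 and c.n_classes == 1

    def test_large_network_guard_rail(self):
        net = random_typed_network(2, scale="large")
        with pytest.raises(ValueError):
            brute_force_census(net, 3)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_fast_census_matches_oracle(self, k):
        for seed in range(8):
            net = random_typed_network(seed)
            assert census(net, k).counts == brute_force_census(net, k).counts
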