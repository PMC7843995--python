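"""Node/edge table loading, TMGN assembly, and the shared-target rule."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ffl_miner.network import Relation, RegulatoryNetwork
from ffl_miner.network_io import (
    assemble_tmgn,
    derive_mirna_mirna_pairs,
    load_network_tables,
    read_merged_edge_table,
    write_edge_table,
    write_node_table,
)


def write_tables(tmp_path, nodes, edges_by_rel):
    node_path = tmp_path / "nodes.tsv"
    node_path.write_text(
        "id\troles\n" + "".join(f"{i}\t{r}\n" for i, r in nodes)
    )
    paths = {}
    for rel, pairs in edges_by_rel.items():
        p = tmp_path / f"{rel.value}.tsv"
        p.write_text("source\ttarget\n" + "".join(f"{s}\t{t}\n" for s, t in pairs))
        paths[rel] = p
    return node_path, paths


class TestLoadNetworkTables:
    def test_minimal_valid_input(self, tmp_path):
        node_path, paths = write_tables(
            tmp_path,
            [("t1", "TF;gene"), ("m1", "miRNA"), ("g1", "gene")],
            {Relation.TF_REGULATES_GENE: [("t1", "g1")]},
        )
        net, report = load_network_tables(node_path, paths)
        assert net.n_nodes == 3 and net.n_edges == 1
        assert net.roles["t1"] == {"TF", "gene"}

    def test_duplicate_edge_collapses(self, tmp_path):
        node_path, paths = write_tables(
            tmp_path,
            [("t1", "TF"), ("g1", "gene")],
            {Relation.TF_REGULATES_GENE: [("t1", "g1"), ("t1", "g1")]},
        )
        net, _ = load_network_tables(node_path, paths)
        assert net.n_edges == 1

    def test_role_inconsistent_row_rejected_and_logged(self, tmp_path):
        node_path, paths = write_tables(
            tmp_path,
            [("g1", "gene"), ("m1", "miRNA"), ("t1", "TF")],
            {Relation.TF_ACTIVATES_MIRNA: [("g1", "m1"), ("t1", "m1")]},
        )
        net, report = load_network_tables(node_path, paths)
        assert net.n_edges == 1
        assert len(report.rejected) == 1
        assert "g1" in report.rejected[0].reason

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_network_tables(
                tmp_path / "absent.tsv", {Relation.GENE_GENE: tmp_path / "x.tsv"}
            )

    def test_empty_node_table_fatal(self, tmp_path):
        p = tmp_path / "nodes.tsv"
        p.write_text("id\troles\n")
        with pytest.raises(ValueError):
            load_network_tables(p, {})


class TestAssembleTmgn:
    def test_empty_input_empty_network(self):
        net, _ = assemble_tmgn([])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_swapped_undirected_orientation_counted_once(self):
        net, _ = assemble_tmgn(
            [
                (Relation.GENE_GENE, [("a", "b")]),
                (Relation.GENE_GENE, [("b", "a")]),
            ]
        )
        assert net.n_edges == 1

    def test_roles_inferred_with_dual_role_nodes(self):
        net, _ = assemble_tmgn(
            [
                (Relation.TF_REGULATES_GENE, [("x", "y")]),
                (Relation.MIRNA_REPRESSES_GENE, [("m", "x")]),
            ]
        )
        assert net.roles["x"] == {"TF", "gene"}

    def test_conflicting_roles_fatal(self):
        with pytest.raises(ValueError, match="m"):
            assemble_tmgn(
                [
                    (Relation.MIRNA_REPRESSES_GENE, [("m", "g")]),
                    (Relation.TF_REGULATES_GENE, [("t", "m")]),
                ]
            )

    def test_isolated_declared_nodes_dropped_but_reported(self):
        roles = {"t": frozenset({"TF"}), "g": frozenset({"gene"}), "iso": frozenset({"gene"})}
        net, report = assemble_tmgn(
            [(Relation.TF_REGULATES_GENE, [("t", "g")])], declared_roles=roles
        )
        assert "iso" not in net.roles
        assert report.isolated_nodes == ["iso"]

    def test_assembly_idempotent(self):
        pair_sets = [
            (Relation.TF_REGULATES_GENE, [("t", "g1"), ("t", "g2")]),
            (Relation.GENE_GENE, [("g1", "g2")]),
        ]
        a, _ = assemble_tmgn(pair_sets)
        b, _ = assemble_tmgn(pair_sets + pair_sets)
        assert a.edges == b.edges and a.roles == b.roles

    def test_per_relation_counts_sum_to_total(self):
        pair_sets = [
            (Relation.TF_REGULATES_GENE, [("t", "g1")]),
            (Relation.GENE_GENE, [("g1", "g2"), ("g2", "g3")]),
        ]
        net, report = assemble_tmgn(pair_sets)
        assert sum(report.edge_counts.values()) == net.n_edges


class TestDeriveMirnaMirnaPairs:
    def test_shared_target_example(self):
        edges = [("m1", g) for g in ("g1", "g2", "g3")]
        edges += [("m2", g) for g in ("g2", "g3", "g4")]
        edges += [("m3", "g4")]
        pairs, shared = derive_mirna_mirna_pairs(edges)
        assert pairs == [("m1", "m2")]
        assert shared[("m1", "m2")] == ["g2", "g3"]

    def test_single_shared_target_below_threshold(self):
        pairs, _ = derive_mirna_mirna_pairs([("m1", "g1"), ("m2", "g1")])
        assert pairs == []

    def test_brute_force_agreement(self):
        import numpy as np

        rng = np.random.default_rng(5)
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(12)]
        edges = sorted(
            {
                (mirnas[rng.integers(8)], genes[rng.integers(12)])
                for _ in range(40)
            }
        )
        pairs, shared = derive_mirna_mirna_pairs(edges, min_shared=2)
        targets = {}
        for m, g in edges:
            targets.setdefault(m, set()).add(g)
        expected = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(targets, 2)
            if len(targets[a] & targets[b]) >= 2
        }
        assert set(pairs) == expected

    def test_min_shared_below_one_fatal(self):
        with pytest.raises(ValueError):
            derive_mirna_mirna_pairs([], min_shared=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        edges=st.lists(
            st.tuples(
                st.sampled_from(["m1", "m2", "m3", "m4"]),
                st.sampled_from(["g1", "g2", "g3", "g4", "g5"]),
            ),
            max_size=20,
        ),
        min_shared=st.integers(min_value=1, max_value=4),
    )
    def test_order_invariant_and_monotone(self, edges, min_shared):
        pairs, _ = derive_mirna_mirna_pairs(edges, min_shared)
        pairs_rev, _ = derive_mirna_mirna_pairs(list(reversed(edges)), min_shared)
        assert pairs == pairs_rev
        stricter, _ = derive_mirna_mirna_pairs(edges, min_shared + 1)
        assert set(stricter) <= set(pairs)


def test_edge_table_roundtrip(tmp_path, chain_net):
    write_node_table(chain_net, tmp_path / "n.tsv")
    write_edge_table(chain_net, tmp_path / "e.tsv")
    pair_sets = read_merged_edge_table(tmp_path / "e.tsv")
    net, _ = assemble_tmgn(pair_sets, declared_roles=chain_net.roles, drop_isolated=False)
    assert net.edges == chain_net.edges
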