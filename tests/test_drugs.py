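"""Hypergeometric overlap scoring, drug curation filtering, enrichment."""

from fractions import Fraction
from itertools import combinations
from math import comb

import pytest
from scipy.stats import hypergeom

from ffl_miner.drugs import (
    DrugRecord,
    cumulative_hypergeometric,
    filter_drugs,
    gene_set_enrichment,
    mirna_drug_association,
    read_drug_tables,
    read_gmt,
    upper_tail_hypergeometric,
)
from ffl_miner.synthetic import (
    PASS_EVERYTHING_RATES,
    generate_drug_fixture,
)


def rational_cdf(x, M, K, N) -> Fraction:
    """Independent rational-arithmetic oracle for F(x | M, K, N)."""
    if x < 0:
        return Fraction(0)
    total = Fraction(0)
    for i in range(0, min(x, K, N) + 1):
        if N - i <= M - K:
            total += Fraction(comb(K, i) * comb(M - K, N - i), comb(M, N))
    return total


class TestCumulativeHypergeometric:
    def test_full_support_is_one(self):
        assert cumulative_hypergeometric(min(4, 3), 10, 4, 3) == 1.0
        assert cumulative_hypergeometric(7, 12, 7, 9) == 1.0

    def test_enumerated_draws_example(self):
        """F(1 | 10, 4, 3) by enumerating all C(10,3) draws: 80/120."""
        population = ["s"] * 4 + ["f"] * 6
        hits = sum(
            1
            for draw in combinations(range(10), 3)
            if sum(population[i] == "s" for i in draw) <= 1
        )
        assert hits == 80
        assert cumulative_hypergeometric(1, 10, 4, 3) == pytest.approx(
            80 / 120, abs=1e-15
        )

    def test_negative_x_is_zero(self):
        assert cumulative_hypergeometric(-1, 10, 4, 3) == 0.0

    def test_invalid_params_fatal(self):
        with pytest.raises(ValueError):
            cumulative_hypergeometric(0, 5, 6, 2)
        with pytest.raises(ValueError):
            cumulative_hypergeometric(0, 5, 2, 6)

    def test_matches_scipy_cross_check(self):
        for M, K, N, x in [(50, 10, 8, 3), (100, 30, 20, 10), (20, 5, 4, 2)]:
            assert cumulative_hypergeometric(x, M, K, N) == pytest.approx(
                hypergeom.cdf(x, M, K, N), rel=1e-10
            )

    def test_tail_identity(self):
        for M, K, N in [(20, 5, 4), (33, 11, 7), (60, 25, 30)]:
            for x in range(min(K, N) + 2):
                lower = cumulative_hypergeometric(x - 1, M, K, N)
                upper = upper_tail_hypergeometric(x, M, K, N)
                assert lower + upper == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nondecreasing(self):
        M, K, N = 40, 12, 9
        vals = [cumulative_hypergeometric(x, M, K, N) for x in range(-1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestMirnaDrugAssociation:
    def test_single_target_drug_excluded(self):
        drugs = [DrugRecord("d1", "one", frozenset({"g1"}))]
        out = mirna_drug_association({"m1": {"g1", "g2"}}, drugs, universe=100)
        assert out == []

    def test_worked_upper_tail_value(self):
        """M=20, K=5, N=4, x=2 -> 1 - 3640/4845 by rational arithmetic."""
        expected = 1 - rational_cdf(1, 20, 5, 4)
        assert expected == 1 - Fraction(3640, 4845)
        drugs = [DrugRecord("d1", "d", frozenset({"g1", "g2", "g3", "g4"}))]
        targets = {"m1": {"g1", "g2", "x1", "x2", "x3"}}
        out = mirna_drug_association(targets, drugs, universe=20)
        assert out[0].x == 2 and out[0].K == 5 and out[0].N == 4
        assert out[0].p_value == pytest.approx(float(expected), abs=1e-12)

    def test_lower_tail_mode_reproduces_cdf(self):
        drugs = [DrugRecord("d1", "d", frozenset({"g1", "g2"}))]
        targets = {"m1": {"g1", "g3"}}
        out = mirna_drug_association(targets, drugs, universe=10, tail="lower")
        assert out[0].p_value == pytest.approx(
            cumulative_hypergeometric(1, 10, 2, 2), abs=1e-15
        )

    def test_universe_clipping(self):
        drugs = [DrugRecord("d1", "d", frozenset({"g1", "g2", "zz"}))]
        targets = {"m1": {"g1", "g2", "qq"}}
        universe = {f"g{i}" for i in range(10)}
        out = mirna_drug_association(targets, drugs, universe=universe)
        assert out[0].M == 10 and out[0].N == 2 and out[0].K == 2 and out[0].x == 2


class TestFilterDrugs:
    def test_empty(self):
        assert filter_drugs([]) == []

    def test_single_flag_veto(self):
        good = DrugRecord("a", "a", frozenset())
        veto = DrugRecord("b", "b", frozenset(), vaginal_route=True)
        assert filter_drugs([good, veto]) == [good]

    def test_38_drug_screen_keeps_exactly_the_passing_12(self):
        """Synthetic mirror of the 38-candidate screen in which 12 drugs
        satisfy every curation flag."""
        drugs = []
        failing_flags = [
            {"approved": False},
            {"marketed": False},
            {"carcinogenic": True},
            {"illegal": True},
            {"mixture_only": True},
            {"vaginal_route": True},
            {"has_aprd": False},
        ]
        for i in range(38):
            kw = {} if i < 12 else failing_flags[i % len(failing_flags)]
            drugs.append(DrugRecord(f"d{i}", f"d{i}", frozenset({"ESR1"}), **kw))
        kept = filter_drugs(drugs)
        assert [d.drug_id for d in kept] == [f"d{i}" for i in range(12)]


class TestGeneSetEnrichment:
    def test_query_identical_to_set_ranks_first(self):
        sets = {"hit": {"a", "b", "c"}, "other": {"x", "y", "z"}}
        out = gene_set_enrichment({"a", "b", "c"}, sets, universe=20)
        assert out.iloc[0]["gene_set"] == "hit"
        assert out.iloc[0]["p_value"] < out.iloc[1]["p_value"]

    def test_disjoint_query_all_p_one(self):
        sets = {"s1": {"x", "y"}, "s2": {"z"}}
        out = gene_set_enrichment({"a", "b"}, sets, universe=50)
        assert (out["p_value"] == 1.0).all()

    def test_empty_query_fatal(self):
        with pytest.raises(ValueError):
            gene_set_enrichment([], {"s": {"a"}}, universe=10)

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        sets = read_gmt(p)
        assert sets == {"setA": frozenset({"g1", "g2"}), "setB": frozenset({"g3"})}


class TestDrugFixture:
    def test_pass_everything_rates_keep_all(self):
        fx = generate_drug_fixture(
            [f"g{i}" for i in range(20)], 15, flag_rates=PASS_EVERYTHING_RATES, seed=1
        )
        assert len(filter_drugs(fx.records)) == 15

    def test_single_target_drugs_never_associated(self):
        fx = generate_drug_fixture(
            [f"g{i}" for i in range(20)], 10, targets_per_drug=(1, 1), seed=2
        )
        out = mirna_drug_association({"m": {"g0", "g1"}}, fx.records, universe=100)
        assert out == []

    def test_deterministic(self):
        a = generate_drug_fixture([f"g{i}" for i in range(10)], 8, seed=3)
        b = generate_drug_fixture([f"g{i}" for i in range(10)], 8, seed=3)
        assert a.target_table.equals(b.target_table)
        assert a.metadata_table.equals(b.metadata_table)

    def test_table_roundtrip(self, tmp_path):
        fx = generate_drug_fixture([f"g{i}" for i in range(10)], 5, seed=4)
        fx.target_table.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        fx.metadata_table.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        records = read_drug_tables(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert {r.drug_id: r.targets for r in records} == {
            r.drug_id: r.targets for r in fx.records
        }
        assert {r.drug_id: r.approved for r in records} == {
            r.drug_id: r.approved for r in fx.records
        }
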