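"""Venn partitioning, enrichment, TF sign classes and ceRNA calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adjacoex.model import OmicsMatrix, RegulatorSetCollection, ValidationError
from adjacoex.regulators import (
    ACTIVATOR_LIKE,
    REPRESSOR_LIKE,
    cerna_candidates,
    mirna_anticorrelation,
    pathway_partition,
    shared_mirnas,
    shared_regulator_enrichment,
    tf_sign_classification,
    venn_partition,
)
from adjacoex.simulate import default_config, simulate_bundle


class TestVenn:
    def test_disjoint_sets_have_empty_full_intersection(self):
        v = venn_partition({"a": {"x"}, "b": {"y"}})
        assert v.full_intersection == frozenset()

    def test_three_set_hand_enumeration(self):
        v = venn_partition(
            {"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"}, "s3": {"c", "d", "e"}}
        )
        assert v.full_intersection == {"c"}
        assert v.cell("110") == {"b"}
        assert v.cell("011") == {"d"}
        assert v.cell("100") == {"a"}

    @settings(derandomize=True, max_examples=50)
    @given(
        sets=st.lists(
            st.sets(st.integers(0, 20), min_size=0, max_size=10),
            min_size=1,
            max_size=5,
        )
    )
    def test_cells_partition_the_union(self, sets):
        named = {f"s{i}": {str(x) for x in s} for i, s in enumerate(sets)}
        v = venn_partition(named)
        union = set().union(*named.values())
        cells = list(v.cells.values())
        assert v.union_size() == len(union)
        flat = [el for c in cells for el in c]
        assert len(flat) == len(set(flat))
        assert set(flat) == union

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValidationError):
            venn_partition({f"s{i}": {"x"} for i in range(9)})


class TestEnrichment:
    def _sets(self, targets):
        coll = RegulatorSetCollection()
        coll.add("R1", "src", targets)
        return coll

    def test_full_overlap_certainty_has_unit_p(self):
        universe = {f"g{i}" for i in range(6)}
        out = shared_regulator_enrichment(self._sets(universe), universe, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_hand_enumeration_half(self):
        # universe 8, targets {g1,g2,g3}, query {g1,g2,g4,g5}: P(X>=2) = 35/70
        universe = {f"g{i}" for i in range(1, 9)}
        out = shared_regulator_enrichment(
            self._sets({"g1", "g2", "g3"}), {"g1", "g2", "g4", "g5"}, universe
        )
        assert out.loc[0, "overlap"] == 2
        assert out.loc[0, "p"] == pytest.approx(0.5, rel=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            shared_regulator_enrichment(
                self._sets({"g1"}), {"gX"}, {"g1", "g2"}
            )

    def test_planted_block_factor_ranks_first(self):
        hits = 0
        for seed in range(20):
            _, _, truth, _, expr, _, sets = simulate_bundle(default_config(seed=seed))
            tf_sets = sets.subset_source("ChIP")
            query = set(truth.blocks[0])
            out = shared_regulator_enrichment(tf_sets, query, set(expr.row_ids))
            if out.loc[0, "regulator"] == "TF-block-1":
                hits += 1
        assert hits >= 18


class TestTfSigns:
    def _expr(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50)
        data = pd.DataFrame(
            {
                "target": z,
                "tf_same": z,
                "tf_anti": -z,
                "tf_noise": rng.normal(size=50),
            }
        ).T
        data.columns = [f"s{i}" for i in range(50)]
        return OmicsMatrix(data)

    def test_identical_row_is_activator_like(self):
        table, _ = tf_sign_classification(["tf_same"], self._expr(), "target")
        assert table.loc[0, "sign_class"] == ACTIVATOR_LIKE
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_negated_row_is_repressor_like(self):
        table, _ = tf_sign_classification(["tf_anti"], self._expr(), "target")
        assert table.loc[0, "sign_class"] == REPRESSOR_LIKE
        assert table.loc[0, "r"] == pytest.approx(-1.0)

    def test_missing_tf_listed_in_exclusions(self):
        table, excluded = tf_sign_classification(
            ["tf_same", "ghost"], self._expr(), "target"
        )
        assert excluded == ["ghost"]
        assert len(table) == 1


class TestSharedMirnas:
    def _sets(self):
        coll = RegulatorSetCollection()
        coll.add("m1", "srcA", {"A", "B"})
        coll.add("m2", "srcA", {"A", "B", "C"})
        coll.add("m3", "srcA", {"A"})
        coll.add("m1", "srcB", {"A", "B"})
        coll.add("m4", "srcB", {"A", "B"})
        return coll

    def test_single_gene_group_returns_full_sets(self):
        per_source, _ = shared_mirnas(["A"], self._sets(), ["srcA"])
        assert per_source["srcA"] == {"m1", "m2", "m3"}

    def test_toy_intersections_and_union(self):
        per_source, union = shared_mirnas(["A", "B"], self._sets(), ["srcA", "srcB"])
        assert per_source["srcA"] == {"m1", "m2"}
        assert per_source["srcB"] == {"m1", "m4"}
        assert union == {"m1", "m2", "m4"}
        assert len(union) <= sum(len(s) for s in per_source.values())

    def test_group_order_irrelevant(self):
        a = shared_mirnas(["A", "B"], self._sets(), ["srcA"])
        b = shared_mirnas(["B", "A"], self._sets(), ["srcA"])
        assert a == b

    def test_unknown_source_rejected(self):
        with pytest.raises(KeyError):
            shared_mirnas(["A"], self._sets(), ["nope"])


class TestCerna:
    def test_anticorrelation_trivial_cases(self):
        cols = [f"s{i}" for i in range(10)]
        z = np.arange(10, dtype=float)
        expr = OmicsMatrix(pd.DataFrame([z, -z], index=["gpos", "gneg"], columns=cols))
        mirna = OmicsMatrix(pd.DataFrame([z], index=["m"], columns=cols))
        r, p, flag = mirna_anticorrelation("m", "gneg", mirna, expr)
        assert flag and r == pytest.approx(-1.0)
        r, p, flag = mirna_anticorrelation("m", "gpos", mirna, expr)
        assert not flag and r == pytest.approx(1.0)

    def test_zero_shared_mirnas_never_a_candidate(self, bundle):
        _, _, truth, _, expr, mirna, sets = bundle
        # two highly co-expressed block genes share no planted miRNA
        [c] = cerna_candidates(
            [("G017", "G018")], sets, expr, mirna,
            sources=["TarBase", "miRTarBase", "starBase"],
        )
        assert c.union_count == 0 and not c.verdict

    def test_planted_pair_called(self, bundle):
        _, _, truth, _, expr, mirna, sets = bundle
        (left, right, *_ ) = truth.divergent_pairs[0]
        [c] = cerna_candidates([(left, right)], sets, expr, mirna)
        assert c.verdict
        assert c.union_count == 6
        assert c.anticorr_support >= 3
        assert c.pair_r >= 0.6

    def test_verdicts_monotone_in_thresholds(self, bundle):
        _, _, truth, _, expr, mirna, sets = bundle
        (left, right, *_ ) = truth.divergent_pairs[0]
        base = cerna_candidates([(left, right)], sets, expr, mirna)[0]
        assert base.verdict
        for kw in (
            {"min_shared": 7},
            {"r_pair_min": 0.999},
            {"min_support": 7},
        ):
            tightened = cerna_candidates([(left, right)], sets, expr, mirna, **kw)[0]
            assert not tightened.verdict


class TestPathways:
    def test_identical_sets_single_full_cell(self):
        v = pathway_partition({"g1": {"P1", "P2"}, "g2": {"P1", "P2"}})
        assert v.cells == {"11": frozenset({"P1", "P2"})}

    def test_toy_hand_enumeration(self):
        v = pathway_partition(
            {"g1": {"P1", "P2"}, "g2": {"P2", "P3"}, "g3": {"P2"}}
        )
        assert v.full_intersection == {"P2"}
        assert v.cell("100") == {"P1"}
        assert v.cell("010") == {"P3"}

    def test_single_gene_rejected(self):
        with pytest.raises(ValidationError):
            pathway_partition({"g1": {"P1"}})
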