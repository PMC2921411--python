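from math import comb

import numpy as np
import pytest

from pyramabs import (
    AnnotationTable,
    ModuleSet,
    WeightedNetwork,
    hypergeometric_pvalue,
    module_enrichment,
    p_decrease_ratio,
    proximity_signtest,
)
from pyramabs.pyramid import PyramidLevel


def hypergeom_tail_by_enumeration(k, n, K, N):
    """Oracle: upper-tail mass summed term by term from binomial coefficients."""
    return sum(
        comb(K, x) * comb(N - K, n - x) / comb(N, n)
        for x in range(k, min(n, K) + 1)
    )


class TestHypergeometricPvalue:
    def test_full_overlap_worked_example(self):
        assert hypergeometric_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_one(self):
        assert hypergeometric_pvalue(0, 3, 5, 10) == 1.0

    def test_small_complement_example(self):
        assert hypergeometric_pvalue(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_matches_enumeration_for_small_populations(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeometric_pvalue(k, n, K, N) == pytest.approx(
                            hypergeom_tail_by_enumeration(k, n, K, N), abs=1e-12
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(1, 11, 5, 10)


@pytest.fixture
def two_category_table():
    membership = {f"a{i}": {"catA"} for i in range(5)}
    membership.update({f"b{i}": {"catB"} for i in range(5)})
    return AnnotationTable(membership)


class TestModuleEnrichment:
    def test_pure_module_reduces_to_hypergeometric_example(self, two_category_table):
        res = module_enrichment({f"a{i}" for i in range(5)}, two_category_table)
        assert res.best_category == "catA"
        assert res.best_pvalue == pytest.approx(1 / 252)

    def test_unannotated_module_yields_no_annotation_result(self, two_category_table):
        res = module_enrichment({"z1", "z2"}, two_category_table)
        assert res.no_annotation
        assert res.best_pvalue is None

    def test_whole_background_module_scores_one_everywhere(self, two_category_table):
        res = module_enrichment(set(two_category_table.background), two_category_table)
        assert all(p == pytest.approx(1.0) for p in res.per_category.values())

    def test_adding_matching_member_never_weakens_enrichment(self, two_category_table):
        small = {f"a{i}" for i in range(3)}
        p_small = module_enrichment(small, two_category_table).best_pvalue
        p_big = module_enrichment(small | {"a3"}, two_category_table).best_pvalue
        assert p_big <= p_small

    def test_bonferroni_scales_by_categories_tested(self):
        table = AnnotationTable({"x": {"c1", "c2"}, "y": {"c1"}, "z": {"c2"}})
        raw = module_enrichment({"x"}, table)
        adj = module_enrichment({"x"}, table, bonferroni=True)
        assert len(raw.per_category) == 2
        for cat in raw.per_category:
            assert adj.per_category[cat] == pytest.approx(
                min(1.0, 2 * raw.per_category[cat])
            )


class TestPDecreaseRatio:
    def test_worked_example(self):
        assert p_decrease_ratio(0.01, 0.02, 0.005) == pytest.approx(0.5)

    def test_no_decrease_is_zero(self):
        assert p_decrease_ratio(0.01, 0.02, 0.01) == 0.0

    def test_increase_is_negative(self):
        assert p_decrease_ratio(0.01, 0.02, 0.015) < 0.0

    @pytest.mark.parametrize("bad", [(0.0, 0.5, 0.5), (0.5, 0.5, 1.5), (-0.1, 0.5, 0.5)])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            p_decrease_ratio(*bad)


def binom_tail_enumeration(k, n):
    return sum(comb(n, x) for x in range(k, n + 1)) / 2**n


class TestProximitySignTest:
    def _level(self, prox_by_link, modules, annotations):
        ids = sorted(modules)
        ms = ModuleSet([frozenset(modules[i]) for i in ids], module_ids=ids)
        abstract = WeightedNetwork.from_edges(
            [(a, b, w) for (a, b), w in prox_by_link.items()], nodes=ids
        )
        nodes = sorted(x for m in modules.values() for x in m)
        return PyramidLevel(
            input_network=WeightedNetwork(nodes),
            module_set=ms,
            abstract_network=abstract,
            parent_of={x: i for i in ids for x in modules[i]},
        ), AnnotationTable(annotations)

    def test_concordant_links_give_small_one_sided_p(self):
        # four modules over two annotation categories; the strong link joins
        # two same-category modules (big enrichment gain on merge), the weak
        # link joins modules of different categories (no gain)
        modules = {
            "M1": {"a0", "a1", "a2"},
            "M2": {"a3", "a4"},
            "M3": {"b0", "b1", "b2"},
            "M4": {"b3", "b4"},
        }
        ann = {f"a{i}": {"A"} for i in range(5)}
        ann.update({f"b{i}": {"B"} for i in range(5)})
        level, table = self._level(
            {("M1", "M2"): 9.0, ("M3", "M4"): 8.0, ("M2", "M3"): 1.0},
            modules,
            ann,
        )
        rep = proximity_signtest(level, table, alpha=0.05)
        assert not rep.insufficient_data
        assert rep.successes == rep.trials  # same-category merges always win
        assert rep.pvalue == pytest.approx(binom_tail_enumeration(rep.successes,
                                                                  rep.trials))

    def test_single_link_is_insufficient_data(self):
        modules = {"M1": {"a0"}, "M2": {"a1"}}
        ann = {"a0": {"A"}, "a1": {"A"}}
        level, table = self._level({("M1", "M2"): 1.0}, modules, ann)
        assert proximity_signtest(level, table).insufficient_data

    def test_equal_proximities_are_not_compared(self):
        modules = {"M1": {"a0"}, "M2": {"a1"}, "M3": {"b0"}, "M4": {"b1"}}
        ann = {"a0": {"A"}, "a1": {"A"}, "b0": {"B"}, "b1": {"B"}}
        level, table = self._level(
            {("M1", "M2"): 2.0, ("M3", "M4"): 2.0}, modules, ann
        )
        assert proximity_signtest(level, table).insufficient_data

    def test_exact_binomial_agreement(self):
        # the reported p must equal the enumerated tail for every k <= n <= 20
        from scipy.stats import binomtest

        for n in range(1, 21):
            for k in range(n + 1):
                assert binomtest(k, n, 0.5, alternative="greater").pvalue == (
                    pytest.approx(binom_tail_enumeration(k, n))
                )

    def test_nine_of_ten_matches_printed_tail(self):
        assert binom_tail_enumeration(9, 10) == pytest.approx(11 / 1024)
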