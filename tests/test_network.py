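"""Pair construction, coverage statistics and enrichment tests."""

import random

import pytest

from rlenet.core import InhibitionLink, PathwayCategory, ProductLink
from rlenet.network import (
    CoverageReport,
    EnrichmentResult,
    IntegrityError,
    InhibitorProductionStats,
    build_pairs,
    coverage_report,
    cross_pathway_matrix,
    cross_pathway_pairs,
    enrichment_rle_targets,
    hypergeometric_tail,
    inhibitor_production_stats,
)
from conftest import CARB, LIPID, NUC, mkenzyme


def prod(ec, c, org="hsa"):
    return ProductLink(org, ec, c)


def inh(c, ec, org="hsa", in_vivo=True):
    return InhibitionLink(org, c, ec, in_vivo)


class TestBuildPairs:
    def test_minimal_compound_join(self, toy_enzymes):
        pairs = build_pairs(
            [prod("1.1.1.1", "C1")], [inh("C1", "2.2.2.2")], toy_enzymes, "hsa"
        )
        assert [(p.provider_ec, p.target_ec, p.compound) for p in pairs] == [
            ("1.1.1.1", "2.2.2.2", "C1")
        ]
        assert pairs[0].provider_is_rle and not pairs[0].target_is_rle

    def test_cartesian_join_on_shared_compound(self, toy_enzymes):
        pairs = build_pairs(
            [prod("1.1.1.1", "C1"), prod("2.2.2.2", "C1")],
            [inh("C1", "3.3.3.3"), inh("C1", "4.4.4.4")],
            toy_enzymes,
            "hsa",
        )
        assert len(pairs) == 4

    def test_no_shared_compound_yields_nothing(self, toy_enzymes):
        assert (
            build_pairs(
                [prod("1.1.1.1", "C1")], [inh("C2", "2.2.2.2")], toy_enzymes, "hsa"
            )
            == []
        )

    def test_deduplicated_on_provider_target_compound(self, toy_enzymes):
        pairs = build_pairs(
            [prod("1.1.1.1", "C1"), prod("1.1.1.1", "C1")],
            [inh("C1", "2.2.2.2")],
            toy_enzymes,
            "hsa",
        )
        assert len(pairs) == 1

    def test_in_vivo_filter_default(self, toy_enzymes):
        links = [inh("C1", "2.2.2.2", in_vivo=False)]
        assert build_pairs([prod("1.1.1.1", "C1")], links, toy_enzymes, "hsa") == []
        kept = build_pairs(
            [prod("1.1.1.1", "C1")], links, toy_enzymes, "hsa", in_vivo_only=False
        )
        assert len(kept) == 1

    def test_self_pairs_flagged_and_excludable(self, toy_enzymes):
        products = [prod("1.1.1.1", "C1")]
        inhibitions = [inh("C1", "1.1.1.1")]
        (pair,) = build_pairs(products, inhibitions, toy_enzymes, "hsa")
        assert pair.is_self_pair
        assert (
            build_pairs(
                products, inhibitions, toy_enzymes, "hsa", include_self_pairs=False
            )
            == []
        )

    def test_no_cross_organism_transfer(self, toy_enzymes):
        # Product annotated in mmu only must not pair with an hsa inhibition.
        pairs = build_pairs(
            [prod("1.1.1.1", "C1", org="mmu")],
            [inh("C1", "2.2.2.2", org="hsa")],
            toy_enzymes,
            "hsa",
        )
        assert pairs == []

    def test_unknown_ec_raises_integrity_error(self, toy_enzymes):
        with pytest.raises(IntegrityError, match="9.9.9.9"):
            build_pairs(
                [prod("9.9.9.9", "C1")], [inh("C1", "2.2.2.2")], toy_enzymes, "hsa"
            )

    def test_join_size_matches_triple_loop_oracle(self, toy_enzymes):
        """|pairs| equals the brute-force count of distinct joined triples."""
        rng = random.Random(7)
        ecs = [r.ec for r in toy_enzymes]
        for _ in range(25):
            products = [
                prod(rng.choice(ecs), f"C{rng.randrange(4)}") for _ in range(12)
            ]
            inhibitions = [
                inh(f"C{rng.randrange(4)}", rng.choice(ecs)) for _ in range(12)
            ]
            expected = {
                (p.ec, i.target_ec, p.compound)
                for p in products
                for i in inhibitions
                if p.compound == i.compound
            }
            pairs = build_pairs(products, inhibitions, toy_enzymes, "hsa")
            assert len(pairs) == len(expected)


class TestInhibitorProductionStats:
    def test_no_rles_gives_zero_fraction(self, toy_enzymes):
        stats = inhibitor_production_stats(
            [prod("2.2.2.2", "C1")], [inh("C1", "4.4.4.4")], toy_enzymes, "hsa"
        )
        assert stats.fraction == 0.0

    def test_all_inhibitors_rle_produced_saturates(self, toy_enzymes):
        stats = inhibitor_production_stats(
            [prod("1.1.1.1", "C1")], [inh("C1", "2.2.2.2")], toy_enzymes, "hsa"
        )
        assert stats.fraction == 1.0 and stats.percent == 100

    def test_zero_inhibitors_fraction_null(self, toy_enzymes):
        stats = inhibitor_production_stats([], [], toy_enzymes, "hsa")
        assert stats.fraction is None and stats.percent is None

    def test_distinct_compound_counting(self, toy_enzymes):
        # The same compound inhibiting two targets is one inhibitor.
        stats = inhibitor_production_stats(
            [prod("1.1.1.1", "C1")],
            [inh("C1", "2.2.2.2"), inh("C1", "4.4.4.4")],
            toy_enzymes,
            "hsa",
        )
        assert stats.n_inhibitors == 1


class TestCoverageReport:
    def test_three_edge_toy_network_hand_count(self, toy_enzymes):
        # R1->E2, R1->E3, E4->E3 with R1 rate-limiting.
        pairs = build_pairs(
            [prod("1.1.1.1", "C1"), prod("1.1.1.1", "C2"), prod("4.4.4.4", "C3")],
            [inh("C1", "2.2.2.2"), inh("C2", "3.3.3.3"), inh("C3", "3.3.3.3")],
            toy_enzymes,
            "hsa",
        )
        cov = coverage_report(pairs, toy_enzymes, "hsa")
        assert (cov.providers_all, cov.providers_rle) == (2, 1)
        assert (cov.targets_all, cov.targets_by_rle) == (2, 2)
        assert cov.targets_rle == 1  # 3.3.3.3
        assert cov.rle_targets_inhibited_by_rle == 1

    def test_empty_network_zero_counts_null_fractions(self, toy_enzymes):
        cov = coverage_report([], toy_enzymes, "hsa")
        assert cov.providers_all == 0 and cov.frac_providers_rle is None

    def test_all_rle_providers_fraction_one(self, toy_enzymes):
        pairs = build_pairs(
            [prod("1.1.1.1", "C1"), prod("3.3.3.3", "C1")],
            [inh("C1", "2.2.2.2")],
            toy_enzymes,
            "hsa",
        )
        assert coverage_report(pairs, toy_enzymes, "hsa").frac_providers_rle == 1.0

    def test_category_filter_uses_own_side_annotation(self, toy_enzymes):
        # Provider 1.1.1.1 (Carbohydrate) -> target 2.2.2.2 (Lipid).
        pairs = build_pairs(
            [prod("1.1.1.1", "C1")], [inh("C1", "2.2.2.2")], toy_enzymes, "hsa"
        )
        carb = coverage_report(pairs, toy_enzymes, "hsa", CARB)
        lipid = coverage_report(pairs, toy_enzymes, "hsa", LIPID)
        assert (carb.providers_all, carb.targets_all) == (1, 0)
        assert (lipid.providers_all, lipid.targets_all) == (0, 1)

    def test_adding_links_never_decreases_counts(self, toy_enzymes):
        rng = random.Random(13)
        ecs = [r.ec for r in toy_enzymes]
        products = [prod(rng.choice(ecs), f"C{rng.randrange(3)}") for _ in range(8)]
        inhibitions = [
            inh(f"C{rng.randrange(3)}", rng.choice(ecs)) for _ in range(8)
        ]
        base = coverage_report(
            build_pairs(products, inhibitions, toy_enzymes, "hsa"),
            toy_enzymes, "hsa",
        )
        grown = coverage_report(
            build_pairs(
                products + [prod("3.3.3.3", "C0")],
                inhibitions + [inh("C1", "5.5.5.5")],
                toy_enzymes, "hsa",
            ),
            toy_enzymes, "hsa",
        )
        assert grown.providers_all >= base.providers_all
        assert grown.targets_all >= base.targets_all
        assert grown.targets_by_rle >= base.targets_by_rle


class TestEnrichment:
    def test_derived_tail_value(self):
        assert hypergeometric_tail(3, 5, 4, 10).p_value == pytest.approx(
            66 / 252, abs=1e-12
        )

    def test_rle_target_enrichment_direction(self, toy_enzymes):
        # Both targets are RLEs while only 2 of 5 enzymes are: p < 1.
        pairs = build_pairs(
            [prod("2.2.2.2", "C1")],
            [inh("C1", "1.1.1.1"), inh("C1", "3.3.3.3")],
            toy_enzymes,
            "hsa",
        )
        res = enrichment_rle_targets(pairs, toy_enzymes, "hsa")
        assert res.k == 2 and res.n == 2 and res.K == 2 and res.N == 5
        assert 0 < res.p_value < 1

    def test_empty_category_returns_null(self, toy_enzymes):
        res = enrichment_rle_targets([], toy_enzymes, "hsa",
                                     PathwayCategory.OTHERS)
        assert res is None

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            EnrichmentResult(k=5, n=4, K=10, N=20, p_value=0.5)


class TestCrossPathway:
    def _pair(self, toy_enzymes, provider, target, compound="C1"):
        return build_pairs(
            [prod(provider, compound)], [inh(compound, target)], toy_enzymes, "hsa"
        )[0]

    def test_disjoint_singletons_retained(self, toy_enzymes):
        pair = self._pair(toy_enzymes, "1.1.1.1", "2.2.2.2")  # Carb -> Lipid
        assert cross_pathway_pairs([pair]) == [pair]

    def test_shared_category_dropped(self, toy_enzymes):
        pair = self._pair(toy_enzymes, "2.2.2.2", "4.4.4.4")  # Lipid -> {Carb,Lipid}
        assert cross_pathway_pairs([pair]) == []
        # but retained under the weaker not-identical criterion
        assert cross_pathway_pairs([pair], "not_identical") == [pair]

    def test_identical_sets_dropped_under_both_criteria(self, toy_enzymes):
        pair = self._pair(toy_enzymes, "3.3.3.3", "5.5.5.5")  # Nuc -> Nuc
        assert cross_pathway_pairs([pair]) == []
        assert cross_pathway_pairs([pair], "not_identical") == []

    def test_partition_into_cross_and_within(self, toy_enzymes):
        pairs = [
            self._pair(toy_enzymes, "1.1.1.1", "2.2.2.2"),
            self._pair(toy_enzymes, "2.2.2.2", "4.4.4.4", "C2"),
            self._pair(toy_enzymes, "3.3.3.3", "5.5.5.5", "C3"),
        ]
        cross = cross_pathway_pairs(pairs)
        within = [p for p in pairs if p not in cross]
        assert sorted(map(str, cross + within)) == sorted(map(str, pairs))
        assert not set(map(str, cross)) & set(map(str, within))

    def test_single_edge_matrix_cell(self, toy_enzymes):
        pair = self._pair(toy_enzymes, "1.1.1.1", "2.2.2.2")
        matrix = cross_pathway_matrix([pair], toy_enzymes, "hsa")
        cell = matrix.cell(CARB, LIPID)
        assert (cell.targets_by_rle, cell.targets_by_all, cell.fraction) == (1, 1, 1.0)
        assert matrix.cell(LIPID, CARB).targets_by_all == 0
        assert len(matrix.cells) == 36

    def test_distinct_target_counting_in_denominator(self, toy_enzymes):
        # Same Lipid target hit by an RLE and a non-RLE Nucleotide provider.
        pairs = [
            self._pair(toy_enzymes, "3.3.3.3", "2.2.2.2", "C1"),  # RLE provider
            self._pair(toy_enzymes, "5.5.5.5", "2.2.2.2", "C2"),
        ]
        cell = cross_pathway_matrix(pairs, toy_enzymes, "hsa").cell(NUC, LIPID)
        assert (cell.targets_by_rle, cell.targets_by_all) == (1, 1)

    def test_random_matrix_matches_exhaustive_tally(self, toy_enzymes):
        """Every cell equals an independent nested-loop tally."""
        rng = random.Random(5)
        ecs = [r.ec for r in toy_enzymes]
        pairs = []
        for i in range(12):
            a, b = rng.choice(ecs), rng.choice(ecs)
            pairs.append(self._pair(toy_enzymes, a, b, f"C{i}"))
        cross = cross_pathway_pairs(pairs)
        matrix = cross_pathway_matrix(cross, toy_enzymes, "hsa")
        for src in PathwayCategory:
            for tgt in PathwayCategory:
                all_t = {
                    p.target_ec
                    for p in cross
                    if src in p.provider_categories and tgt in p.target_categories
                }
                rle_t = {
                    p.target_ec
                    for p in cross
                    if src in p.provider_categories
                    and tgt in p.target_categories
                    and p.provider_is_rle
                }
                cell = matrix.cell(src, tgt)
                assert (cell.targets_by_rle, cell.targets_by_all) == (
                    len(rle_t),
                    len(all_t),
                )


def test_fraction_percent_rounding_ties_away_from_zero():
    assert InhibitorProductionStats.from_counts(1, 8).percent == 13  # 12.5 -> 13
    assert InhibitorProductionStats.from_counts(7, 10).percent == 70
    with pytest.raises(ValueError):
        InhibitorProductionStats.from_counts(5, 3)
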