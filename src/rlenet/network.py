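"""Inhibiting-pair construction and provider/target statistics.

An inhibiting pair (provider, target, compound, organism) exists exactly
when the provider produces the compound in that organism and the compound
is an in-vivo inhibitor of the target in the same organism.  Inhibitor
annotations are never transferred between organisms.

All counting is over distinct entities (compounds, EC numbers), never over
link multiplicity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from .core import (
    EnzymeIndex,
    InhibitionLink,
    PathwayCategory,
    ProductLink,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InhibitingPair",
    "InhibitorProductionStats",
    "CoverageReport",
    "EnrichmentResult",
    "CrossPathwayCell",
    "CrossPathwayMatrix",
    "build_pairs",
    "inhibitor_production_stats",
    "enrichment_inhibitor_production",
    "coverage_report",
    "hypergeometric_tail",
    "enrichment_rle_targets",
    "cross_pathway_pairs",
    "cross_pathway_matrix",
]


@dataclass(frozen=True)
class InhibitingPair:
    """A provider→target edge of the inhibitory network in one organism."""

    organism: str
    provider_ec: str
    target_ec: str
    compound: str
    provider_is_rle: bool
    target_is_rle: bool
    provider_categories: frozenset[PathwayCategory]
    target_categories: frozenset[PathwayCategory]

    @property
    def is_self_pair(self) -> bool:
        """Autoinhibition: the product inhibits its own producing enzyme."""
        return self.provider_ec == self.target_ec


class IntegrityError(ValueError):
    """Links referencing unknown enzymes; message lists every offender."""


def build_pairs(
    products: list[ProductLink],
    inhibitions: list[InhibitionLink],
    enzymes: EnzymeIndex,
    organism: str,
    in_vivo_only: bool = True,
    include_self_pairs: bool = True,
) -> list[InhibitingPair]:
    """Compound-join of product and inhibition links for one organism.

    Returns exactly the Cartesian join on the shared compound, deduplicated
    on (provider_ec, target_ec, compound).  Self-pairs are retained by
    default but can be excluded.
    """
    unknown = sorted(
        {p.ec for p in products if p.organism == organism and p.ec not in enzymes}
        | {
            i.target_ec
            for i in inhibitions
            if i.organism == organism and i.target_ec not in enzymes
        }
    )
    if unknown:
        raise IntegrityError(f"links reference unknown enzymes: {unknown}")

    producers: dict[str, set[str]] = {}
    for p in products:
        if p.organism == organism:
            producers.setdefault(p.compound, set()).add(p.ec)
    targets: dict[str, set[str]] = {}
    for i in inhibitions:
        if i.organism != organism:
            continue
        if in_vivo_only and not i.in_vivo:
            continue
        targets.setdefault(i.compound, set()).add(i.target_ec)

    pairs: list[InhibitingPair] = []
    seen: set[tuple[str, str, str]] = set()
    for compound in sorted(set(producers) & set(targets)):
        for provider_ec in sorted(producers[compound]):
            for target_ec in sorted(targets[compound]):
                key = (provider_ec, target_ec, compound)
                if key in seen:
                    continue
                seen.add(key)
                if provider_ec == target_ec and not include_self_pairs:
                    continue
                provider = enzymes[provider_ec]
                target = enzymes[target_ec]
                pairs.append(
                    InhibitingPair(
                        organism=organism,
                        provider_ec=provider_ec,
                        target_ec=target_ec,
                        compound=compound,
                        provider_is_rle=provider.is_rle,
                        target_is_rle=target.is_rle,
                        provider_categories=provider.categories,
                        target_categories=target.categories,
                    )
                )
    return pairs


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class InhibitorProductionStats:
    """How many distinct in-vivo inhibitors an organism has, and how many
    are products of rate-limiting enzymes."""

    organism: str
    n_inhibitors: int
    n_rle_produced: int

    @property
    def fraction(self) -> float | None:
        if self.n_inhibitors == 0:
            return None
        return self.n_rle_produced / self.n_inhibitors

    @property
    def percent(self) -> int | None:
        """Fraction as a percentage rounded to the nearest integer
        (ties away from zero), the form used in headline figures."""
        f = self.fraction
        return None if f is None else _round_half_away(100.0 * f)

    @classmethod
    def from_counts(
        cls, n_rle_produced: int, n_inhibitors: int, organism: str = ""
    ) -> "InhibitorProductionStats":
        if n_rle_produced > n_inhibitors:
            raise ValueError("RLE-produced count exceeds total inhibitor count")
        return cls(
            organism=organism,
            n_inhibitors=n_inhibitors,
            n_rle_produced=n_rle_produced,
        )


def inhibitor_production_stats(
    products: list[ProductLink],
    inhibitions: list[InhibitionLink],
    enzymes: EnzymeIndex,
    organism: str,
) -> InhibitorProductionStats:
    """Count distinct in-vivo inhibitor compounds and the RLE-produced subset.

    A compound counts as RLE-produced when at least one RLE of the same
    organism has it as a product.
    """
    inhibitors = {
        i.compound
        for i in inhibitions
        if i.organism == organism and i.in_vivo
    }
    rle_products = {
        p.compound
        for p in products
        if p.organism == organism and enzymes.is_rle(p.ec)
    }
    return InhibitorProductionStats(
        organism=organism,
        n_inhibitors=len(inhibitors),
        n_rle_produced=len(inhibitors & rle_products),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Inputs and upper-tail probability of a hypergeometric test.

    k successes in a sample of n, drawn from a population of N containing
    K successes; p_value = P(X >= k).
    """

    k: int
    n: int
    K: int
    N: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid k={self.k} for n={self.n}, K={self.K}")
        if not (0 <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValueError(f"invalid margins n={self.n}, K={self.K}, N={self.N}")


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in a size-n sample drawn without replacement from a
    population of N with K successes.  Evaluated through log-space survival
    functions, so it is numerically exact well past N = 10^6.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"require n <= N and K <= N; got n={n}, K={K}, N={N}")
    # sf(k-1) = P(X >= k); exactly 1 at k = 0.
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    if p == 0.0:  # guard against underflow of an always-positive tail
        p = 5e-324
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=p)


def enrichment_inhibitor_production(
    products: list[ProductLink],
    inhibitions: list[InhibitionLink],
    enzymes: EnzymeIndex,
    organism: str,
) -> EnrichmentResult | None:
    """Are in-vivo inhibitors over-represented among RLE products?

    Population: distinct compounds produced in the organism.  Successes:
    those produced by at least one RLE.  Sample: produced compounds that
    are in-vivo inhibitors.  Inhibitor compounds never produced in the
    organism fall outside the population and are excluded from the sample.
    """
    produced: set[str] = set()
    rle_produced: set[str] = set()
    for p in products:
        if p.organism != organism:
            continue
        produced.add(p.compound)
        if enzymes.is_rle(p.ec):
            rle_produced.add(p.compound)
    inhibitors = {
        i.compound for i in inhibitions if i.organism == organism and i.in_vivo
    }
    sample = inhibitors & produced
    if not produced or not sample:
        logger.warning(
            "inhibitor-production enrichment degenerate for %s", organism
        )
        return None
    return hypergeometric_tail(
        k=len(sample & rle_produced),
        n=len(sample),
        K=len(rle_produced),
        N=len(produced),
    )


def _frac(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class CoverageReport:
    """Distinct-enzyme provider/target counts for one organism (optionally
    one pathway category) with the derived fractions."""

    organism: str
    category: PathwayCategory | None
    providers_all: int
    providers_rle: int
    targets_all: int
    targets_by_rle: int
    targets_rle: int
    rle_targets_inhibited_by_rle: int

    @property
    def frac_providers_rle(self) -> float | None:
        return _frac(self.providers_rle, self.providers_all)

    @property
    def frac_targets_by_rle(self) -> float | None:
        return _frac(self.targets_by_rle, self.targets_all)

    @property
    def frac_targets_rle(self) -> float | None:
        return _frac(self.targets_rle, self.targets_all)

    @property
    def frac_rle_targets_by_rle(self) -> float | None:
        return _frac(self.rle_targets_inhibited_by_rle, self.targets_rle)


def coverage_report(
    pairs: list[InhibitingPair],
    enzymes: EnzymeIndex,
    organism: str,
    category: PathwayCategory | None = None,
) -> CoverageReport:
    """Provider/target coverage over a pair list, counting distinct ECs.

    With a category filter, provider statistics restrict to providers
    annotated with the category and target statistics to targets annotated
    with it (multi-category enzymes count once in each of their categories).
    """
    providers: set[str] = set()
    providers_rle: set[str] = set()
    targets: set[str] = set()
    targets_by_rle: set[str] = set()
    targets_rle: set[str] = set()
    rle_targets_by_rle: set[str] = set()
    for pair in pairs:
        if pair.organism != organism:
            continue
        if category is None or category in pair.provider_categories:
            providers.add(pair.provider_ec)
            if pair.provider_is_rle:
                providers_rle.add(pair.provider_ec)
        if category is None or category in pair.target_categories:
            targets.add(pair.target_ec)
            if pair.provider_is_rle:
                targets_by_rle.add(pair.target_ec)
            if pair.target_is_rle:
                targets_rle.add(pair.target_ec)
                if pair.provider_is_rle:
                    rle_targets_by_rle.add(pair.target_ec)
    return CoverageReport(
        organism=organism,
        category=category,
        providers_all=len(providers),
        providers_rle=len(providers_rle),
        targets_all=len(targets),
        targets_by_rle=len(targets_by_rle),
        targets_rle=len(targets_rle),
        rle_targets_inhibited_by_rle=len(rle_targets_by_rle),
    )


def enrichment_rle_targets(
    pairs: list[InhibitingPair],
    enzymes: EnzymeIndex,
    organism: str,
    category: PathwayCategory | None = None,
) -> EnrichmentResult | None:
    """Are inhibited targets over-represented among rate-limiting enzymes?

    Population: enzymes of the organism (in the category); successes: RLEs
    among them; sample: distinct inhibited targets; k: RLE targets.  Raw
    one-sided p, no multiplicity correction.
    """
    population = enzymes.enzymes_in(organism, category)
    if not population:
        logger.warning(
            "empty enzyme population for %s / %s", organism, category
        )
        return None
    pop_ecs = {rec.ec for rec in population}
    K = sum(1 for rec in population if rec.is_rle)
    target_ecs = {
        p.target_ec
        for p in pairs
        if p.organism == organism
        and (category is None or category in p.target_categories)
    }
    target_ecs &= pop_ecs
    if not target_ecs:
        logger.warning("no inhibited targets for %s / %s", organism, category)
        return None
    k = sum(1 for ec in target_ecs if enzymes.is_rle(ec))
    return hypergeometric_tail(k=k, n=len(target_ecs), K=K, N=len(pop_ecs))


def cross_pathway_pairs(
    pairs: list[InhibitingPair], criterion: str = "disjoint"
) -> list[InhibitingPair]:
    """Isolate pairs whose provider and target pathway annotations differ.

    ``criterion="disjoint"`` (default) keeps pairs whose category sets
    share no category — the conservative reading for multi-category
    enzymes; ``"not_identical"`` keeps any pair whose sets are not equal.
    """
    if criterion == "disjoint":
        return [
            p
            for p in pairs
            if not (p.provider_categories & p.target_categories)
        ]
    if criterion == "not_identical":
        return [p for p in pairs if p.provider_categories != p.target_categories]
    raise ValueError(f"unknown cross-pathway criterion {criterion!r}")


@dataclass(frozen=True)
class CrossPathwayCell:
    targets_by_rle: int
    targets_by_all: int

    @property
    def fraction(self) -> float | None:
        return _frac(self.targets_by_rle, self.targets_by_all)


@dataclass
class CrossPathwayMatrix:
    """6x6 source-category × target-category coverage of cross-pathway
    inhibition: per cell, distinct targets inhibited from the source
    category by RLE providers vs by all providers."""

    organism: str
    cells: dict[tuple[PathwayCategory, PathwayCategory], CrossPathwayCell]

    def cell(
        self, source: PathwayCategory, target: PathwayCategory
    ) -> CrossPathwayCell:
        return self.cells[(source, target)]


def cross_pathway_matrix(
    pairs: list[InhibitingPair],
    enzymes: EnzymeIndex,
    organism: str,
) -> CrossPathwayMatrix:
    """Tally the cross-pathway pair list into the 6x6 category matrix.

    A multi-category provider contributes from each of its categories; a
    multi-category target is counted toward each of its categories.  Each
    cell counts distinct target ECs.
    """
    by_all: dict[tuple[PathwayCategory, PathwayCategory], set[str]] = {}
    by_rle: dict[tuple[PathwayCategory, PathwayCategory], set[str]] = {}
    for src in PathwayCategory:
        for tgt in PathwayCategory:
            by_all[(src, tgt)] = set()
            by_rle[(src, tgt)] = set()
    for pair in pairs:
        if pair.organism != organism:
            continue
        for src in pair.provider_categories:
            for tgt in pair.target_categories:
                by_all[(src, tgt)].add(pair.target_ec)
                if pair.provider_is_rle:
                    by_rle[(src, tgt)].add(pair.target_ec)
    cells = {
        key: CrossPathwayCell(
            targets_by_rle=len(by_rle[key]), targets_by_all=len(by_all[key])
        )
        for key in by_all
    }
    return CrossPathwayMatrix(organism=organism, cells=cells)
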