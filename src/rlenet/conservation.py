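"""Cross-organism conserved inhibiting pairs and compound-initiation analysis.

A pair is *conservative* when the same (provider_ec, target_ec) edge occurs
in at least ``min_organisms`` of the analyzed organisms (3 of 5 by
default).  The mediating compound is carried as an attribute, not part of
the pair identity.  The compound-initiation summaries support the ADP
(C00008) vs AMP (C00020) comparison: among conserved pairs initiated by
each nucleotide, how many have a rate-limiting provider, and is the RLE
share higher on the ADP side than chance allows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .network import EnrichmentResult, InhibitingPair, hypergeometric_tail

logger = logging.getLogger(__name__)

__all__ = [
    "ConservativePair",
    "CompoundInitiationSummary",
    "find_conservative_pairs",
    "compound_initiation",
    "adp_vs_amp_enrichment",
    "ADP_COMPOUND",
    "AMP_COMPOUND",
]

# Default KEGG compound identifiers; configurable, not semantic constants.
ADP_COMPOUND = "C00008"
AMP_COMPOUND = "C00020"


@dataclass(frozen=True)
class ConservativePair:
    provider_ec: str
    target_ec: str
    organisms: frozenset[str]
    compounds: frozenset[str]
    provider_is_rle: bool

    @property
    def n_organisms(self) -> int:
        return len(self.organisms)


def find_conservative_pairs(
    pairs_by_organism: dict[str, list[InhibitingPair]],
    min_organisms: int = 3,
) -> list[ConservativePair]:
    """Pairs occurring (as provider→target edges) in >= min_organisms organisms.

    The compound set is the union of mediating inhibitors over all
    organisms where the pair occurs; the provider's global RLE flag labels
    the pair.
    """
    if min_organisms < 2:
        raise ValueError("min_organisms must be at least 2")
    if len(pairs_by_organism) < min_organisms:
        raise ValueError(
            f"only {len(pairs_by_organism)} organisms supplied; "
            f"need at least min_organisms={min_organisms}"
        )
    occurrences: dict[tuple[str, str], dict] = {}
    for organism, pairs in pairs_by_organism.items():
        for p in pairs:
            entry = occurrences.setdefault(
                (p.provider_ec, p.target_ec),
                {"organisms": set(), "compounds": set(), "rle": p.provider_is_rle},
            )
            entry["organisms"].add(organism)
            entry["compounds"].add(p.compound)
    out = [
        ConservativePair(
            provider_ec=prov,
            target_ec=tgt,
            organisms=frozenset(e["organisms"]),
            compounds=frozenset(e["compounds"]),
            provider_is_rle=e["rle"],
        )
        for (prov, tgt), e in sorted(occurrences.items())
        if len(e["organisms"]) >= min_organisms
    ]
    return out


@dataclass(frozen=True)
class CompoundInitiationSummary:
    """Conserved pairs whose mediating-compound set contains ``compound``,
    split by whether the provider is rate-limiting."""

    compound: str
    n_pairs: int
    n_rle_pairs: int

    def __post_init__(self) -> None:
        if self.n_rle_pairs > self.n_pairs:
            raise ValueError("n_rle_pairs exceeds n_pairs")


def compound_initiation(
    conservative_pairs: list[ConservativePair], compound: str
) -> CompoundInitiationSummary:
    """Count conserved pairs initiated by ``compound`` in >= 1 organism."""
    initiated = [p for p in conservative_pairs if compound in p.compounds]
    return CompoundInitiationSummary(
        compound=compound,
        n_pairs=len(initiated),
        n_rle_pairs=sum(1 for p in initiated if p.provider_is_rle),
    )


def adp_vs_amp_enrichment(
    adp: CompoundInitiationSummary, amp: CompoundInitiationSummary
) -> EnrichmentResult | None:
    """Upper-tail hypergeometric on the 2x2 ADP/AMP × RLE/non-RLE table.

    Population: all pairs on either side (N = adp.n + amp.n); successes:
    RLE-provider pairs on either side; sample: the ADP side; k: ADP pairs
    with RLE provider.  Small p means RLE providers concentrate on ADP.
    """
    if adp.n_pairs == 0 or amp.n_pairs == 0:
        logger.warning(
            "ADP/AMP comparison degenerate: %d ADP pairs, %d AMP pairs",
            adp.n_pairs,
            amp.n_pairs,
        )
        return None
    return hypergeometric_tail(
        k=adp.n_rle_pairs,
        n=adp.n_pairs,
        K=adp.n_rle_pairs + amp.n_rle_pairs,
        N=adp.n_pairs + amp.n_pairs,
    )
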