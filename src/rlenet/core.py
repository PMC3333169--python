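"""Domain types for metabolic inhibitory-network analysis.

The analysis revolves around *inhibiting enzyme pairs*: ordered pairs
(provider, target) in one organism, where a metabolic product of the
provider enzyme is an in-vivo inhibitor of the target enzyme.  Enzymes are
identified by EC number, carry a curated rate-limiting-enzyme (RLE) flag,
a set of organisms in which a gene encodes them, and one or more of the
six KEGG pathway categories.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "PathwayCategory",
    "EnzymeRecord",
    "ProductLink",
    "InhibitionLink",
    "GenomePanel",
    "EnzymeIndex",
    "Dataset",
    "is_partial_ec",
    "validate_integrity",
]

#: EC number: four dot-separated fields; trailing fields may be "-" (partial).
_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def is_valid_ec(ec: str) -> bool:
    return bool(_EC_RE.match(ec))


def is_partial_ec(ec: str) -> bool:
    """True for incompletely specified EC numbers such as ``1.1.1.-``."""
    return is_valid_ec(ec) and "-" in ec


class PathwayCategory(enum.Enum):
    """The six KEGG metabolic pathway categories used throughout."""

    CARBOHYDRATE = "Carbohydrate"
    LIPID = "Lipid"
    NUCLEOTIDE = "Nucleotide"
    AMINO_ACID = "AminoAcid"
    COFACTOR_VITAMIN = "CofactorVitamin"
    OTHERS = "Others"

    @classmethod
    def parse(cls, label: str) -> "PathwayCategory":
        """Parse a category label; unknown labels raise ``ValueError``.

        Accepts the canonical tokens used in the TSV dialect plus the
        human-readable KEGG names ("Amino acid", "Cofactor and vitamin").
        """
        key = label.strip()
        alias = _CATEGORY_ALIASES.get(key.lower())
        if alias is None:
            raise ValueError(
                f"unknown pathway category {label!r}; expected one of "
                f"{[c.value for c in cls]}"
            )
        return alias


_CATEGORY_ALIASES: dict[str, PathwayCategory] = {}
for _c in PathwayCategory:
    _CATEGORY_ALIASES[_c.value.lower()] = _c
_CATEGORY_ALIASES.update(
    {
        "amino acid": PathwayCategory.AMINO_ACID,
        "amino_acid": PathwayCategory.AMINO_ACID,
        "cofactor and vitamin": PathwayCategory.COFACTOR_VITAMIN,
        "cofactor_vitamin": PathwayCategory.COFACTOR_VITAMIN,
        "cofactors and vitamins": PathwayCategory.COFACTOR_VITAMIN,
        "other": PathwayCategory.OTHERS,
    }
)


@dataclass(frozen=True)
class EnzymeRecord:
    """One enzyme (EC number) with organism membership and annotations.

    ``is_rle`` is a global curated flag: the enzyme is rate-limiting in at
    least one pathway.  Membership convention: the enzyme belongs to every
    organism with a gene encoding it.
    """

    ec: str
    organisms: frozenset[str]
    is_rle: bool
    categories: frozenset[PathwayCategory]

    def __post_init__(self) -> None:
        if not is_valid_ec(self.ec):
            raise ValueError(f"malformed EC number: {self.ec!r}")
        if not self.organisms:
            raise ValueError(f"enzyme {self.ec}: organism set is empty")
        if not self.categories:
            raise ValueError(f"enzyme {self.ec}: category set is empty")


@dataclass(frozen=True)
class ProductLink:
    """Organism-specific record: enzyme ``ec`` produces compound ``compound``."""

    organism: str
    ec: str
    compound: str


@dataclass(frozen=True)
class InhibitionLink:
    """Organism-specific record: ``compound`` inhibits enzyme ``target_ec``.

    ``in_vivo`` distinguishes naturally occurring intracellular inhibition
    from in-vitro-only annotations; the pipeline filters to in-vivo by
    default.
    """

    organism: str
    compound: str
    target_ec: str
    in_vivo: bool


@dataclass(frozen=True)
class GenomePanel:
    """Ordered reference genome panel over which profiles are built.

    The default panel has 82 slots: 23 prokaryotes followed by 59
    eukaryotes.  The real genome identities are user-supplied; the default
    uses placeholders.
    """

    genomes: tuple[str, ...]
    kingdom: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.kingdom):
            raise ValueError("genomes and kingdom must have equal length")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("genome identifiers must be unique")
        bad = set(self.kingdom) - {"prokaryote", "eukaryote"}
        if bad:
            raise ValueError(f"unknown kingdom tags: {sorted(bad)}")

    @property
    def size(self) -> int:
        return len(self.genomes)

    @classmethod
    def default(cls, n_prokaryotes: int = 23, n_eukaryotes: int = 59) -> "GenomePanel":
        genomes = tuple(
            [f"prok{i + 1:02d}" for i in range(n_prokaryotes)]
            + [f"euk{i + 1:02d}" for i in range(n_eukaryotes)]
        )
        kingdom = ("prokaryote",) * n_prokaryotes + ("eukaryote",) * n_eukaryotes
        return cls(genomes=genomes, kingdom=kingdom)


class EnzymeIndex:
    """EC-keyed lookup over a set of :class:`EnzymeRecord`."""

    def __init__(self, records: Iterable[EnzymeRecord]):
        self._by_ec: dict[str, EnzymeRecord] = {}
        for rec in records:
            if rec.ec in self._by_ec:
                raise ValueError(f"duplicate EC in index: {rec.ec}")
            self._by_ec[rec.ec] = rec

    def __contains__(self, ec: str) -> bool:
        return ec in self._by_ec

    def __getitem__(self, ec: str) -> EnzymeRecord:
        return self._by_ec[ec]

    def __len__(self) -> int:
        return len(self._by_ec)

    def __iter__(self) -> Iterator[EnzymeRecord]:
        return iter(self._by_ec.values())

    def get(self, ec: str) -> EnzymeRecord | None:
        return self._by_ec.get(ec)

    def is_rle(self, ec: str) -> bool:
        return self._by_ec[ec].is_rle

    def categories(self, ec: str) -> frozenset[PathwayCategory]:
        return self._by_ec[ec].categories

    @property
    def organisms(self) -> set[str]:
        out: set[str] = set()
        for rec in self._by_ec.values():
            out |= rec.organisms
        return out

    def enzymes_in(
        self, organism: str, category: PathwayCategory | None = None
    ) -> list[EnzymeRecord]:
        """Enzymes present in ``organism``, optionally restricted to a category."""
        return [
            rec
            for rec in self._by_ec.values()
            if organism in rec.organisms
            and (category is None or category in rec.categories)
        ]

    def partial_ecs(self) -> list[str]:
        """Partial EC numbers carried as opaque identifiers (validation report)."""
        return sorted(ec for ec in self._by_ec if is_partial_ec(ec))


@dataclass
class Dataset:
    """A complete analysis input: enzymes, links and the presence matrix."""

    enzymes: EnzymeIndex
    products: list[ProductLink]
    inhibitions: list[InhibitionLink]
    presence: dict[str, np.ndarray] = field(default_factory=dict)
    panel: GenomePanel = field(default_factory=GenomePanel.default)

    @property
    def organisms(self) -> list[str]:
        return sorted(self.enzymes.organisms)


def validate_integrity(dataset: Dataset) -> list[str]:
    """Referential-integrity check; returns every violation (empty = pass).

    Every product/inhibition link must reference a known enzyme that lists
    the link's organism, and every presence vector must match the panel.
    """
    violations: list[str] = []
    enzymes = dataset.enzymes
    for link in dataset.products:
        rec = enzymes.get(link.ec)
        if rec is None:
            violations.append(f"product link {link.organism}/{link.ec}: unknown EC")
        elif link.organism not in rec.organisms:
            violations.append(
                f"product link {link.organism}/{link.ec}: enzyme does not list organism"
            )
    for link in dataset.inhibitions:
        rec = enzymes.get(link.target_ec)
        if rec is None:
            violations.append(
                f"inhibition link {link.organism}/{link.target_ec}: unknown EC"
            )
        elif link.organism not in rec.organisms:
            violations.append(
                f"inhibition link {link.organism}/{link.target_ec}: "
                "enzyme does not list organism"
            )
    for ec, bits in dataset.presence.items():
        if len(bits) != dataset.panel.size:
            violations.append(
                f"presence vector {ec}: length {len(bits)} != panel size "
                f"{dataset.panel.size}"
            )
    return violations
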