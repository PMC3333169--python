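"""Synthetic multi-organism datasets with planted inhibitory structure.

The generator emits the four analysis tables (enzymes, products,
inhibitions, presence matrix) for a panel of model organisms, with the
statistical structure the pipeline is designed to detect planted at
configurable strength:

* ``inhibitor_boost`` raises the probability that a compound produced by a
  rate-limiting enzyme is an in-vivo inhibitor (inhibitor-production
  enrichment);
* ``p_rle_target_boost`` up-weights RLEs when inhibitor targets are drawn
  (target enrichment);
* ``rho_pair`` couples the phylogenetic profiles of enzymes joined by an
  inhibiting pair whose provider is rate-limiting, with 1.5x strength when
  both members are (class-mean ordering of Jaccard similarities);
* ``p_shared_across_organisms`` controls how often an enzyme — and hence
  its links — recurs in organisms beyond the first, planting conserved
  pairs.

With ``inhibitor_boost=1``, ``p_rle_target_boost=1`` and ``rho_pair=0``
the tables are exchangeable between RLEs and non-RLEs: every downstream
enrichment test is then an exact null, which the calibration tests exploit.

All randomness flows from one seed through named, deterministically
derived sub-streams, so identical configurations produce byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    Dataset,
    EnzymeIndex,
    EnzymeRecord,
    GenomePanel,
    InhibitionLink,
    PathwayCategory,
    ProductLink,
)
from . import io as rio

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "profile_coupling",
           "write_run"]

#: Conventional identifiers for the five model organisms; extra organisms
#: get generic names.
_ORGANISM_CONVENTIONS = ("hsa", "mmu", "rno", "sce", "eco")

_CATEGORIES = tuple(PathwayCategory)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults are the study conditions.

    Counts are Poisson with the configured mean, truncated at >= 1 where a
    zero would break invariants.  Probability boosts multiply a base
    probability and are clipped into [0, 1].
    """

    seed: int = 0
    n_organisms: int = 5
    n_enzymes: int = 400
    rle_fraction: float = 0.25
    n_compounds: int = 350
    products_per_enzyme: float = 2.0
    p_inhibitor_base: float = 0.2
    inhibitor_boost: float = 2.0
    targets_per_inhibitor: float = 4.0
    p_rle_target_boost: float = 2.0
    n_prokaryotes: int = 23
    n_eukaryotes: int = 59
    p_presence_base: float = 0.5
    rho_pair: float = 0.6
    p_in_vitro_extra: float = 0.1
    p_shared_across_organisms: float = 0.7

    def __post_init__(self) -> None:
        for name in ("rle_fraction", "p_inhibitor_base", "p_presence_base",
                     "rho_pair", "p_in_vitro_extra", "p_shared_across_organisms"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        for name in ("inhibitor_boost", "p_rle_target_boost"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1; got {getattr(self, name)}")
        for name in ("n_organisms", "n_enzymes", "n_compounds",
                     "n_prokaryotes", "n_eukaryotes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.products_per_enzyme < 0 or self.targets_per_inhibitor < 0:
            raise ValueError("count means must be non-negative")

    @property
    def panel_size(self) -> int:
        return self.n_prokaryotes + self.n_eukaryotes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Realized planted quantities, consistent with the emitted tables."""

    rle_ecs: list[str]
    rho_eff_by_class: dict[str, float]
    inhibitor_fraction_by_organism: dict[str, float | None]
    n_template_pairs_by_class: dict[str, int]
    conservative_pairs_min3: list[list]  # [provider, target, n_organisms]

    def to_dict(self) -> dict:
        return {
            "rle_ecs": self.rle_ecs,
            "rho_eff_by_class": self.rho_eff_by_class,
            "inhibitor_fraction_by_organism": self.inhibitor_fraction_by_organism,
            "n_template_pairs_by_class": self.n_template_pairs_by_class,
            "conservative_pairs_min3": self.conservative_pairs_min3,
        }


def _organism_names(n: int) -> list[str]:
    names = list(_ORGANISM_CONVENTIONS[:n])
    names += [f"org{i + 1:02d}" for i in range(len(names), n)]
    return names


def _ec_name(i: int) -> str:
    return f"{i % 6 + 1}.{(i // 6) % 25 + 1}.{(i // 150) % 25 + 1}.{i + 1}"


def _trunc_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    return np.maximum(1, rng.poisson(mean, size=size))


def profile_coupling(
    pair_class: str,
    rho_pair: float,
    provider_bits: np.ndarray,
    target_bits: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Couple a target profile to its provider's at the class strength.

    Each genome position of the target is copied from the provider with
    probability ``rho_eff`` and keeps its independent draw otherwise,
    where rho_eff = rho_pair for rle_provider pairs, min(1, 1.5*rho_pair)
    for rle_both pairs, and 0 for pairs with a non-rate-limiting provider.
    Expected Jaccard rises monotonically in rho_eff.
    """
    rho_eff = _rho_eff(pair_class, rho_pair)
    if rho_eff == 0.0:
        return target_bits.copy()
    mask = rng.random(len(target_bits)) < rho_eff
    return np.where(mask, provider_bits, target_bits)


_CLASS_RANK = {"common": 0, "rle_provider": 1, "rle_both": 2}


def _rho_eff(pair_class: str, rho_pair: float) -> float:
    if pair_class == "rle_both":
        return min(1.0, 1.5 * rho_pair)
    if pair_class == "rle_provider":
        return rho_pair
    if pair_class == "common":
        return 0.0
    raise ValueError(f"unknown pair class {pair_class!r}")


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic dataset and its ground truth.

    A global template (enzyme products, inhibitor annotations, targets) is
    drawn once; each organism instantiates the links of the enzymes it
    contains.  The first organism contains every enzyme; each further
    organism contains each enzyme independently with probability
    ``p_shared_across_organisms``, so an inhibiting pair recurs in an
    organism exactly when both members do.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("flags", "categories", "products", "inhibitors", "targets",
             "membership", "presence", "coupling"),
            ss.spawn(8),
        )
    }
    n = config.n_enzymes
    ecs = [_ec_name(i) for i in range(n)]

    # RLE flags: a uniform random subset of the configured size.
    n_rle = int(round(config.rle_fraction * n))
    rle_idx = np.sort(streams["flags"].choice(n, size=n_rle, replace=False))
    is_rle = np.zeros(n, dtype=bool)
    is_rle[rle_idx] = True

    # Pathway categories: one uniform category, a second with prob 0.15.
    rng_cat = streams["categories"]
    primary = rng_cat.integers(0, 6, size=n)
    second = rng_cat.random(n) < 0.15
    second_cat = (primary + 1 + rng_cat.integers(0, 5, size=n)) % 6
    categories: list[frozenset[PathwayCategory]] = []
    for i in range(n):
        cats = {_CATEGORIES[primary[i]]}
        if second[i]:
            cats.add(_CATEGORIES[second_cat[i]])
        categories.append(frozenset(cats))

    # Product template: each enzyme produces >= 1 distinct compounds.
    rng_prod = streams["products"]
    prod_counts = _trunc_poisson(rng_prod, config.products_per_enzyme, n)
    products_template: list[tuple[int, int]] = []  # (enzyme, compound)
    producers: dict[int, set[int]] = {}
    for i in range(n):
        cnt = min(int(prod_counts[i]), config.n_compounds)
        for c in rng_prod.choice(config.n_compounds, size=cnt, replace=False):
            products_template.append((i, int(c)))
            producers.setdefault(int(c), set()).add(i)

    # In-vivo inhibitor status of produced compounds: base probability,
    # boosted when some producer is rate-limiting.
    rng_inh = streams["inhibitors"]
    produced = sorted(producers)
    rle_produced = {c for c in produced if any(is_rle[e] for e in producers[c])}
    inhibitors: list[int] = []
    for c in produced:
        p = config.p_inhibitor_base
        if c in rle_produced:
            p = min(1.0, p * config.inhibitor_boost)
        if rng_inh.random() < p:
            inhibitors.append(c)

    # Inhibition targets: weighted draw over enzymes (RLEs up-weighted).
    rng_tgt = streams["targets"]
    weights = np.where(is_rle, config.p_rle_target_boost, 1.0)
    weights = weights / weights.sum()
    inhibitions_template: list[tuple[int, int, bool]] = []  # (compound, target, in_vivo)
    tgt_counts = _trunc_poisson(rng_tgt, config.targets_per_inhibitor, len(inhibitors))
    for c, cnt in zip(inhibitors, tgt_counts):
        cnt = min(int(cnt), n)
        for t in rng_tgt.choice(n, size=cnt, replace=False, p=weights):
            inhibitions_template.append((c, int(t), True))
    # A few in-vitro-only annotations on non-inhibitor produced compounds,
    # to exercise the in-vivo filter.
    non_inhibitors = [c for c in produced if c not in set(inhibitors)]
    for c in non_inhibitors:
        if rng_tgt.random() < config.p_in_vitro_extra:
            t = int(rng_tgt.integers(0, n))
            inhibitions_template.append((c, t, False))

    # Organism membership: anchor organism holds everything.
    organisms = _organism_names(config.n_organisms)
    rng_mem = streams["membership"]
    member = np.zeros((n, config.n_organisms), dtype=bool)
    member[:, 0] = True
    if config.n_organisms > 1:
        member[:, 1:] = (
            rng_mem.random((n, config.n_organisms - 1))
            < config.p_shared_across_organisms
        )

    # Presence matrix: independent Bernoulli base profiles, then pair
    # coupling.  For a target of several template pairs only the single
    # strongest coupling applies, copying from the provider's base profile.
    rng_pres = streams["presence"]
    base = (
        rng_pres.random((n, config.panel_size)) < config.p_presence_base
    ).astype(np.int8)
    pair_class_of: dict[tuple[int, int], str] = {}
    inhibitor_targets: dict[int, set[int]] = {}
    for c, t, in_vivo in inhibitions_template:
        if in_vivo:
            inhibitor_targets.setdefault(c, set()).add(t)
    for c, tgts in inhibitor_targets.items():
        for e in producers.get(c, ()):
            for t in tgts:
                if not is_rle[e]:
                    cls = "common"
                elif is_rle[t]:
                    cls = "rle_both"
                else:
                    cls = "rle_provider"
                prev = pair_class_of.get((e, t))
                if prev is None or _CLASS_RANK[cls] > _CLASS_RANK[prev]:
                    pair_class_of[(e, t)] = cls
    rng_cpl = streams["coupling"]
    bits = base.copy()
    strongest: dict[int, tuple[float, int, str]] = {}
    for (e, t), cls in sorted(pair_class_of.items()):
        rho = _rho_eff(cls, config.rho_pair)
        if rho == 0.0 or e == t:
            continue
        cur = strongest.get(t)
        if cur is None or rho > cur[0] or (rho == cur[0] and e < cur[1]):
            strongest[t] = (rho, e, cls)
    for t in sorted(strongest):
        rho, e, cls = strongest[t]
        bits[t] = profile_coupling(cls, config.rho_pair, base[e], base[t], rng_cpl)

    # Assemble per-organism tables.
    records = [
        EnzymeRecord(
            ec=ecs[i],
            organisms=frozenset(
                organisms[j] for j in range(config.n_organisms) if member[i, j]
            ),
            is_rle=bool(is_rle[i]),
            categories=categories[i],
        )
        for i in range(n)
    ]
    compound_name = [f"C{c + 1:05d}" for c in range(config.n_compounds)]
    products: list[ProductLink] = []
    for e, c in products_template:
        for j in range(config.n_organisms):
            if member[e, j]:
                products.append(
                    ProductLink(
                        organism=organisms[j], ec=ecs[e], compound=compound_name[c]
                    )
                )
    inhibitions: list[InhibitionLink] = []
    for c, t, in_vivo in inhibitions_template:
        for j in range(config.n_organisms):
            if member[t, j]:
                inhibitions.append(
                    InhibitionLink(
                        organism=organisms[j],
                        compound=compound_name[c],
                        target_ec=ecs[t],
                        in_vivo=in_vivo,
                    )
                )
    panel = GenomePanel.default(config.n_prokaryotes, config.n_eukaryotes)
    dataset = Dataset(
        enzymes=EnzymeIndex(records),
        products=products,
        inhibitions=inhibitions,
        presence={ecs[i]: bits[i] for i in range(n)},
        panel=panel,
    )

    # Ground truth, tallied directly from the templates.
    inhibitor_set = set(inhibitors)
    frac_by_org: dict[str, float | None] = {}
    for j, org in enumerate(organisms):
        inh_here = {
            c for c, t, iv in inhibitions_template if iv and member[t, j]
        }
        rle_prod_here = {
            c
            for c in produced
            if any(is_rle[e] and member[e, j] for e in producers[c])
        }
        frac_by_org[org] = (
            len(inh_here & rle_prod_here) / len(inh_here) if inh_here else None
        )
    n_by_class = {"common": 0, "rle_provider": 0, "rle_both": 0}
    for cls in pair_class_of.values():
        n_by_class[cls] += 1
    conservative: list[list] = []
    for (e, t), _cls in sorted(pair_class_of.items()):
        n_org = int(np.count_nonzero(member[e] & member[t]))
        if n_org >= 3:
            conservative.append([ecs[e], ecs[t], n_org])
    truth = GroundTruth(
        rle_ecs=[ecs[i] for i in range(n) if is_rle[i]],
        rho_eff_by_class={
            cls: _rho_eff(cls, config.rho_pair) for cls in n_by_class
        },
        inhibitor_fraction_by_organism=frac_by_org,
        n_template_pairs_by_class=n_by_class,
        conservative_pairs_min3=conservative,
    )
    logger.info(
        "generated dataset: %d enzymes (%d RLE), %d product links, "
        "%d inhibition links, %d organisms",
        n, n_rle, len(products), len(inhibitions), config.n_organisms,
    )
    return dataset, truth


def write_run(
    config: GeneratorConfig, directory: str | Path
) -> tuple[Dataset, GroundTruth]:
    """Generate and write a dataset directory with manifest and ground truth."""
    import hashlib

    directory = Path(directory)
    dataset, truth = generate(config)
    rio.write_dataset(dataset, directory)
    (directory / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    hashes = {}
    for name in sorted(rio.DATASET_FILES.values()) + ["ground_truth.json"]:
        path = directory / name
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"config": config.to_dict(), "sha256": hashes}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return dataset, truth
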