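"""Phylogenetic profiles, Jaccard similarity and group comparisons.

A phylogenetic profile is a 0/1 vector recording the presence of an
enzyme's genes across an ordered reference genome panel (82 genomes by
default: 23 prokaryotes + 59 eukaryotes).  Similarity of two profiles is
the Jaccard coefficient J = M11 / (M01 + M10 + M11), which ignores joint
absences (M00).  Pair classes follow the nested grouping used for the
class comparison: *common* = all pairs; *rle_provider* = provider is a
rate-limiting enzyme; *rle_both* = both members are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EnzymeIndex, GenomePanel
from .network import InhibitingPair

logger = logging.getLogger(__name__)

__all__ = [
    "PhylogeneticProfile",
    "ProfilePairCounts",
    "JaccardScore",
    "ScoredPair",
    "GroupComparison",
    "PAIR_CLASSES",
    "build_profile",
    "pair_counts",
    "jaccard",
    "score_pairs",
    "class_means",
    "welch_t_test",
    "class_similarity_analysis",
]

#: Nested pair classes, most inclusive first.
PAIR_CLASSES = ("common", "rle_provider", "rle_both")


@dataclass(frozen=True)
class PhylogeneticProfile:
    """0/1 presence vector of one enzyme over the genome panel."""

    ec: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"profile {self.ec}: entries must be 0 or 1")


def build_profile(
    ec: str,
    presence: dict[str, np.ndarray],
    panel: GenomePanel,
    strict: bool = True,
) -> PhylogeneticProfile:
    """Wrap the stored presence vector of ``ec`` as a profile.

    In lenient mode an EC absent from the presence map yields an all-zero
    profile with a logged warning; strict mode raises.
    """
    bits = presence.get(ec)
    if bits is None:
        if strict:
            raise KeyError(f"no presence vector for EC {ec}")
        logger.warning("no presence vector for EC %s; using all-zero profile", ec)
        return PhylogeneticProfile(ec=ec, bits=(0,) * panel.size)
    if len(bits) != panel.size:
        raise ValueError(
            f"presence vector for {ec} has length {len(bits)}, panel size "
            f"is {panel.size}"
        )
    return PhylogeneticProfile(ec=ec, bits=tuple(int(b) for b in bits))


@dataclass(frozen=True)
class ProfilePairCounts:
    """Positional agreement counts of two equal-length binary profiles."""

    m11: int
    m01: int
    m10: int
    m00: int

    @property
    def total(self) -> int:
        return self.m11 + self.m01 + self.m10 + self.m00


def pair_counts(a: PhylogeneticProfile, b: PhylogeneticProfile) -> ProfilePairCounts:
    if len(a.bits) != len(b.bits):
        raise ValueError(
            f"profile length mismatch: {len(a.bits)} vs {len(b.bits)}"
        )
    va = np.asarray(a.bits, dtype=bool)
    vb = np.asarray(b.bits, dtype=bool)
    return ProfilePairCounts(
        m11=int(np.count_nonzero(va & vb)),
        m01=int(np.count_nonzero(~va & vb)),
        m10=int(np.count_nonzero(va & ~vb)),
        m00=int(np.count_nonzero(~va & ~vb)),
    )


@dataclass(frozen=True)
class JaccardScore:
    """J = M11 / (M01 + M10 + M11); undefined when both profiles are
    all-zero (the data then support no similarity statement)."""

    value: float | None
    defined: bool


def jaccard(counts: ProfilePairCounts) -> JaccardScore:
    denom = counts.m11 + counts.m01 + counts.m10
    if denom == 0:
        return JaccardScore(value=None, defined=False)
    return JaccardScore(value=counts.m11 / denom, defined=True)


@dataclass(frozen=True)
class ScoredPair:
    """One distinct (provider, target) pair with its similarity score."""

    organism: str
    provider_ec: str
    target_ec: str
    provider_is_rle: bool
    target_is_rle: bool
    score: JaccardScore

    def in_class(self, pair_class: str) -> bool:
        if pair_class == "common":
            return True
        if pair_class == "rle_provider":
            return self.provider_is_rle
        if pair_class == "rle_both":
            return self.provider_is_rle and self.target_is_rle
        raise ValueError(f"unknown pair class {pair_class!r}")


def score_pairs(
    pairs: list[InhibitingPair],
    profiles: dict[str, PhylogeneticProfile],
    panel: GenomePanel | None = None,
) -> list[ScoredPair]:
    """Jaccard-score each distinct (provider_ec, target_ec) pair once.

    Compound multiplicity is collapsed so a pair mediated by several
    inhibitors is not over-weighted.  Pairs whose score is undefined are
    returned flagged; aggregation excludes them with a logged count.
    """
    distinct: dict[tuple[str, str, str], InhibitingPair] = {}
    for p in pairs:
        distinct.setdefault((p.organism, p.provider_ec, p.target_ec), p)
    scored: list[ScoredPair] = []
    size = panel.size if panel is not None else None
    for (organism, prov, tgt), pair in sorted(distinct.items()):
        a = profiles.get(prov)
        b = profiles.get(tgt)
        if a is None or b is None:
            missing = prov if a is None else tgt
            if size is None:
                raise KeyError(f"no profile for EC {missing}")
            logger.warning("no profile for EC %s; using all-zero profile", missing)
            zero = PhylogeneticProfile(ec=missing, bits=(0,) * size)
            a = a if a is not None else zero
            b = b if b is not None else zero
        scored.append(
            ScoredPair(
                organism=organism,
                provider_ec=prov,
                target_ec=tgt,
                provider_is_rle=pair.provider_is_rle,
                target_is_rle=pair.target_is_rle,
                score=jaccard(pair_counts(a, b)),
            )
        )
    return scored


def _defined_scores(scored: list[ScoredPair], pair_class: str) -> np.ndarray:
    values = [
        s.score.value
        for s in scored
        if s.in_class(pair_class) and s.score.defined
    ]
    n_undef = sum(
        1 for s in scored if s.in_class(pair_class) and not s.score.defined
    )
    if n_undef:
        logger.info(
            "class %s: excluded %d pairs with undefined Jaccard", pair_class, n_undef
        )
    return np.asarray(values, dtype=float)


def class_means(scored: list[ScoredPair]) -> dict[str, tuple[int, float | None]]:
    """Per-class (n, mean Jaccard) over defined scores; mean None if empty."""
    out: dict[str, tuple[int, float | None]] = {}
    for cls in PAIR_CLASSES:
        vals = _defined_scores(scored, cls)
        out[cls] = (len(vals), float(vals.mean()) if len(vals) else None)
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Welch (unequal-variance) t-test between two score groups."""

    group_label_a: str
    group_label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    alternative: str


def welch_t_test(
    scores_a: np.ndarray | list[float],
    scores_b: np.ndarray | list[float],
    alternative: str = "greater",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison | None:
    """Welch's t-test with Welch–Satterthwaite degrees of freedom.

    ``alternative="greater"`` tests mean(a) > mean(b), the directional
    hypothesis used for the class comparisons.  Returns None (with a
    warning) for groups of fewer than two scores or when both groups are
    constant, where the statistic is undefined.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        logger.warning(
            "Welch test skipped: group sizes %d, %d below 2", len(a), len(b)
        )
        return None
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        logger.warning("Welch test degenerate: both groups constant")
        return None
    scipy_alt = "greater" if alternative == "greater" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=scipy_alt)
    return GroupComparison(
        group_label_a=label_a,
        group_label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
    )


@dataclass
class ClassSimilarityResult:
    """Per-class mean similarities and the two directional comparisons."""

    organism: str
    means: dict[str, tuple[int, float | None]]
    comparisons: list[GroupComparison]


def class_similarity_analysis(
    pairs: list[InhibitingPair],
    profiles: dict[str, PhylogeneticProfile],
    enzymes: EnzymeIndex,
    organism: str,
    panel: GenomePanel | None = None,
    alternative: str = "greater",
) -> ClassSimilarityResult:
    """Mean Jaccard per pair class plus the two class comparisons.

    Compares rle_provider vs common (are RLE-provider pairs more tightly
    co-occurring than inhibiting pairs at large?) and rle_both vs
    rle_provider.
    """
    org_pairs = [p for p in pairs if p.organism == organism]
    scored = score_pairs(org_pairs, profiles, panel=panel)
    means = class_means(scored)
    comparisons: list[GroupComparison] = []
    for cls_a, cls_b in (("rle_provider", "common"), ("rle_both", "rle_provider")):
        cmp = welch_t_test(
            _defined_scores(scored, cls_a),
            _defined_scores(scored, cls_b),
            alternative=alternative,
            label_a=cls_a,
            label_b=cls_b,
        )
        if cmp is not None:
            comparisons.append(cmp)
    return ClassSimilarityResult(
        organism=organism, means=means, comparisons=comparisons
    )
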