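"""End-to-end analysis runs: orchestration, TSV/JSON output, manifests.

``run_full_analysis`` executes every stage of the pipeline on a dataset —
per-organism inhibitor production, provider/target coverage and
enrichments, cross-pathway matrices, profile-similarity class comparisons,
and the conservation + compound-initiation analysis — and writes one TSV
per table plus a single JSON summary.  Outputs contain no timestamps, so
reruns with identical configuration and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import (
    ADP_COMPOUND,
    AMP_COMPOUND,
    adp_vs_amp_enrichment,
    compound_initiation,
    find_conservative_pairs,
)
from .core import Dataset, PathwayCategory, validate_integrity
from .network import (
    build_pairs,
    coverage_report,
    cross_pathway_matrix,
    cross_pathway_pairs,
    enrichment_inhibitor_production,
    enrichment_rle_targets,
    inhibitor_production_stats,
)
from .profiles import build_profile, class_similarity_analysis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    organisms: list[str] | None = None  # None = every organism in the data
    in_vivo_only: bool = True
    include_self_pairs: bool = True
    cross_pathway_criterion: str = "disjoint"
    min_organisms: int = 3
    adp_compound: str = ADP_COMPOUND
    amp_compound: str = AMP_COMPOUND
    alternative: str = "greater"
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class IntegrityFailure(RuntimeError):
    """Dataset failed referential-integrity validation."""


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _fmt(x: float | None) -> float | None:
    return None if x is None else float(x)


def run_full_analysis(
    dataset: Dataset, config: RunConfig, out_dir: str | Path
) -> dict:
    """Run the whole pipeline and write the report bundle; returns the summary.

    Aborts with a consolidated violation report if referential integrity
    fails.  Every number in the JSON summary comes from exactly one
    upstream operation; the reporter only collects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    violations = validate_integrity(dataset)
    if violations:
        raise IntegrityFailure(
            "dataset integrity check failed:\n" + "\n".join(violations)
        )
    organisms = config.organisms or dataset.organisms
    meta = {"version": __version__, "config_hash": config.config_hash()}

    profiles = {
        ec: build_profile(ec, dataset.presence, dataset.panel, strict=False)
        for ec in sorted({rec.ec for rec in dataset.enzymes})
    }

    pair_rows, stats_rows, enr_prod_rows = [], [], []
    coverage_rows, enr_target_rows, xpw_rows = [], [], []
    sim_rows, cmp_rows = [], []
    pairs_by_organism = {}
    summary: dict = {"meta": meta, "organisms": {}}

    for organism in organisms:
        pairs = build_pairs(
            dataset.products,
            dataset.inhibitions,
            dataset.enzymes,
            organism,
            in_vivo_only=config.in_vivo_only,
            include_self_pairs=config.include_self_pairs,
        )
        pairs_by_organism[organism] = pairs
        for p in pairs:
            pair_rows.append(
                {
                    "organism": p.organism,
                    "provider_ec": p.provider_ec,
                    "target_ec": p.target_ec,
                    "compound": p.compound,
                    "provider_is_rle": int(p.provider_is_rle),
                    "target_is_rle": int(p.target_is_rle),
                    "self_pair": int(p.is_self_pair),
                }
            )

        stats = inhibitor_production_stats(
            dataset.products, dataset.inhibitions, dataset.enzymes, organism
        )
        stats_rows.append(
            {
                "organism": organism,
                "n_inhibitors": stats.n_inhibitors,
                "n_rle_produced": stats.n_rle_produced,
                "fraction": _fmt(stats.fraction),
                "percent": stats.percent,
            }
        )
        enr_prod = enrichment_inhibitor_production(
            dataset.products, dataset.inhibitions, dataset.enzymes, organism
        )
        if enr_prod is not None:
            enr_prod_rows.append(
                {"organism": organism, "k": enr_prod.k, "n": enr_prod.n,
                 "K": enr_prod.K, "N": enr_prod.N, "p": enr_prod.p_value}
            )

        for category in [None, *PathwayCategory]:
            cov = coverage_report(pairs, dataset.enzymes, organism, category)
            coverage_rows.append(
                {
                    "organism": organism,
                    "category": category.value if category else "Total",
                    "providers_all": cov.providers_all,
                    "providers_rle": cov.providers_rle,
                    "targets_all": cov.targets_all,
                    "targets_by_rle": cov.targets_by_rle,
                    "targets_rle": cov.targets_rle,
                    "rle_targets_inhibited_by_rle": cov.rle_targets_inhibited_by_rle,
                    "frac_providers_rle": _fmt(cov.frac_providers_rle),
                    "frac_targets_by_rle": _fmt(cov.frac_targets_by_rle),
                    "frac_targets_rle": _fmt(cov.frac_targets_rle),
                    "frac_rle_targets_by_rle": _fmt(cov.frac_rle_targets_by_rle),
                }
            )
            enr = enrichment_rle_targets(pairs, dataset.enzymes, organism, category)
            if enr is not None:
                enr_target_rows.append(
                    {"organism": organism,
                     "category": category.value if category else "Total",
                     "k": enr.k, "n": enr.n, "K": enr.K, "N": enr.N,
                     "p": enr.p_value}
                )

        xpairs = cross_pathway_pairs(pairs, config.cross_pathway_criterion)
        matrix = cross_pathway_matrix(xpairs, dataset.enzymes, organism)
        for (src, tgt), cell in sorted(
            matrix.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            xpw_rows.append(
                {
                    "organism": organism,
                    "source_category": src.value,
                    "target_category": tgt.value,
                    "targets_by_rle": cell.targets_by_rle,
                    "targets_by_all": cell.targets_by_all,
                    "fraction": _fmt(cell.fraction),
                }
            )

        sim = class_similarity_analysis(
            pairs, profiles, dataset.enzymes, organism,
            panel=dataset.panel, alternative=config.alternative,
        )
        for cls, (n, mean) in sim.means.items():
            sim_rows.append(
                {"organism": organism, "pair_class": cls, "n_pairs": n,
                 "mean_jaccard": _fmt(mean)}
            )
        for cmp in sim.comparisons:
            cmp_rows.append(
                {
                    "organism": organism,
                    "group_a": cmp.group_label_a,
                    "group_b": cmp.group_label_b,
                    "n_a": cmp.n_a,
                    "n_b": cmp.n_b,
                    "mean_a": cmp.mean_a,
                    "mean_b": cmp.mean_b,
                    "t": cmp.t_statistic,
                    "p": cmp.p_value,
                    "alternative": cmp.alternative,
                }
            )

        total_cov = coverage_report(pairs, dataset.enzymes, organism, None)
        summary["organisms"][organism] = {
            "n_pairs": len(pairs),
            "n_distinct_provider_target": len(
                {(p.provider_ec, p.target_ec) for p in pairs}
            ),
            "n_cross_pathway_pairs": len(xpairs),
            "inhibitor_production": {
                "n_inhibitors": stats.n_inhibitors,
                "n_rle_produced": stats.n_rle_produced,
                "percent": stats.percent,
                "enrichment_p": enr_prod.p_value if enr_prod else None,
            },
            "coverage_total": {
                "providers_all": total_cov.providers_all,
                "providers_rle": total_cov.providers_rle,
                "targets_all": total_cov.targets_all,
                "targets_by_rle": total_cov.targets_by_rle,
                "frac_providers_rle": _fmt(total_cov.frac_providers_rle),
                "frac_targets_by_rle": _fmt(total_cov.frac_targets_by_rle),
            },
            "profile_similarity": {
                "means": {
                    cls: {"n": n, "mean": _fmt(mean)}
                    for cls, (n, mean) in sim.means.items()
                },
                "comparisons": [
                    {"a": c.group_label_a, "b": c.group_label_b,
                     "t": c.t_statistic, "p": c.p_value}
                    for c in sim.comparisons
                ],
            },
        }

    # Conservation runs over every analyzed organism at once.
    conservation_summary: dict = {}
    cons_rows, init_rows = [], []
    if len(pairs_by_organism) >= config.min_organisms:
        cons = find_conservative_pairs(pairs_by_organism, config.min_organisms)
        for cp in cons:
            cons_rows.append(
                {
                    "provider_ec": cp.provider_ec,
                    "target_ec": cp.target_ec,
                    "n_organisms": cp.n_organisms,
                    "organisms": ",".join(sorted(cp.organisms)),
                    "compounds": ",".join(sorted(cp.compounds)),
                    "provider_is_rle": int(cp.provider_is_rle),
                }
            )
        adp = compound_initiation(cons, config.adp_compound)
        amp = compound_initiation(cons, config.amp_compound)
        enr = adp_vs_amp_enrichment(adp, amp)
        for s in (adp, amp):
            init_rows.append(
                {"compound": s.compound, "n_pairs": s.n_pairs,
                 "n_rle_pairs": s.n_rle_pairs}
            )
        conservation_summary = {
            "n_conservative_pairs": len(cons),
            "n_rle_provider_pairs": sum(1 for c in cons if c.provider_is_rle),
            "adp": {"n_pairs": adp.n_pairs, "n_rle_pairs": adp.n_rle_pairs},
            "amp": {"n_pairs": amp.n_pairs, "n_rle_pairs": amp.n_rle_pairs},
            "adp_vs_amp_p": enr.p_value if enr is not None else None,
        }
    else:
        logger.warning(
            "conservation analysis skipped: %d organisms < min_organisms=%d",
            len(pairs_by_organism), config.min_organisms,
        )
    summary["conservation"] = conservation_summary

    tables = {
        "pairs.tsv": pd.DataFrame(
            pair_rows,
            columns=["organism", "provider_ec", "target_ec", "compound",
                     "provider_is_rle", "target_is_rle", "self_pair"],
        ),
        "inhibitor_production.tsv": pd.DataFrame(stats_rows),
        "inhibitor_production_enrichment.tsv": pd.DataFrame(
            enr_prod_rows, columns=["organism", "k", "n", "K", "N", "p"]
        ),
        "coverage.tsv": pd.DataFrame(coverage_rows),
        "target_enrichment.tsv": pd.DataFrame(
            enr_target_rows,
            columns=["organism", "category", "k", "n", "K", "N", "p"],
        ),
        "cross_pathway_matrix.tsv": pd.DataFrame(xpw_rows),
        "profile_similarity.tsv": pd.DataFrame(sim_rows),
        "profile_comparisons.tsv": pd.DataFrame(
            cmp_rows,
            columns=["organism", "group_a", "group_b", "n_a", "n_b",
                     "mean_a", "mean_b", "t", "p", "alternative"],
        ),
        "conservative_pairs.tsv": pd.DataFrame(
            cons_rows,
            columns=["provider_ec", "target_ec", "n_organisms", "organisms",
                     "compounds", "provider_is_rle"],
        ),
        "compound_initiation.tsv": pd.DataFrame(
            init_rows, columns=["compound", "n_pairs", "n_rle_pairs"]
        ),
    }
    for name, df in tables.items():
        for col in ("version", "config_hash"):
            df[col] = meta[col]
        _write_tsv(df, out_dir / name)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
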