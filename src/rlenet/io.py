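"""Readers and writers for the tab-separated input and output tables.

Dialect: TSV with a header row, UTF-8, list-valued fields comma-separated.
The presence matrix has the EC in the first column and one column per panel
genome, in panel order.  Writers sort set-valued fields so that identical
in-memory datasets always serialize to identical bytes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Dataset,
    EnzymeIndex,
    EnzymeRecord,
    GenomePanel,
    InhibitionLink,
    PathwayCategory,
    ProductLink,
    is_valid_ec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_enzyme_table",
    "write_enzyme_table",
    "read_product_table",
    "write_product_table",
    "read_inhibition_table",
    "write_inhibition_table",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_panel",
    "write_panel",
    "read_dataset",
    "write_dataset",
]

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class ParseError(ValueError):
    """Malformed table content; the message names the offending line."""


def _parse_bool(value: str, path: Path, line: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ParseError(f"{path}:{line}: cannot parse boolean {value!r}")


def _split_list(value: str) -> list[str]:
    return [tok.strip() for tok in str(value).split(",") if tok.strip()]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_enzyme_table(path: str | Path) -> list[EnzymeRecord]:
    """Parse the enzyme table; duplicate EC rows are merged.

    Merging unions organisms and categories and OR-combines the RLE flag;
    each merge event is logged.
    """
    path = Path(path)
    df = _read_tsv(path, ["ec", "organisms", "is_rle", "categories"])
    merged: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        ec = row["ec"].strip()
        if not is_valid_ec(ec):
            raise ParseError(f"{path}:{line}: malformed EC number {ec!r}")
        organisms = _split_list(row["organisms"])
        if not organisms:
            raise ParseError(f"{path}:{line}: empty organism list for {ec}")
        try:
            categories = {PathwayCategory.parse(c) for c in _split_list(row["categories"])}
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
        if not categories:
            raise ParseError(f"{path}:{line}: empty category list for {ec}")
        is_rle = _parse_bool(row["is_rle"], path, line)
        if ec in merged:
            logger.info("merging duplicate enzyme row for EC %s (line %d)", ec, line)
            merged[ec]["organisms"] |= set(organisms)
            merged[ec]["categories"] |= categories
            merged[ec]["is_rle"] = merged[ec]["is_rle"] or is_rle
        else:
            merged[ec] = {
                "organisms": set(organisms),
                "categories": categories,
                "is_rle": is_rle,
            }
    return [
        EnzymeRecord(
            ec=ec,
            organisms=frozenset(d["organisms"]),
            is_rle=d["is_rle"],
            categories=frozenset(d["categories"]),
        )
        for ec, d in merged.items()
    ]


def write_enzyme_table(records: list[EnzymeRecord], path: str | Path) -> None:
    rows = [
        {
            "ec": rec.ec,
            "organisms": ",".join(sorted(rec.organisms)),
            "is_rle": int(rec.is_rle),
            "categories": ",".join(sorted(c.value for c in rec.categories)),
        }
        for rec in sorted(records, key=lambda r: r.ec)
    ]
    pd.DataFrame(rows, columns=["ec", "organisms", "is_rle", "categories"]).to_csv(
        path, sep="\t", index=False
    )


def read_product_table(path: str | Path) -> list[ProductLink]:
    """Parse product links; exact-duplicate rows are dropped (logged count)."""
    path = Path(path)
    df = _read_tsv(path, ["organism", "ec", "compound"])
    seen: set[ProductLink] = set()
    out: list[ProductLink] = []
    dropped = 0
    for _, row in df.iterrows():
        link = ProductLink(
            organism=row["organism"].strip(),
            ec=row["ec"].strip(),
            compound=row["compound"].strip(),
        )
        if link in seen:
            dropped += 1
            continue
        seen.add(link)
        out.append(link)
    if dropped:
        logger.info("%s: dropped %d duplicate product rows", path, dropped)
    return out


def write_product_table(links: list[ProductLink], path: str | Path) -> None:
    rows = sorted(
        ({"organism": l.organism, "ec": l.ec, "compound": l.compound} for l in links),
        key=lambda r: (r["organism"], r["ec"], r["compound"]),
    )
    pd.DataFrame(rows, columns=["organism", "ec", "compound"]).to_csv(
        path, sep="\t", index=False
    )


def read_inhibition_table(path: str | Path) -> list[InhibitionLink]:
    """Parse inhibition links; exact-duplicate rows are dropped (logged count)."""
    path = Path(path)
    df = _read_tsv(path, ["organism", "compound", "target_ec", "in_vivo"])
    seen: set[InhibitionLink] = set()
    out: list[InhibitionLink] = []
    dropped = 0
    for idx, row in df.iterrows():
        link = InhibitionLink(
            organism=row["organism"].strip(),
            compound=row["compound"].strip(),
            target_ec=row["target_ec"].strip(),
            in_vivo=_parse_bool(row["in_vivo"], path, int(idx) + 2),
        )
        if link in seen:
            dropped += 1
            continue
        seen.add(link)
        out.append(link)
    if dropped:
        logger.info("%s: dropped %d duplicate inhibition rows", path, dropped)
    return out


def write_inhibition_table(links: list[InhibitionLink], path: str | Path) -> None:
    rows = sorted(
        (
            {
                "organism": l.organism,
                "compound": l.compound,
                "target_ec": l.target_ec,
                "in_vivo": int(l.in_vivo),
            }
            for l in links
        ),
        key=lambda r: (r["organism"], r["compound"], r["target_ec"], r["in_vivo"]),
    )
    pd.DataFrame(
        rows, columns=["organism", "compound", "target_ec", "in_vivo"]
    ).to_csv(path, sep="\t", index=False)


def read_presence_matrix(
    path: str | Path, panel: GenomePanel
) -> dict[str, np.ndarray]:
    """Parse the EC × genome 0/1 presence matrix against a fixed panel.

    Columns after the first must match the panel's genome order exactly.
    """
    path = Path(path)
    df = _read_tsv(path, ["ec"])
    cols = list(df.columns[1:])
    if tuple(cols) != panel.genomes:
        raise ValueError(
            f"{path}: presence columns do not match the genome panel "
            f"({len(cols)} columns vs panel size {panel.size})"
        )
    out: dict[str, np.ndarray] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        ec = row["ec"].strip()
        values = row.iloc[1:].to_numpy()
        bits = np.empty(panel.size, dtype=np.int8)
        for j, v in enumerate(values):
            v = str(v).strip()
            if v not in ("0", "1"):
                raise ParseError(
                    f"{path}:{line}: presence value {v!r} outside {{0,1}}"
                )
            bits[j] = int(v)
        out[ec] = bits
    return out


def write_presence_matrix(
    presence: dict[str, np.ndarray], panel: GenomePanel, path: str | Path
) -> None:
    rows = []
    for ec in sorted(presence):
        bits = np.asarray(presence[ec], dtype=int)
        if len(bits) != panel.size:
            raise ValueError(f"presence vector {ec}: wrong length {len(bits)}")
        rows.append([ec] + bits.tolist())
    pd.DataFrame(rows, columns=["ec"] + list(panel.genomes)).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path: str | Path) -> GenomePanel:
    df = _read_tsv(path, ["genome", "kingdom"])
    return GenomePanel(
        genomes=tuple(g.strip() for g in df["genome"]),
        kingdom=tuple(k.strip() for k in df["kingdom"]),
    )


def write_panel(panel: GenomePanel, path: str | Path) -> None:
    pd.DataFrame({"genome": panel.genomes, "kingdom": panel.kingdom}).to_csv(
        path, sep="\t", index=False
    )


# Canonical file names inside a dataset directory.
DATASET_FILES = {
    "enzymes": "enzymes.tsv",
    "products": "products.tsv",
    "inhibitions": "inhibitions.tsv",
    "presence": "presence.tsv",
    "panel": "panel.tsv",
}


def read_dataset(directory: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    panel_path = directory / DATASET_FILES["panel"]
    panel = read_panel(panel_path) if panel_path.exists() else GenomePanel.default()
    records = read_enzyme_table(directory / DATASET_FILES["enzymes"])
    presence_path = directory / DATASET_FILES["presence"]
    presence = (
        read_presence_matrix(presence_path, panel) if presence_path.exists() else {}
    )
    return Dataset(
        enzymes=EnzymeIndex(records),
        products=read_product_table(directory / DATASET_FILES["products"]),
        inhibitions=read_inhibition_table(directory / DATASET_FILES["inhibitions"]),
        presence=presence,
        panel=panel,
    )


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_enzyme_table(list(dataset.enzymes), directory / DATASET_FILES["enzymes"])
    write_product_table(dataset.products, directory / DATASET_FILES["products"])
    write_inhibition_table(
        dataset.inhibitions, directory / DATASET_FILES["inhibitions"]
    )
    write_presence_matrix(
        dataset.presence, dataset.panel, directory / DATASET_FILES["presence"]
    )
    write_panel(dataset.panel, directory / DATASET_FILES["panel"])
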