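"""Readers and writers for gene tables (TSV) and organism constants (JSON).

Gene tables are UTF-8, tab-separated, Unix newlines, with the header

    gene_id  essential  mrna_per_cell  protein_mean  protein_cv2

plus optional derived columns ``message_number``, ``transcription_rate_per_h``
and ``below_detection``.  Empty string means missing.  TSV rather than CSV
avoids locale decimal-separator ambiguity.

Organism constants are JSON with a ``schema_version`` field; times are in
hours by default, with explicit ``*_min`` key variants accepted for
minute-denominated sources.  Constants files for four reference conditions
(E. coli in rich and minimal media, budding yeast, human) ship with the
package and are loadable by name.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import OrganismConstants

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "BUNDLED_ORGANISMS",
    "read_gene_table",
    "write_gene_table",
    "load_organism",
    "organism_to_dict",
    "write_fit_json",
    "toy_gene_table_path",
]

SCHEMA_VERSION = 1

REQUIRED_COLUMNS = ["gene_id", "essential", "mrna_per_cell", "protein_mean", "protein_cv2"]
OPTIONAL_COLUMNS = ["message_number", "transcription_rate_per_h", "below_detection"]

BUNDLED_ORGANISMS = ("ecoli_lb", "ecoli_m9", "yeast", "human")

_MINUTE_KEYS = {"doubling_time_min": "doubling_time_h", "mrna_lifetime_min": "mrna_lifetime_h"}


def read_gene_table(path) -> pd.DataFrame:
    """Read and validate a gene table.

    Raises ``ValueError`` naming any missing required column, and listing
    the 1-based file line numbers of malformed rows (negative or non-finite
    numeric values, essential flags outside {0, 1}).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, na_values=[""],
                     keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")

    bad_lines: list[str] = []
    for column in df.columns:
        if column == "gene_id":
            continue
        parsed = pd.to_numeric(df[column], errors="coerce")
        raw_present = df[column].notna() if df[column].dtype == object else parsed.notna()
        unparsable = raw_present & parsed.isna()
        negative = parsed < 0
        bad = unparsable | negative
        if column == "essential":
            bad |= parsed.notna() & ~parsed.isin([0, 1])
            bad |= parsed.isna() & ~unparsable  # essential is mandatory per row
        for i in np.flatnonzero(bad.to_numpy()):
            bad_lines.append(f"line {i + 2}: bad value {df[column].iloc[i]!r} in {column}")
        df[column] = parsed
    if bad_lines:
        raise ValueError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_lines))
    df["essential"] = df["essential"].astype(int)
    return df


def write_gene_table(records: pd.DataFrame, path) -> None:
    """Write a gene table as TSV (missing values as empty strings).

    Column order is normalized (required, then known optional, then extras)
    so that identical records yield byte-identical files.
    """
    ordered = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in records.columns]
    extras = [c for c in records.columns if c not in ordered]
    records[ordered + extras].to_csv(
        path, sep="\t", index=False, na_rep="", lineterminator="\n", encoding="utf-8"
    )


def _constants_from_dict(data: dict, source: str) -> OrganismConstants:
    data = dict(data)
    for minute_key, hour_key in _MINUTE_KEYS.items():
        if minute_key in data:
            if hour_key in data:
                raise ValueError(f"{source}: both {minute_key} and {hour_key} present")
            data[hour_key] = data.pop(minute_key) / 60.0
    try:
        return OrganismConstants(
            name=data["name"],
            growth_condition=data.get("condition", ""),
            doubling_time_h=float(data["doubling_time_h"]),
            mrna_lifetime_h=float(data["mrna_lifetime_h"]),
            total_mrna_per_cell=float(data["total_mrna_per_cell"]),
            total_messages_per_cycle=float(data["total_messages_per_cycle"]),
            total_protein=float(data["total_protein"]),
        )
    except KeyError as exc:
        raise ValueError(f"{source}: missing key {exc.args[0]!r}") from None


def load_organism(name_or_path) -> OrganismConstants:
    """Load organism constants from a bundled name or a JSON file path.

    Bundled names: ``ecoli_lb``, ``ecoli_m9``, ``yeast``, ``human``.
    """
    name = str(name_or_path)
    if name in BUNDLED_ORGANISMS:
        text = resources.files("msgnoise.data").joinpath(f"{name}.json").read_text()
        return _constants_from_dict(json.loads(text), f"bundled:{name}")
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"{name!r} is neither a bundled organism {BUNDLED_ORGANISMS} nor a file"
        )
    return _constants_from_dict(json.loads(path.read_text()), str(path))


def organism_to_dict(org: OrganismConstants) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": org.name,
        "condition": org.growth_condition,
        "doubling_time_h": org.doubling_time_h,
        "mrna_lifetime_h": org.mrna_lifetime_h,
        "total_mrna_per_cell": org.total_mrna_per_cell,
        "total_messages_per_cycle": org.total_messages_per_cycle,
        "total_protein": org.total_protein,
    }


def write_fit_json(payload: dict, path) -> None:
    """Write an analysis result as JSON with a schema_version stamp."""
    body = {"schema_version": SCHEMA_VERSION}
    body.update(payload)
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=False) + "\n")


def toy_gene_table_path() -> Path:
    """Path to the small bundled example gene table."""
    with resources.as_file(resources.files("msgnoise.data").joinpath("toy_genes.tsv")) as p:
        return Path(p)
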