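"""TSV input/output and cross-validation of the three pipeline inputs.

Schemas match the generator's output: tab-separated, header row, '.' decimal,
"NA" for missing values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["LoadError", "read_stations", "read_catalog", "read_counts", "read_inputs"]

STATION_COLUMNS = [
    "station_id",
    "latitude",
    "longitude",
    "temperature",
    "salinity",
    "chla",
    "poc",
    "nitrate",
    "phosphate",
]
CATALOG_COLUMNS = ["gene_id", "length_bp"]


class LoadError(ValueError):
    """Raised when an input file violates the expected schema."""


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kwargs)


def read_stations(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    missing = [c for c in STATION_COLUMNS if c not in table.columns]
    if missing:
        raise LoadError(f"stations table missing columns: {missing}")
    if table["station_id"].duplicated().any():
        dupes = table.loc[table["station_id"].duplicated(), "station_id"].tolist()
        raise LoadError(f"duplicate id in stations: {dupes}")
    if table["temperature"].isna().any():
        raise LoadError("stations table has missing temperature")
    return table


def read_catalog(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    missing = [c for c in CATALOG_COLUMNS if c not in table.columns]
    if missing:
        raise LoadError(f"catalog missing columns: {missing}")
    for col in ("taxon_id", "ko_id", "cazy_family", "brite_category"):
        if col not in table.columns:
            table[col] = pd.NA
    if table["gene_id"].duplicated().any():
        raise LoadError("duplicate id in catalog gene_id")
    if (table["length_bp"] < 1).any():
        raise LoadError("catalog length_bp must be >= 1")
    return table


def read_counts(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise LoadError("duplicate id in counts station columns")
    table = _read_tsv(path, index_col=0)
    table.index.name = "gene_id"
    if table.index.duplicated().any():
        raise LoadError("duplicate id in counts gene_id")
    if pd.Index(table.columns).duplicated().any():
        raise LoadError("duplicate id in counts station columns")
    if table.isna().any().any() or (table < 0).any().any():
        raise LoadError("counts must be finite non-negative integers")
    return table.astype(int)


def read_inputs(
    stations_path: str | Path,
    catalog_path: str | Path,
    counts_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate the (stations, catalog, counts) triple."""
    stations = read_stations(stations_path)
    catalog = read_catalog(catalog_path)
    counts = read_counts(counts_path)
    unknown_genes = counts.index.difference(pd.Index(catalog["gene_id"]))
    if len(unknown_genes):
        raise LoadError(
            f"unknown gene in counts, absent from catalog: {list(unknown_genes[:5])}"
        )
    unknown_stations = pd.Index(counts.columns).difference(
        pd.Index(stations["station_id"])
    )
    if len(unknown_stations):
        raise LoadError(
            f"unknown station in counts: {list(unknown_stations[:5])}"
        )
    return stations, catalog, counts
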