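"""Occupancy-based thermal ranges of taxa and their per-KO gene variants.

A feature's temperature range is the spread of ambient temperatures over the
stations where its abundance reaches at least ``frac`` (default 15%) of its
maximum — an occupancy-threshold definition of realised thermal niche width.
Applied to taxon-aggregated profiles it measures the taxon's overall range;
applied to single gene variants (distinct catalog genes sharing one
(taxon, KO) pair) it measures sub-niche widths, with the pair only analysed
when it has at least ``min_variants`` detected variants.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["occupancy_range", "variant_ranges", "summarize_ranges"]

log = logging.getLogger(__name__)


def occupancy_range(
    abundance: np.ndarray, temperatures: np.ndarray, frac: float = 0.15
) -> tuple[float, float, float, int]:
    """(t_min, t_max, range, n_qualifying) of the occupancy thermal range.

    Qualifying stations have abundance >= frac * max(abundance); the range is
    max - min of their ambient temperatures. Invariant to rescaling the
    abundance vector by any positive constant.
    """
    ab = np.asarray(abundance, dtype=float)
    temps = np.asarray(temperatures, dtype=float)
    if ab.shape != temps.shape:
        raise ValueError("abundance and temperatures must be aligned")
    peak = ab.max()
    if peak <= 0:
        raise ValueError("undefined range: all-zero abundance")
    qualifying = temps[ab >= frac * peak]
    t_min, t_max = float(qualifying.min()), float(qualifying.max())
    return t_min, t_max, t_max - t_min, int(len(qualifying))


def variant_ranges(
    gene_profile,
    catalog: pd.DataFrame,
    stations: pd.DataFrame,
    frac: float = 0.15,
    min_variants: int = 10,
) -> pd.DataFrame:
    """Thermal-range table: one row per qualifying variant plus taxon rows.

    Variants are grouped by (taxon_id, ko_id); only pairs with at least
    ``min_variants`` variants with nonzero abundance are emitted (zero-
    abundance variants count toward neither the filter nor the output). Taxon
    rows are computed from the taxon-aggregated profile with the same
    occupancy fraction. Excluded pairs are counted in the run log.
    """
    from .profiles import aggregate

    data = gene_profile.data if hasattr(gene_profile, "data") else gene_profile
    temps = (
        stations.set_index("station_id")["temperature"]
        .loc[data.columns]
        .to_numpy(float)
    )
    ann = catalog.set_index("gene_id").loc[data.index, ["taxon_id", "ko_id"]]
    detected = data.sum(axis=1) > 0

    rows: list[dict] = []
    n_excluded = 0
    grouped = ann[ann["taxon_id"].notna() & ann["ko_id"].notna() & detected].groupby(
        ["taxon_id", "ko_id"]
    )
    for (taxon, ko), members in grouped:
        if len(members) < min_variants:
            n_excluded += 1
            continue
        for gid in members.index:
            t_min, t_max, rng, n_q = occupancy_range(
                data.loc[gid].to_numpy(), temps, frac
            )
            rows.append(
                {
                    "unit": "variant",
                    "taxon_id": taxon,
                    "ko_id": ko,
                    "gene_id": gid,
                    "t_min": t_min,
                    "t_max": t_max,
                    "range": rng,
                    "n_qualifying_stations": n_q,
                }
            )
    if n_excluded:
        log.info("excluded %d (taxon, KO) pairs below min_variants", n_excluded)

    taxon_profile = aggregate(gene_profile, catalog, "taxon")
    for taxon in taxon_profile.data.index:
        ab = taxon_profile.data.loc[taxon].to_numpy()
        if ab.max() <= 0:
            continue
        t_min, t_max, rng, n_q = occupancy_range(ab, temps, frac)
        rows.append(
            {
                "unit": "taxon",
                "taxon_id": taxon,
                "ko_id": None,
                "gene_id": None,
                "t_min": t_min,
                "t_max": t_max,
                "range": rng,
                "n_qualifying_stations": n_q,
            }
        )
    return pd.DataFrame(rows)


def summarize_ranges(
    table: pd.DataFrame,
    group_by: str = "taxon",
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Grouped descriptive statistics (mean, sd, median, IQR, n) of ranges.

    ``group_by="taxon"`` groups variant rows by source taxon;
    ``group_by="brite"`` maps variants through the catalog's BRITE category
    (unannotated variants are excluded, with a count in the run log).
    """
    variants = table[table["unit"] == "variant"].copy()
    if group_by == "taxon":
        key = variants["taxon_id"]
    elif group_by == "brite":
        if catalog is None:
            raise ValueError("group_by='brite' requires the catalog")
        brite = catalog.set_index("gene_id")["brite_category"]
        key = variants["gene_id"].map(brite)
        n_drop = int(key.isna().sum())
        if n_drop:
            log.info("excluded %d variants without BRITE annotation", n_drop)
        variants = variants[key.notna()]
        key = key.dropna()
    else:
        raise ValueError(f"unknown group_by: {group_by!r}")
    if variants.empty:
        warnings.warn("empty group set; returning empty summary", stacklevel=2)
        return pd.DataFrame(
            columns=["group", "mean", "sd", "median", "iqr", "n"]
        ).set_index("group")

    def _agg(sub: pd.Series) -> pd.Series:
        q75, q25 = np.percentile(sub, [75, 25])
        return pd.Series(
            {
                "mean": sub.mean(),
                "sd": sub.std(ddof=1) if len(sub) > 1 else 0.0,
                "median": sub.median(),
                "iqr": q75 - q25,
                "n": len(sub),
            }
        )

    out = variants.groupby(key.to_numpy())["range"].apply(_agg).unstack()
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    return out
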