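"""Abundance profiles: classification filter, RPK->CPM, level aggregation.

A *profile* is a features x stations matrix of counts-per-million (CPM)
abundances at one of three levels: gene (the catalog's non-redundant genes),
KO (functional orthologue), or taxon. Gene-level CPM corrects for gene length
(reads per kilobase, RPK) before per-station scaling to one million; KO and
taxon profiles are obtained by summing member-gene CPM values and re-scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Profile",
    "filter_classified",
    "rpk_cpm",
    "aggregate",
    "aggregate_counts",
    "build_profiles",
]

LEVELS = ("gene", "ko", "taxon")
_LEVEL_COLUMN = {"ko": "ko_id", "taxon": "taxon_id", "cazy": "cazy_family"}


@dataclass
class Profile:
    """A features x stations CPM abundance matrix at one level."""

    level: str
    data: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def stations(self) -> list[str]:
        return list(self.data.columns)


def filter_classified(counts: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Keep genes that are taxonomically AND functionally classified.

    Functional classification means either a KO or a CAZy family; this is the
    consistency filter applied before every comparative analysis.
    """
    cat = catalog.set_index("gene_id")
    keep = cat.loc[
        counts.index,
        ["taxon_id", "ko_id", "cazy_family"],
    ]
    mask = keep["taxon_id"].notna() & (
        keep["ko_id"].notna() | keep["cazy_family"].notna()
    )
    return counts.loc[mask.to_numpy()]


def rpk_cpm(counts: pd.DataFrame, catalog: pd.DataFrame) -> Profile:
    """Length-normalise counts to RPK, then scale each station to CPM.

    value(g, s) = RPK(g, s) / sum_g' RPK(g', s) * 1e6 with
    RPK(g, s) = count(g, s) / (length_bp(g) / 1000). Stations with no reads
    are emitted as all-zero columns with a warning.
    """
    lengths = catalog.set_index("gene_id")["length_bp"].loc[counts.index]
    if (lengths < 1).any():
        raise ValueError("every gene must have length_bp >= 1")
    rpk = counts.div(lengths / 1000.0, axis=0)
    totals = rpk.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"stations with zero counts emitted as all-zero columns: "
            f"{list(totals.index[zero])}",
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    cpm = rpk.div(totals, axis=1).fillna(0.0) * 1e6
    return Profile(level="gene", data=cpm)


def aggregate(profile: Profile, catalog: pd.DataFrame, level: str) -> Profile:
    """Sum member-gene CPM values into KO or taxon features and re-scale.

    Genes lacking the target annotation are excluded before summing; columns
    are then re-normalised to 1e6 so the result is again a CPM profile.
    """
    if profile.level != "gene":
        raise ValueError("aggregate expects a gene-level profile")
    if level not in ("ko", "taxon", "cazy"):
        raise ValueError(f"unknown level: {level!r}")
    ann = catalog.set_index("gene_id")[_LEVEL_COLUMN[level]].loc[profile.data.index]
    keep = ann.notna().to_numpy()
    summed = profile.data.loc[keep].groupby(ann[keep].to_numpy()).sum()
    totals = summed.sum(axis=0).replace(0, np.nan)
    rescaled = summed.div(totals, axis=1).fillna(0.0) * 1e6
    rescaled.index.name = _LEVEL_COLUMN[level]
    return Profile(level=level, data=rescaled)


def aggregate_counts(
    counts: pd.DataFrame, catalog: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum raw counts to KO / taxon / CAZy level (for count-based models)."""
    if level not in _LEVEL_COLUMN:
        raise ValueError(f"unknown level: {level!r}")
    ann = catalog.set_index("gene_id")[_LEVEL_COLUMN[level]].loc[counts.index]
    keep = ann.notna().to_numpy()
    return counts.loc[keep].groupby(ann[keep].to_numpy()).sum()


def build_profiles(
    counts: pd.DataFrame, catalog: pd.DataFrame
) -> dict[str, Profile]:
    """Classification filter + CPM + aggregation, for all three levels."""
    filtered = filter_classified(counts, catalog)
    gene = rpk_cpm(filtered, catalog)
    return {
        "gene": gene,
        "ko": aggregate(gene, catalog, "ko"),
        "taxon": aggregate(gene, catalog, "taxon"),
    }
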