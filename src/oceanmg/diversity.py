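"""Rarefaction-based richness and Shannon diversity per station.

Rarefaction draws a fixed number of reads *without replacement* from a
station's read multiset (multivariate hypergeometric), which is the standard
ecology semantics for comparing diversity across unequal sequencing effort.
Richness and Shannon entropy (natural log) are averaged over replicate draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rarefy", "diversity_metrics", "depth_correlation"]


def rarefy(
    counts_column: np.ndarray, depth: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Subsample one station's counts to ``depth`` reads without replacement."""
    col = np.asarray(counts_column, dtype=np.int64)
    total = int(col.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds column total {total}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multivariate_hypergeometric(col, depth, method="marginals")


def _shannon(col: np.ndarray) -> float:
    p = col[col > 0] / col.sum()
    return float(-(p * np.log(p)).sum())


def diversity_metrics(
    counts: pd.DataFrame,
    depth: int | str = "auto",
    n_reps: int = 99,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean rarefied richness and Shannon entropy per station.

    ``depth="auto"`` rarefies to the minimum station total so every station
    qualifies. Returns one row per station with columns
    ``richness_mean, shannon_mean, n_reps, depth``.
    """
    totals = counts.sum(axis=0)
    if depth == "auto":
        depth = int(totals.min())
    depth = int(depth)
    if depth > totals.min():
        raise ValueError(
            f"depth {depth} exceeds the smallest station total {int(totals.min())}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for station in counts.columns:
        col = counts[station].to_numpy(np.int64)
        rich = np.empty(n_reps)
        shan = np.empty(n_reps)
        for rep in range(n_reps):
            sub = rarefy(col, depth, rng)
            rich[rep] = int((sub > 0).sum())
            shan[rep] = _shannon(sub)
        rows.append(
            {
                "station_id": station,
                "richness_mean": rich.mean(),
                "shannon_mean": shan.mean(),
                "n_reps": n_reps,
                "depth": depth,
            }
        )
    return pd.DataFrame(rows).set_index("station_id")


def depth_correlation(
    div: pd.DataFrame, counts: pd.DataFrame
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of mean richness vs total mapped reads.

    A sanity check that rarefied richness is not an artifact of sequencing
    depth; a non-significant r is the desired outcome.
    """
    if len(div) < 3:
        raise ValueError("need >= 3 stations for a correlation")
    totals = counts.sum(axis=0).loc[div.index]
    richness = div["richness_mean"]
    if np.ptp(richness.to_numpy()) == 0 or np.ptp(totals.to_numpy()) == 0:
        raise ValueError("undefined correlation: constant vector")
    r, p = stats.pearsonr(richness, totals)
    return float(r), float(p)
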