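"""Differential abundance between station clusters (simplified NB Wald test).

A deliberately lean DESeq2-style procedure on raw counts aggregated to KO or
CAZy-family level: median-of-ratios size factors, per-feature method-of-
moments negative-binomial dispersion, a Wald test on the log2 fold change
between two groups with a delta-method standard error, and Benjamini-
Hochberg adjustment. There is no dispersion shrinkage, no fold-change
moderation and no outlier filtering; calibration is established by
simulation in the test suite rather than by agreement with any external
tool. Fold changes of significant features are binned 0-2 (no or weak
difference), 2-4 (intermediate) and >4 (strong).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cazy import bh_adjust

__all__ = [
    "size_factors",
    "nb_wald",
    "bin_lfc",
    "pairwise_cluster_enrichment",
]

PSEUDO = 0.5  # pseudo normalized count added to both means in the LFC
DISPERSION_FLOOR = 1e-8
BINS = ("none", "intermediate", "strong")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Geometric means are taken over features with no zero count; each
    sample's factor is the median ratio of its counts to those means.
    """
    arr = counts.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; filter or pseudo-count first"
        )
    ref = arr[positive]
    log_gm = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_gm[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald(
    counts: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test between two groups of samples.

    Returns a DataFrame with ``lfc`` (log2((m_B + 0.5)/(m_A + 0.5)) on
    normalized means, groups in sorted label order), ``se``, ``p_value``.
    The dispersion alpha solves var(q) = mean(q)/sf + alpha * mean(q)^2 by
    method of moments on normalized counts (pooled within-group variance),
    floored at 1e-8.
    """
    labels = pd.Series(np.asarray(group_labels), index=counts.columns)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("nb_wald requires exactly two groups")
    idx_a = labels[labels == groups[0]].index
    idx_b = labels[labels == groups[1]].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if factors is None:
        factors = size_factors(counts)
    q = counts.div(factors, axis=1)
    qa, qb = q[idx_a].to_numpy(float), q[idx_b].to_numpy(float)
    na, nb = qa.shape[1], qb.shape[1]
    m_a, m_b = qa.mean(axis=1), qb.mean(axis=1)

    # pooled within-group variance of normalized counts
    ss = ((qa - m_a[:, None]) ** 2).sum(axis=1) + ((qb - m_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / max(na + nb - 2, 1)
    m_bar = (na * m_a + nb * m_b) / (na + nb)
    inv_sf = float((1.0 / factors).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m_bar * inv_sf) / np.where(m_bar > 0, m_bar**2, 1.0)
    alpha = np.clip(np.nan_to_num(alpha), DISPERSION_FLOOR, None)

    inv_sf_a = float((1.0 / factors.loc[idx_a]).sum())
    inv_sf_b = float((1.0 / factors.loc[idx_b]).sum())
    var_ma = (m_a * inv_sf_a + alpha * m_a**2 * na) / na**2
    var_mb = (m_b * inv_sf_b + alpha * m_b**2 * nb) / nb**2

    # computed as a difference of logs so a label swap negates it exactly
    lfc = np.log2(m_b + PSEUDO) - np.log2(m_a + PSEUDO)
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_ma / ((m_a + PSEUDO) ** 2 * ln2sq) + var_mb / ((m_b + PSEUDO) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((m_a == 0) & (m_b == 0), 1.0, p)
    return pd.DataFrame(
        {"lfc": lfc, "se": se, "p_value": p},
        index=counts.index,
    )


def bin_lfc(lfc: np.ndarray, q_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Bin |log2 fold change|: none [0,2), intermediate [2,4), strong >=4.

    Non-significant features (q > alpha) always fall in "none".
    """
    lfc = np.abs(np.asarray(lfc, dtype=float))
    q = np.asarray(q_values, dtype=float)
    out = np.full(len(lfc), "none", dtype=object)
    sig = q <= alpha
    out[sig & (lfc >= 2) & (lfc < 4)] = "intermediate"
    out[sig & (lfc >= 4)] = "strong"
    return out


def pairwise_cluster_enrichment(
    counts: pd.DataFrame,
    cluster_labels: pd.Series,
    feature_sets: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
) -> tuple[dict[tuple, pd.DataFrame], pd.DataFrame]:
    """Differential abundance for every cluster pair, with per-set summaries.

    For each pair of clusters (each needing >= 2 stations) runs size factors,
    the NB Wald test and BH adjustment, bins the fold changes, and reports
    per feature set the proportion of member features in each bin x direction
    ("none" carries no direction; proportions per set sum to 1). Returns
    (per-pair result tables, tidy summary DataFrame). The summary also
    contains one "__all__" row per pair with the overall enriched fraction.
    """
    labels = cluster_labels.loc[counts.columns]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    if feature_sets is None:
        feature_sets = {}
    results: dict[tuple, pd.DataFrame] = {}
    summary_rows: list[dict] = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            sel = labels.isin([a, b])
            if (labels == a).sum() < 2 or (labels == b).sum() < 2:
                warnings.warn(
                    f"cluster pair ({a}, {b}) skipped: a group has < 2 stations",
                    stacklevel=2,
                )
                continue
            sub = counts.loc[:, sel.index[sel]]
            res = nb_wald(sub, labels[sel])
            res["q_value"] = bh_adjust(res["p_value"].to_numpy())
            res["bin"] = bin_lfc(res["lfc"].to_numpy(), res["q_value"].to_numpy(), alpha)
            res["direction"] = np.where(
                res["bin"] == "none",
                "",
                np.where(res["lfc"] > 0, f"up_in_{b}", f"up_in_{a}"),
            )
            results[(a, b)] = res
            sets = {"__all__": list(res.index), **feature_sets}
            for set_name, members in sets.items():
                members = [f for f in members if f in res.index]
                if not members:
                    warnings.warn(f"feature set {set_name!r} empty; skipped", stacklevel=2)
                    continue
                sub_res = res.loc[members]
                n = len(sub_res)
                combos = sub_res.groupby(["bin", "direction"]).size()
                for (bin_name, direction), cnt in combos.items():
                    summary_rows.append(
                        {
                            "cluster_a": a,
                            "cluster_b": b,
                            "set": set_name,
                            "bin": bin_name,
                            "direction": direction,
                            "proportion": cnt / n,
                            "n_features": n,
                        }
                    )
                summary_rows.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "set": set_name,
                        "bin": "enriched_total",
                        "direction": "",
                        "proportion": float((sub_res["bin"] != "none").mean()),
                        "n_features": n,
                    }
                )
    return results, pd.DataFrame(summary_rows)
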