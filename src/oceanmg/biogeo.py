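"""Biogeographic clustering of station profiles.

Bray-Curtis dissimilarities between station columns, Ward.D2 agglomeration
with the cluster number selected by the mean silhouette width, per-cluster
Kruskal-Wallis validation (within-cluster vs member-to-outgroup pairwise
dissimilarities), linear interpolation of missing environmental covariates
along the transect, Ward-on-Euclidean province definition, and a seeded
random-forest explanation of clusters from environmental variables.

Ward.D2 here means the Lance-Williams update applied to *unsquared* input
dissimilarities with the squaring inside the criterion, i.e. exactly what
``scipy.cluster.hierarchy.linkage(..., method="ward")`` computes on a
condensed dissimilarity vector (and what R's ``hclust(method="ward.D2")``
computes on the same input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterResult",
    "RFExplanation",
    "bray_curtis",
    "ward_cluster",
    "optimal_k",
    "validate_clusters",
    "interpolate_missing",
    "define_provinces",
    "explain_clusters_rf",
]

RF_COVARIATES = ("temperature", "salinity", "chla", "poc", "nitrate", "phosphate")
PROVINCE_VARIABLES = ("latitude", "longitude", "temperature", "salinity", "chla")


@dataclass
class ClusterResult:
    labels: pd.Series
    k: int
    mean_silhouette: float
    per_cluster_validation: dict[int, tuple[float, float]]
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


@dataclass
class RFExplanation:
    importances: pd.Series  # normalised to sum 1
    oob_score: float
    n_trees: int
    seed: int


def bray_curtis(profile) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between station columns.

    Stations whose column is entirely zero are excluded with a warning (their
    dissimilarity to anything is undefined).
    """
    data = profile.data if hasattr(profile, "data") else profile
    totals = data.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding all-zero stations from dissimilarities: "
            f"{list(totals.index[zero])}",
            stacklevel=2,
        )
        data = data.loc[:, ~zero]
    if data.shape[1] < 2:
        raise ValueError("need >= 2 stations with nonzero columns")
    mat = squareform(pdist(data.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(mat, index=data.columns, columns=data.columns)


def _check_square(dist: pd.DataFrame) -> np.ndarray:
    arr = dist.to_numpy(float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    return arr


def ward_linkage(dist: pd.DataFrame) -> np.ndarray:
    """Ward.D2 linkage matrix from a square dissimilarity DataFrame."""
    arr = _check_square(dist)
    return linkage(squareform(arr, checks=False), method="ward")


def ward_cluster(dist: pd.DataFrame, k: int) -> pd.Series:
    """Cut the Ward.D2 dendrogram into ``k`` clusters (labels 1..k)."""
    n = dist.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must lie in [2, {n - 1}]")
    labels = fcluster(ward_linkage(dist), t=k, criterion="maxclust")
    return pd.Series(labels, index=dist.index, name="cluster")


def _mean_silhouette(arr: np.ndarray, labels: np.ndarray) -> float:
    # sklearn follows the standard conventions: singleton clusters score 0.
    # Degenerate cuts (ties can prevent a dendrogram from splitting) score 0.
    if len(np.unique(labels)) < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = silhouette_score(arr, labels, metric="precomputed")
    return float(np.nan_to_num(score))


def optimal_k(
    dist: pd.DataFrame, k_min: int = 2, k_max: int | None = None
) -> ClusterResult:
    """Select k by maximising mean silhouette width over Ward.D2 cuts.

    Ties are broken toward the smallest k. The returned result also carries
    the per-cluster Kruskal-Wallis validation at the selected k.
    """
    n = dist.shape[0]
    if k_max is None:
        k_max = min(8, n - 1)
    if not k_min <= k_max <= n - 1:
        raise ValueError("require k_min <= k_max <= n - 1")
    arr = _check_square(dist)
    best_k, best_s = None, -np.inf
    by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = ward_cluster(dist, k)
        s = _mean_silhouette(arr, labels.to_numpy())
        by_k[k] = s
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    labels = ward_cluster(dist, best_k)
    validation = validate_clusters(dist, labels)
    return ClusterResult(
        labels=labels,
        k=best_k,
        mean_silhouette=best_s,
        per_cluster_validation=validation,
        silhouette_by_k=by_k,
    )


def validate_clusters(
    dist: pd.DataFrame, labels: pd.Series
) -> dict[int, tuple[float, float]]:
    """Kruskal-Wallis test per cluster: within vs member-to-outgroup distances.

    For each cluster the multiset of within-cluster pairwise dissimilarities
    is compared (rank test, tie-corrected H, chi-square p) against the
    dissimilarities from cluster members to all non-members. Clusters of size
    1 are skipped with a warning.
    """
    arr = _check_square(dist)
    labels = labels.loc[dist.index]
    out: dict[int, tuple[float, float]] = {}
    for cl in sorted(labels.unique()):
        members = np.flatnonzero((labels == cl).to_numpy())
        others = np.flatnonzero((labels != cl).to_numpy())
        if len(members) < 2:
            warnings.warn(f"cluster {cl} has a single member; skipped", stacklevel=2)
            continue
        within = arr[np.ix_(members, members)][
            np.triu_indices(len(members), k=1)
        ]
        between = arr[np.ix_(members, others)].ravel()
        if len(between) == 0:
            continue
        if np.ptp(np.concatenate([within, between])) == 0:
            out[int(cl)] = (0.0, 1.0)
            continue
        h, p = stats.kruskal(within, between)
        out[int(cl)] = (float(h), float(p))
    return out


def interpolate_missing(
    stations: pd.DataFrame,
    covariates: tuple[str, ...] = ("salinity", "chla", "poc", "nitrate", "phosphate"),
) -> pd.DataFrame:
    """Fill missing covariates by linear interpolation along the transect.

    Interpolation is against transect (row) order; leading/trailing gaps are
    filled with the nearest observed value. A covariate with no observed
    value at all raises.
    """
    out = stations.copy()
    for cov in covariates:
        if cov not in out.columns:
            continue
        col = out[cov]
        if col.isna().all():
            raise ValueError(f"covariate entirely missing: {cov}")
        filled = col.reset_index(drop=True).interpolate(
            method="linear", limit_direction="both"
        )
        out[cov] = filled.to_numpy()
    return out


def define_provinces(stations: pd.DataFrame, k: int) -> pd.Series:
    """Cluster stations into k provinces from position + hydrography.

    Latitude, longitude, temperature, salinity and chlorophyll a are z-score
    standardised; Euclidean distances are clustered with Ward's minimum
    variance criterion.
    """
    sub = stations[list(PROVINCE_VARIABLES)]
    if sub.isna().any().any():
        raise ValueError(
            "province variables contain missing values; run interpolate_missing first"
        )
    z = stats.zscore(sub.to_numpy(float), axis=0, ddof=0)
    dist = pd.DataFrame(
        squareform(pdist(z, metric="euclidean")),
        index=stations["station_id"],
        columns=stations["station_id"],
    )
    return ward_cluster(dist, k)


def explain_clusters_rf(
    stations: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    include_province: bool = True,
) -> RFExplanation:
    """Random-forest explanation of cluster membership from covariates.

    Fits a seeded classifier (impurity importances, out-of-bag accuracy)
    predicting cluster labels from temperature, salinity, chla, POC, nitrate,
    phosphate and (optionally) one-hot province. One-hot province importances
    are summed back into a single "province" entry; importances are
    normalised to sum 1.
    """
    labels = labels.loc[stations["station_id"]] if not labels.index.equals(
        pd.Index(stations["station_id"])
    ) else labels
    if labels.nunique() < 2:
        raise ValueError("need >= 2 clusters to explain")
    X = stations[list(RF_COVARIATES)].copy()
    if X.isna().any().any():
        raise ValueError("covariates contain missing values; interpolate first")
    feature_names = list(RF_COVARIATES)
    if include_province and "province" in stations.columns:
        onehot = pd.get_dummies(stations["province"], prefix="province")
        X = pd.concat([X.reset_index(drop=True), onehot.reset_index(drop=True)], axis=1)
        feature_names += list(onehot.columns)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=seed,
        bootstrap=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n OOB warnings
        rf.fit(X.to_numpy(), labels.to_numpy())
    imp = pd.Series(rf.feature_importances_, index=feature_names)
    prov_cols = [c for c in feature_names if c.startswith("province_")]
    if prov_cols:
        imp.loc["province"] = imp[prov_cols].sum()
        imp = imp.drop(prov_cols)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return RFExplanation(
        importances=imp, oob_score=float(rf.oob_score_), n_trees=n_trees, seed=seed
    )
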