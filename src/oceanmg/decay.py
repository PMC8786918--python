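"""Distance-decay regressions of community dissimilarity.

Ordinary least squares of pairwise Bray-Curtis dissimilarity on great-circle
distance (km) and on absolute temperature difference (degC), per profile
level. OLS on station pairs ignores the non-independence of pairs — that is
the standard descriptive distance-decay regression in biogeography; a Mantel
permutation p-value is available as a clearly-labelled optional extra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DecayFit",
    "haversine_km",
    "pairwise_predictors",
    "decay_fit",
    "fit_all",
    "mantel_p",
]


@dataclass
class DecayFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    predictor: str = ""
    level: str = ""


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def pairwise_predictors(
    stations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(great-circle km, |deltaT| degC) symmetric matrices between stations."""
    if len(stations) < 3:
        raise ValueError("need >= 3 stations")
    ids = stations["station_id"].tolist()
    n = len(ids)
    lat = stations["latitude"].to_numpy(float)
    lon = stations["longitude"].to_numpy(float)
    temp = stations["temperature"].to_numpy(float)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(lat[i], lon[i], lat[j], lon[j])
            dist[i, j] = dist[j, i] = d
    dtemp = np.abs(temp[:, None] - temp[None, :])
    return (
        pd.DataFrame(dist, index=ids, columns=ids),
        pd.DataFrame(dtemp, index=ids, columns=ids),
    )


def _upper(mat: pd.DataFrame, ids: list[str]) -> np.ndarray:
    arr = mat.loc[ids, ids].to_numpy(float)
    iu = np.triu_indices(len(ids), k=1)
    return arr[iu]


def decay_fit(
    dissim: pd.DataFrame, predictor: pd.DataFrame, label: str = ""
) -> DecayFit:
    """OLS of upper-triangle dissimilarities on upper-triangle predictors."""
    ids = [s for s in dissim.index if s in predictor.index]
    if len(ids) < 3:
        raise ValueError("matrices share fewer than 3 stations")
    y = _upper(dissim, ids)
    x = _upper(predictor, ids)
    if np.ptp(x) == 0:
        raise ValueError("undefined fit: constant predictor")
    res = stats.linregress(x, y)
    return DecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=len(y),
        predictor=label,
    )


def fit_all(
    dissims: dict[str, pd.DataFrame], stations: pd.DataFrame
) -> pd.DataFrame:
    """Decay fits for every level x predictor; one tidy row each.

    The distance slope is reported both per km and per 1000 km.
    """
    dist_km, dtemp = pairwise_predictors(stations)
    rows = []
    for level, dissim in dissims.items():
        for name, pred in (("distance_km", dist_km), ("delta_T", dtemp)):
            fit = decay_fit(dissim, pred, label=name)
            row = {
                "level": level,
                "predictor": name,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n_pairs": fit.n_pairs,
            }
            if name == "distance_km":
                row["slope_per_1000km"] = fit.slope * 1000.0
            rows.append(row)
    return pd.DataFrame(rows)


def mantel_p(
    dissim: pd.DataFrame,
    predictor: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """OPTIONAL extra: Mantel permutation test (r, p) between two matrices.

    Permutes station identities jointly over rows and columns; two-sided-free
    one-tailed p for positive association, as is conventional for
    distance-decay. Not part of the core regression output.
    """
    ids = list(dissim.index)
    y = _upper(dissim, ids)
    x = _upper(predictor, ids)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    arr = predictor.loc[ids, ids].to_numpy(float)
    iu = np.triu_indices(len(ids), k=1)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        xp = arr[np.ix_(perm, perm)][iu]
        if np.corrcoef(xp, y)[0, 1] >= r_obs:
            count += 1
    return r_obs, count / (n_perm + 1)
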