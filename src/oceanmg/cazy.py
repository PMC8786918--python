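"""Thermal response of CAZyme families: unimodal regression and clustering.

Family abundance profiles (0-1 normalised across stations) are fit with a
unimodal temperature response — a Gaussian a*exp(-(T-mu)^2/(2 sigma^2)) + c
by default — and tested against the intercept-only model with an F-test.
Benjamini-Hochberg-adjusted p-values gate significance; significant families
are clustered by complete linkage on Euclidean distances of their normalised
profiles, and each cluster's mean profile is refit to characterise the
cluster's thermal optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "UnimodalFit",
    "normalize01",
    "unimodal_fit",
    "bh_adjust",
    "cluster_thermal_profiles",
    "cazy_analysis",
]


@dataclass
class UnimodalFit:
    optimum: float
    r_squared: float
    p_value: float
    converged: bool
    q_value: float | None = None
    model: str = "gaussian"
    params: tuple = field(default_factory=tuple)
    boundary: bool = False  # optimum hit the observed temperature range edge


def normalize01(abundance: np.ndarray) -> np.ndarray:
    """Min-max scale a vector to [0, 1]; constant vectors are undefined."""
    x = np.asarray(abundance, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("undefined normalization: constant vector")
    return (x - lo) / (hi - lo)


def _gauss(t, a, mu, sigma, c):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) + c


def unimodal_fit(
    abundance01: np.ndarray, temperatures: np.ndarray, model: str = "gaussian"
) -> UnimodalFit:
    """Fit a unimodal temperature response to a 0-1 normalised profile.

    Gaussian model: least squares with grid-seeded starts (mu over the
    observed temperature range, sigma over {2, 5, 10} degC); the quadratic
    alternative fits a concave parabola by OLS. The p-value is an F-test of
    the fitted model against the intercept-only model. A fitted optimum
    outside the observed temperature range is clipped to it and flagged.
    """
    y = np.asarray(abundance01, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if len(y) < 6:
        raise ValueError("need >= 6 stations")
    if np.ptp(t) == 0:
        raise ValueError("temperatures must not be constant")
    ss0 = float(((y - y.mean()) ** 2).sum())
    t_lo, t_hi = float(t.min()), float(t.max())

    if model == "quadratic":
        X = np.column_stack([np.ones_like(t), t, t**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss1 = float((resid**2).sum())
        df_num, n_par = 2, 3
        if beta[2] < 0:
            opt = float(-beta[1] / (2.0 * beta[2]))
        else:  # convex fit: optimum at the better-fitting boundary
            opt = t_lo if X[:, 1][np.argmax(y)] < (t_lo + t_hi) / 2 else t_hi
        params: tuple = tuple(beta)
        converged = True
    elif model == "gaussian":
        best = None
        a0, c0 = float(y.max() - y.min()), float(y.min())
        for mu0 in np.linspace(t_lo, t_hi, 8):
            for s0 in (2.0, 5.0, 10.0):
                try:
                    popt, _ = optimize.curve_fit(
                        _gauss,
                        t,
                        y,
                        p0=(a0, mu0, s0, c0),
                        bounds=(
                            (-2.0, t_lo - 15.0, 0.1, -1.0),
                            (2.0, t_hi + 15.0, 60.0, 2.0),
                        ),
                        maxfev=2000,
                    )
                except (RuntimeError, ValueError):
                    continue
                ss = float(((y - _gauss(t, *popt)) ** 2).sum())
                if best is None or ss < best[0]:
                    best = (ss, popt)
        if best is None:
            return UnimodalFit(
                optimum=float((t_lo + t_hi) / 2),
                r_squared=0.0,
                p_value=1.0,
                converged=False,
                model=model,
            )
        ss1, popt = best
        params = tuple(popt)
        opt = float(popt[1]) if popt[0] >= 0 else (t_lo if popt[1] > (t_lo + t_hi) / 2 else t_hi)
        df_num, n_par = 3, 4
        converged = True
    else:
        raise ValueError(f"unknown model: {model!r}")

    boundary = not (t_lo <= opt <= t_hi)
    opt = float(np.clip(opt, t_lo, t_hi))
    n = len(y)
    df_den = n - n_par
    if ss0 <= 0 or df_den <= 0:
        p = 1.0
    else:
        f_stat = max(0.0, (ss0 - ss1) / df_num) / max(ss1 / df_den, 1e-300)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    r2 = 0.0 if ss0 <= 0 else max(0.0, 1.0 - ss1 / ss0)
    return UnimodalFit(
        optimum=opt,
        r_squared=r2,
        p_value=p,
        converged=converged,
        model=model,
        params=params,
        boundary=boundary,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank down enforces monotonicity
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cluster_thermal_profiles(
    profiles: pd.DataFrame,
    temperatures: np.ndarray,
    k: int = 3,
    model: str = "gaussian",
) -> tuple[pd.Series, pd.DataFrame, dict[int, UnimodalFit]]:
    """Complete-linkage clustering of significant family profiles.

    ``profiles`` holds 0-1 normalised family x station values. Returns the
    per-family labels (1..k), the per-cluster mean profiles, and a unimodal
    refit of each cluster mean.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(profiles) < k:
        raise ValueError(
            f"only {len(profiles)} significant families; choose k <= {len(profiles)}"
        )
    if k == 1:
        labels = pd.Series(1, index=profiles.index, name="cluster")
    else:
        z = linkage(pdist(profiles.to_numpy(), metric="euclidean"), method="complete")
        labels = pd.Series(
            fcluster(z, t=k, criterion="maxclust"), index=profiles.index, name="cluster"
        )
    means = profiles.groupby(labels).mean()
    fits = {
        int(cl): unimodal_fit(means.loc[cl].to_numpy(), temperatures, model=model)
        for cl in means.index
    }
    return labels, means, fits


def cazy_analysis(
    gene_profile,
    catalog: pd.DataFrame,
    stations: pd.DataFrame,
    alpha: float = 0.05,
    k: int = 3,
    model: str = "gaussian",
) -> tuple[pd.DataFrame, pd.Series | None, dict[int, UnimodalFit] | None]:
    """Family-level thermal-response analysis end to end.

    Aggregates the gene CPM profile to CAZy families, 0-1 normalises each
    family across stations, fits the unimodal response, BH-adjusts p-values
    and clusters the significant (q <= alpha) families. Returns the fit
    table, the cluster labels and the cluster-mean refits (the latter two are
    None when fewer than k families are significant).
    """
    from .profiles import aggregate

    fam_profile = aggregate(gene_profile, catalog, "cazy")
    temps = (
        stations.set_index("station_id")["temperature"]
        .loc[fam_profile.data.columns]
        .to_numpy(float)
    )
    rows = []
    normed: dict[str, np.ndarray] = {}
    for fam in fam_profile.data.index:
        ab = fam_profile.data.loc[fam].to_numpy()
        if np.ptp(ab) == 0:
            continue
        y = normalize01(ab)
        fit = unimodal_fit(y, temps, model=model)
        normed[fam] = y
        rows.append(
            {
                "family_id": fam,
                "optimum": fit.optimum,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "model": model,
            }
        )
    fits = pd.DataFrame(rows).set_index("family_id")
    fits["q_value"] = bh_adjust(fits["p_value"].to_numpy())
    significant = fits.index[fits["q_value"] <= alpha]
    if len(significant) < k:
        return fits, None, None
    sig_profiles = pd.DataFrame(
        {fam: normed[fam] for fam in significant}, index=fam_profile.data.columns
    ).T
    labels, _, cluster_fits = cluster_thermal_profiles(
        sig_profiles, temps, k=k, model=model
    )
    return fits, labels, cluster_fits
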