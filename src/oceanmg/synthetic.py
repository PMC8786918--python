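"""Synthetic ocean transect generator with planted thermal-niche structure.

The generator emulates the statistical shape of a near-surface ocean-basin
metagenomic survey: a latitudinal station transect with a smooth, unimodal
temperature gradient; taxa occupying Gaussian temperature niches organised
into a small number of thermal regimes (cold / temperate / warm); high
functional (KO) redundancy, because every KO is carried by taxa from every
regime; and, within each (taxon, KO) pair, several gene variants whose
temperature sub-niches are narrower than and nested inside the taxon niche.
Read counts are drawn multinomially per station at fixed depth, with the
sampling probability proportional to niche response x taxon baseline x gene
length (the length factor emulates read mapping, so that RPK normalisation
downstream is exercised non-trivially).

All planted parameters are returned as a :class:`NicheTruth` so tests can do
parameter recovery; the truth is never consumed by the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NicheTruth",
    "make_stations",
    "make_catalog",
    "simulate_counts",
    "expected_counts",
    "make_transect",
    "write_transect",
]

#: covariates that may carry missing values (mirrors the survey's metadata)
COVARIATES = ("salinity", "chla", "poc", "nitrate", "phosphate")

#: default number of missing entries per covariate (survey-style pattern)
DEFAULT_MISSING = {"chla": 1, "poc": 2, "nitrate": 4, "phosphate": 2}

#: latitude bands -> Longhurst-style province codes, south to north
_PROVINCE_EDGES = [-55.0, -45.0, -38.0, -15.0, 8.0, 20.0, 30.0, 42.0]
_PROVINCE_NAMES = [
    "APLR", "ANTA", "SANT", "SATL", "WTRA", "NATR", "NAST", "NADR", "NADR",
]

_BRITE_CATEGORIES = (
    "membrane_transport",
    "energy_metabolism",
    "carbohydrate_metabolism",
    "amino_acid_metabolism",
    "translation",
    "replication_repair",
    "peptidases",
    "signal_transduction",
)

_CAZY_CLASSES = ("GH", "GT", "CE", "CBM", "PL", "AA")


@dataclass
class NicheTruth:
    """Planted ground truth of the synthetic transect.

    taxa: one row per taxon: ``taxon_id, mu, sigma, baseline, regime,
        lat_center`` (regional latitude affinity center, degrees).
    variants: one row per gene: ``gene_id, taxon_id, ko_id, mu, sigma``
        (annotations here are always complete, even for genes whose catalog
        labels were blanked to emulate unclassified sequences).
    cazy_optima: planted thermal optimum (degC) per CAZy family.
    regime_centers: regime temperature centers (degC).
    cross_regime_affinity: relative abundance factor of a taxon outside its
        own thermal regime (partial, not total, regional turnover).
    lat_sigma: width (degrees latitude) of the taxon latitude affinity.
    sub_niche_ratio: sigma_variant / sigma_taxon (constant by construction).
    seed: generator seed for the catalog stage.
    """

    taxa: pd.DataFrame
    variants: pd.DataFrame
    cazy_optima: dict[str, float]
    regime_centers: tuple[float, ...]
    sub_niche_ratio: float
    seed: int
    cross_regime_affinity: float = 0.75
    lat_sigma: float = 80.0
    share_floor: float = 1e-6
    variant_lat_sigma: float = 30.0
    niche_packing: float = 0.0
    envelope_weight: float = 1.0

    def station_regimes(self, stations: pd.DataFrame) -> pd.Series:
        """Planted regime label per station: nearest regime center to the
        station's ambient temperature (the regime whose taxa dominate)."""
        temps = stations["temperature"].to_numpy(float)
        centers = np.asarray(self.regime_centers)
        labels = np.abs(temps[:, None] - centers[None, :]).argmin(axis=1)
        return pd.Series(labels, index=stations["station_id"], name="regime")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "taxa": self.taxa.to_dict(orient="list"),
            "variants": self.variants.to_dict(orient="list"),
            "cazy_optima": self.cazy_optima,
            "regime_centers": list(self.regime_centers),
            "sub_niche_ratio": self.sub_niche_ratio,
            "seed": self.seed,
            "cross_regime_affinity": self.cross_regime_affinity,
            "lat_sigma": self.lat_sigma,
            "share_floor": self.share_floor,
            "variant_lat_sigma": self.variant_lat_sigma,
            "niche_packing": self.niche_packing,
            "envelope_weight": self.envelope_weight,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NicheTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            taxa=pd.DataFrame(payload["taxa"]),
            variants=pd.DataFrame(payload["variants"]),
            cazy_optima=payload["cazy_optima"],
            regime_centers=tuple(payload["regime_centers"]),
            sub_niche_ratio=payload["sub_niche_ratio"],
            seed=payload["seed"],
            cross_regime_affinity=payload["cross_regime_affinity"],
            lat_sigma=payload["lat_sigma"],
            share_floor=payload["share_floor"],
            variant_lat_sigma=payload["variant_lat_sigma"],
            niche_packing=payload["niche_packing"],
            envelope_weight=payload["envelope_weight"],
        )


def transect_temperature(lat: np.ndarray) -> np.ndarray:
    """Noise-free transect temperature curve (degC) at latitude (degrees).

    Unimodal with asymmetric arms: polar water at the southern end, temperate
    drift water at the northern end.
    """
    lat = np.asarray(lat, dtype=float)
    width = np.where(lat < 2.0, 28.0, 42.0)
    return 1.0 + 27.0 * np.exp(-(((lat - 2.0) / width) ** 2))


def _province_of(lat: float) -> str:
    return _PROVINCE_NAMES[int(np.searchsorted(_PROVINCE_EDGES, lat))]


def make_stations(
    n_stations: int = 22,
    lat_range: tuple[float, float] = (-62.0, 47.0),
    seed: int = 0,
    missing: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build the station metadata table for a latitudinal transect.

    Latitudes are evenly spaced over ``lat_range``; temperature is a smooth
    unimodal function of latitude peaking near the equator and spanning
    roughly 1-28 degC. Chlorophyll a and POC rise towards temperate/high
    latitudes, annual-mean nitrate and phosphate are anti-correlated with
    temperature (with climatology-scale noise), and a configurable number of
    covariate entries are blanked to exercise interpolation downstream.
    """
    if n_stations < 4:
        raise ValueError("n_stations must be >= 4")
    rng = np.random.default_rng(seed)
    if missing is None:
        missing = DEFAULT_MISSING

    lat = np.linspace(lat_range[0], lat_range[1], n_stations)
    lon = -20.0 + 0.35 * lat + 8.0 * np.sin(lat / 15.0)
    temp = transect_temperature(lat)
    temp = np.clip(temp + rng.normal(0.0, 0.3, n_stations), 0.5, 29.5)

    abslat = np.abs(lat)
    chla = 0.05 + 0.85 / (1.0 + np.exp(-(abslat - 35.0) / 5.0))
    chla = np.clip(chla * rng.lognormal(0.0, 0.15, n_stations), 0.01, None)
    poc = 2.0 + 8.0 / (1.0 + np.exp(-(abslat - 35.0) / 5.0))
    poc = np.clip(poc * rng.lognormal(0.0, 0.15, n_stations), 0.1, None)
    # climatological annual means: anti-correlated with in-situ temperature
    # but with substantial decoupling noise (they are not same-day measures)
    nitrate = 0.05 + 0.92 * (28.0 - temp)
    nitrate = np.clip(nitrate * rng.lognormal(0.0, 0.3, n_stations), 0.01, None)
    phosphate = np.clip(
        nitrate / 15.0 * rng.lognormal(0.0, 0.2, n_stations), 0.005, None
    )
    salinity = 34.0 + 2.0 * np.exp(-(((abslat - 20.0) / 12.0) ** 2))
    salinity = salinity + rng.normal(0.0, 0.1, n_stations)

    table = pd.DataFrame(
        {
            "station_id": [f"S{i + 1:02d}" for i in range(n_stations)],
            "latitude": lat,
            "longitude": lon,
            "temperature": temp,
            "salinity": salinity,
            "chla": chla,
            "poc": poc,
            "nitrate": nitrate,
            "phosphate": phosphate,
            "province": [_province_of(x) for x in lat],
        }
    )
    for cov, n_miss in missing.items():
        n_miss = min(n_miss, n_stations - 2)
        if n_miss <= 0:
            continue
        idx = rng.choice(np.arange(1, n_stations - 1), size=n_miss, replace=False)
        table.loc[idx, cov] = np.nan
    return table


def make_catalog(
    n_taxa: int = 50,
    n_kos: int = 40,
    variants_per_pair: int = 8,
    cazy_fraction: float = 0.05,
    unclassified_fraction: float = 0.3,
    seed: int = 0,
    sub_niche_ratio: float = 0.3,
    ko_fraction: float = 0.35,
    regime_centers: tuple[float, ...] = (4.0, 14.5, 25.0),
    n_cazy_families: int = 18,
    cross_regime_affinity: float = 0.75,
    lat_sigma: float = 80.0,
    lat_range: tuple[float, float] = (-62.0, 47.0),
    floor_range: tuple[float, float] = (0.35, 0.9),
    sigma_range: tuple[float, float] = (3.0, 13.0),
    variant_spread: float = 2.0,
    share_floor: float = 1e-6,
    variant_lat_sigma: float = 30.0,
    variant_floor_range: tuple[float, float] = (0.01, 0.05),
    niche_packing: float = 0.0,
    envelope_weight: float = 1.0,
) -> tuple[pd.DataFrame, NicheTruth]:
    """Build the gene catalog and its planted niche truth.

    Taxa are split round-robin across thermal regimes; each taxon draws a
    broad Gaussian temperature niche (center near its regime center, width
    sigma ~ U(4, 9) degC), a lognormal baseline abundance, and a regional
    latitude affinity center (broad, width ``lat_sigma``). Outside its own
    regime a taxon is damped to ``cross_regime_affinity`` of its in-regime
    abundance — partial, not total, regional turnover, as real provinces
    show. Each KO is carried by ``ko_fraction`` of the taxa, stratified so
    that every regime contributes at least two carriers (this is what plants
    KO redundancy across the whole gradient). Every (taxon, KO) pair gets
    ``variants_per_pair`` gene variants with sub-niche centers spread inside
    the taxon niche and widths equal to ``sub_niche_ratio`` x the taxon
    width. A ``cazy_fraction`` of genes is assigned a CAZy family with its
    own planted thermal optimum, and an ``unclassified_fraction`` of genes
    loses taxon and/or KO labels in the catalog (the truth keeps them).
    """
    if variants_per_pair < 1:
        raise ValueError("variants_per_pair must be >= 1")
    for name, frac in (
        ("cazy_fraction", cazy_fraction),
        ("unclassified_fraction", unclassified_fraction),
    ):
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_regimes = len(regime_centers)

    taxon_ids = [f"T{i + 1:03d}" for i in range(n_taxa)]
    regime = np.arange(n_taxa) % n_regimes
    mu_taxon = np.array([regime_centers[r] for r in regime]) + rng.normal(
        0.0, 1.8, n_taxa
    )
    sigma_taxon = rng.uniform(sigma_range[0], sigma_range[1], n_taxa)
    # generalists dominate: baseline abundance scales with niche breadth
    # (the broadest clades are also the most abundant in surface oceans)
    baseline = rng.lognormal(0.0, 0.5, n_taxa) * np.sqrt(
        sigma_taxon / np.mean(sigma_range)
    )
    lat_center = rng.uniform(lat_range[0], lat_range[1], n_taxa)
    # generalist floor: fraction of peak response a variant keeps everywhere
    # (cosmopolitan background presence; a few taxa are strongly cosmopolitan)
    niche_floor = rng.uniform(floor_range[0], floor_range[1], n_taxa)
    taxa = pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "mu": mu_taxon,
            "sigma": sigma_taxon,
            "baseline": baseline,
            "regime": regime,
            "lat_center": lat_center,
            "niche_floor": niche_floor,
        }
    )

    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    brite_of_ko = {
        ko: _BRITE_CATEGORIES[i % len(_BRITE_CATEGORIES)]
        for i, ko in enumerate(ko_ids)
    }

    # stratified KO -> taxa assignment: carriers from every regime
    per_regime_idx = [np.flatnonzero(regime == r) for r in range(n_regimes)]
    rows: list[dict] = []
    truth_rows: list[dict] = []
    gene_counter = 0
    for ko in ko_ids:
        carriers: list[int] = []
        for r in range(n_regimes):
            pool = per_regime_idx[r]
            n_pick = max(2, int(round(ko_fraction * len(pool))))
            n_pick = min(n_pick, len(pool))
            carriers.extend(rng.choice(pool, size=n_pick, replace=False))
        for t in carriers:
            mu_t, sig_t = mu_taxon[t], sigma_taxon[t]
            sig_v = sub_niche_ratio * sig_t
            # variant centers: evenly spread over the core niche plus jitter,
            # clipped to stay within +-2 sigma of the taxon center
            # variant optima spread evenly over the taxon niche core
            # intersected with the sampled thermal domain (observable
            # ecotypes have optima where the transect can see them)
            lo = max(mu_t - variant_spread * sig_t, 0.5)
            hi = min(mu_t + variant_spread * sig_t, 28.5)
            centers = np.linspace(lo, hi, variants_per_pair) + rng.normal(
                0.0, 0.05 * (hi - lo), variants_per_pair
            )
            centers = np.clip(centers, mu_t - 2.0 * sig_t, mu_t + 2.0 * sig_t)
            lat_centers = _ecotype_latitudes(
                centers, lat_range, rng, jitter=8.0
            )
            v_floors = rng.uniform(
                variant_floor_range[0], variant_floor_range[1], variants_per_pair
            )
            for mu_v, lam_v, fl_v in zip(
                centers, lat_centers, v_floors, strict=True
            ):
                gene_counter += 1
                gid = f"G{gene_counter:06d}"
                rows.append(
                    {
                        "gene_id": gid,
                        "length_bp": int(rng.integers(210, 4501)),
                        "taxon_id": taxon_ids[t],
                        "ko_id": ko,
                        "cazy_family": None,
                        "brite_category": brite_of_ko[ko],
                    }
                )
                truth_rows.append(
                    {
                        "gene_id": gid,
                        "taxon_id": taxon_ids[t],
                        "ko_id": ko,
                        "mu": float(mu_v),
                        "sigma": float(sig_v),
                        "lat_center": float(lam_v),
                        "floor": float(fl_v),
                    }
                )

    catalog = pd.DataFrame(rows)
    variants = pd.DataFrame(truth_rows)
    n_genes = len(catalog)

    # CAZy families with planted optima on a cold/mid/warm grid; genes join
    # the family whose optimum is closest to their variant center (softly)
    fam_names = []
    fam_optima = []
    optima_grid = (3.0, 15.0, 25.0)
    for i in range(n_cazy_families):
        cls = _CAZY_CLASSES[i % len(_CAZY_CLASSES)]
        fam_names.append(f"{cls}{i + 1}")
        fam_optima.append(optima_grid[i % len(optima_grid)])
    fam_optima_arr = np.array(fam_optima)
    cazy_optima = dict(zip(fam_names, fam_optima, strict=True))

    n_cazy = int(round(cazy_fraction * n_genes))
    if n_cazy:
        cazy_idx = rng.choice(n_genes, size=n_cazy, replace=False)
        mu_v = variants["mu"].to_numpy()
        for gi in cazy_idx:
            w = np.exp(-((mu_v[gi] - fam_optima_arr) ** 2) / (2.0 * 2.0**2))
            w /= w.sum()
            catalog.iat[gi, catalog.columns.get_loc("cazy_family")] = rng.choice(
                fam_names, p=w
            )

    # blank annotations on a fraction of genes (catalog only, truth intact)
    n_unclass = int(round(unclassified_fraction * n_genes))
    if n_unclass:
        drop_idx = rng.choice(n_genes, size=n_unclass, replace=False)
        modes = rng.choice(["taxon", "ko", "both"], size=n_unclass, p=[0.4, 0.4, 0.2])
        for gi, mode in zip(drop_idx, modes, strict=True):
            if mode in ("taxon", "both"):
                catalog.iat[gi, catalog.columns.get_loc("taxon_id")] = None
            if mode in ("ko", "both"):
                catalog.iat[gi, catalog.columns.get_loc("ko_id")] = None
                catalog.iat[gi, catalog.columns.get_loc("brite_category")] = None

    truth = NicheTruth(
        taxa=taxa,
        variants=variants,
        cazy_optima=cazy_optima,
        regime_centers=tuple(regime_centers),
        sub_niche_ratio=sub_niche_ratio,
        seed=seed,
        cross_regime_affinity=cross_regime_affinity,
        lat_sigma=lat_sigma,
        share_floor=share_floor,
        variant_lat_sigma=variant_lat_sigma,
        niche_packing=niche_packing,
        envelope_weight=envelope_weight,
    )
    return catalog, truth


def _ecotype_latitudes(
    mu_v: np.ndarray,
    lat_range: tuple[float, float],
    rng: np.random.Generator,
    jitter: float = 8.0,
) -> np.ndarray:
    """Latitude preference per variant: a point on the transect where the
    ambient temperature matches the variant's thermal optimum, with the
    hemisphere branch chosen at random (ecotypes evolve in situ; either
    branch of the thermal mirror is equally likely)."""
    south = np.linspace(lat_range[0], 2.0, 200)
    north = np.linspace(2.0, lat_range[1], 200)
    t_south, t_north = transect_temperature(south), transect_temperature(north)
    out = np.empty(len(mu_v))
    for i, mu in enumerate(np.asarray(mu_v, dtype=float)):
        cand = [south[np.abs(t_south - mu).argmin()]]
        # the northern arm only reaches temperate temperatures
        if mu <= t_north.max() and mu >= t_north.min():
            cand.append(north[np.abs(t_north - mu).argmin()])
        lam = cand[int(rng.integers(len(cand)))]
        out[i] = np.clip(lam + rng.normal(0.0, jitter), lat_range[0], lat_range[1])
    return out


def _expected_weights(
    catalog: pd.DataFrame, truth: NicheTruth, stations: pd.DataFrame
) -> np.ndarray:
    """Unnormalised expected read weight, genes x stations.

    baseline(taxon) x regime affinity x latitude affinity
    x Gaussian(T; mu_v, sigma_v) x length_bp.
    """
    cat_genes = catalog["gene_id"].to_numpy()
    var = truth.variants.set_index("gene_id").loc[cat_genes]
    taxa = truth.taxa.set_index("taxon_id")
    baseline = taxa["baseline"].loc[var["taxon_id"]].to_numpy()
    taxon_regime = taxa["regime"].loc[var["taxon_id"]].to_numpy()
    lat_center = taxa["lat_center"].loc[var["taxon_id"]].to_numpy()
    mu = var["mu"].to_numpy()[:, None]
    sigma = var["sigma"].to_numpy()[:, None]
    temps = stations["temperature"].to_numpy(float)[None, :]
    lats = stations["latitude"].to_numpy(float)[None, :]
    length = catalog["length_bp"].to_numpy(float)[:, None]
    station_regime = truth.station_regimes(stations).to_numpy()[None, :]
    floor = taxa["niche_floor"].loc[var["taxon_id"]].to_numpy()
    sigma_t = taxa["sigma"].loc[var["taxon_id"]].to_numpy()
    mu_t = taxa["mu"].loc[var["taxon_id"]].to_numpy()
    affinity = np.where(
        taxon_regime[:, None] == station_regime, 1.0, truth.cross_regime_affinity
    )
    lat_aff = np.exp(
        -((lats - lat_center[:, None]) ** 2) / (2.0 * truth.lat_sigma**2)
    )
    # taxon envelope: optionally a broad Gaussian plus cosmopolitan floor.
    # With envelope_weight 0 (default) the taxon's thermal profile is carried
    # entirely by its variant coverage (evenly spaced equal-height Gaussians
    # sum to a flat-topped hump), avoiding double-counting taxon structure.
    w_env = truth.envelope_weight
    envelope = (1.0 - w_env) + w_env * (
        np.exp(-((temps - mu_t[:, None]) ** 2) / (2.0 * sigma_t[:, None] ** 2))
        + floor[:, None]
    )
    # variant response: narrow temperature sub-niche times a regional
    # (latitude) ecotype preference, plus a small per-variant cosmopolitan
    # floor -> the variant's realised curve is a compact Gaussian of width
    # sigma_v, while the heterogeneous floors keep some of every variant
    # everywhere (and keep shifting the far-field composition with region)
    lat_v = var["lat_center"].to_numpy()[:, None]
    v_floor = var["floor"].to_numpy()[:, None]
    resp = (
        np.exp(-((temps - mu) ** 2) / (2.0 * sigma**2))
        * np.exp(-((lats - lat_v) ** 2) / (2.0 * truth.variant_lat_sigma**2))
        + v_floor
    )
    # within-taxon density dependence: competition among a taxon's variants
    # partially compensates the taxon total (exponent gamma), so the taxon
    # envelope, not variant coverage, dominates taxon-level turnover, while
    # each variant's local response width is untouched
    gamma = truth.niche_packing
    if gamma > 0:
        taxon_codes = pd.factorize(var["taxon_id"].to_numpy())[0]
        tot = np.zeros((taxon_codes.max() + 1, resp.shape[1]))
        np.add.at(tot, taxon_codes, resp)
        resp = resp / tot[taxon_codes] ** gamma
    return baseline[:, None] * affinity * lat_aff * envelope * resp * length


def expected_counts(
    catalog: pd.DataFrame,
    truth: NicheTruth,
    stations: pd.DataFrame,
    reads_per_station: int,
) -> pd.DataFrame:
    """Noise-free expected count matrix under the sampling model (the
    per-station multinomial mean). Used as an oracle in parameter-recovery
    tests; not part of the analysis path."""
    w = _expected_weights(catalog, truth, stations)
    p = w / w.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        reads_per_station * p,
        index=pd.Index(catalog["gene_id"], name="gene_id"),
        columns=stations["station_id"].tolist(),
    )


def simulate_counts(
    catalog: pd.DataFrame,
    truth: NicheTruth,
    stations: pd.DataFrame,
    reads_per_station: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the genes x stations read-count matrix.

    Per station the gene counts are multinomial with total
    ``reads_per_station`` and probabilities proportional to
    baseline(taxon) x Gaussian niche response x gene length.
    """
    if reads_per_station < 10_000:
        raise ValueError("reads_per_station must be >= 10000")
    if set(catalog["gene_id"]) != set(truth.variants["gene_id"]):
        raise ValueError("catalog and truth describe different gene sets")
    rng = np.random.default_rng(seed)
    w = _expected_weights(catalog, truth, stations)
    p = w / w.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(reads_per_station, p[:, s]) for s in range(p.shape[1])]
    )
    return pd.DataFrame(
        counts,
        index=pd.Index(catalog["gene_id"], name="gene_id"),
        columns=stations["station_id"].tolist(),
    )


def make_transect(
    seed: int = 0,
    n_stations: int = 22,
    lat_range: tuple[float, float] = (-62.0, 47.0),
    n_taxa: int = 50,
    n_kos: int = 40,
    variants_per_pair: int = 8,
    reads_per_station: int = 200_000,
    cazy_fraction: float = 0.05,
    unclassified_fraction: float = 0.3,
    **catalog_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, NicheTruth]:
    """One-call default transect: (stations, catalog, counts, truth).

    Sub-seeds for the three stages are derived from ``seed`` so that a single
    integer reproduces the whole data set bit-for-bit.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    stations = make_stations(n_stations, lat_range, seed=seeds[0])
    catalog, truth = make_catalog(
        n_taxa=n_taxa,
        n_kos=n_kos,
        variants_per_pair=variants_per_pair,
        cazy_fraction=cazy_fraction,
        unclassified_fraction=unclassified_fraction,
        seed=seeds[1],
        **catalog_kwargs,
    )
    counts = simulate_counts(
        catalog, truth, stations, reads_per_station=reads_per_station, seed=seeds[2]
    )
    return stations, catalog, counts, truth


def write_transect(
    outdir: str | Path,
    stations: pd.DataFrame,
    catalog: pd.DataFrame,
    counts: pd.DataFrame,
    truth: NicheTruth | None = None,
) -> None:
    """Write stations.tsv / catalog.tsv / counts.tsv (+ truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stations.to_csv(outdir / "stations.tsv", sep="\t", index=False, na_rep="NA")
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False, na_rep="NA")
    counts.to_csv(outdir / "counts.tsv", sep="\t", na_rep="NA")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
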