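"""Seeded generator of a synthetic Austria-scale country fixture.

The real report generator runs on restricted national data sources, so the
package ships a generator that emulates the country's *structure* at full
scale: by default 2122 municipalities partitioned into 116 districts, a
connected sparse road network with travel times in minutes, log-normally
distributed municipal populations, facilities placed with probability
increasing in population, and indicator raw values drawn from a spatially
autocorrelated Gaussian field so that nearby municipalities resemble each
other.  Every downstream stage (catchments, aggregation, profiles, reports)
is exercised on this fixture.

What the fixture emulates and what it does not: scale, sparsity, spatial
autocorrelation and plausible value ranges are reproduced; real Austrian
geography, municipality names and calibrated indicator distributions are
not.  Values are fictive by construction.

Randomness: one root seed is split into named child streams (coordinates,
clustering, populations, network noise, facilities, fields, equivalents) so
that the generation steps are reproducible independently of each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial import cKDTree, distance_matrix
from sklearn.cluster import KMeans

from .catalogue import Catalogue, load_catalogue
from .geography import build_network

# Age-band fractions: children (<15), working age (15-64), 65-74, 75+.
DEFAULT_AGE_FRACTIONS = (0.145, 0.655, 0.105, 0.095)

#: (mean, sd, lower clip, upper clip) of each latent indicator raw field on
#: its natural scale.  Chosen as plausible central European magnitudes; the
#: fixture is fictive and not calibrated to any real distribution.
DEFAULT_FIELD_SPECS: dict[str, tuple[float, float, float, float]] = {
    "pct_65_single_household": (30.0, 6.0, 0.0, 100.0),
    "avg_income": (24000.0, 3500.0, 8000.0, math.inf),
    "pct_bad_health": (8.0, 2.0, 0.0, 100.0),
    "pct_smokers": (21.0, 3.0, 0.0, 100.0),
    "pct_low_exercise": (50.0, 7.0, 0.0, 100.0),
    "pct_obesity": (17.0, 3.0, 0.0, 100.0),
    "life_expectancy_men": (79.5, 1.2, 65.0, 95.0),
    "life_expectancy_women": (84.0, 1.0, 65.0, 95.0),
    "prev_diabetes_t2": (5.0, 1.2, 0.0, 100.0),
    "prev_mental_disorders": (6.0, 1.5, 0.0, 100.0),
    "prev_musculoskeletal": (25.0, 4.0, 0.0, 100.0),
    "prev_chronic_pain": (25.0, 4.0, 0.0, 100.0),
    "pct_ltc_level_1_3": (3.5, 0.8, 0.0, 100.0),
    "pct_ltc_level_4_7": (2.0, 0.5, 0.0, 100.0),
    "rate_inpatients_heart": (25.0, 5.0, 0.0, math.inf),
    "rate_inpatients_femoral_fracture": (12.0, 3.0, 0.0, math.inf),
    "rate_inpatients_cerebrovascular": (15.0, 4.0, 0.0, math.inf),
    "rate_inpatients_cancer": (30.0, 5.0, 0.0, math.inf),
    "pct_shi_gp_55_plus": (45.0, 10.0, 0.0, 100.0),
    "pct_visiting_shi_gp": (80.0, 6.0, 0.0, 100.0),
}

#: Fields only available above municipality level in the original system
#: (mostly health-survey items): generated at district level and copied to
#: member municipalities, emulating the "interpolated from higher regional
#: levels" limitation and its blurring of local outputs.
SUPRA_MUNICIPAL_FIELDS = (
    "pct_bad_health",
    "pct_smokers",
    "pct_low_exercise",
    "pct_obesity",
    "prev_diabetes_t2",
    "prev_mental_disorders",
    "prev_musculoskeletal",
    "prev_chronic_pain",
)

#: Mean facility count per inhabitant (Poisson intensity = population x rate);
#: hospitals are rarer and placed at most once per municipality.
DEFAULT_FACILITY_RATES: dict[str, float] = {
    "general_practice": 1 / 1800,
    "private_gp": 1 / 4000,
    "paediatrics": 1 / 16000,
    "internal_medicine": 1 / 12000,
    "pharmacy": 1 / 6000,
    "nursing_home": 1 / 10000,
}

FACILITY_COUNT_FIELDS = {
    "general_practice": "n_gp",
    "private_gp": "n_private_gp",
    "paediatrics": "n_paediatrician",
    "internal_medicine": "n_internist",
    "pharmacy": "n_pharmacies",
    "nursing_home": "n_nursing_home",
}

FIXTURE_FILES = (
    "municipalities.csv",
    "municipalities.geojson",
    "districts.csv",
    "edges.csv",
    "facilities.csv",
    "raw_values.csv",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable settings of the synthetic country.

    ``area_per_municipality_km2`` keeps the spatial density constant when the
    country is scaled down (40 km2 per municipality reproduces an
    Austria-sized country at 2122 municipalities).  ``corr_range_km`` is the
    e-folding range of the exponential spatial correlation of indicator
    fields.  Travel time on an edge is Euclidean distance at ``speed_kmh``
    with multiplicative log-normal noise of ``edge_noise_sigma``.
    """

    area_per_municipality_km2: float = 40.0
    aspect_ratio: float = 2.4
    knn_k: int = 4
    speed_kmh: float = 60.0
    edge_noise_sigma: float = 0.15
    median_population: float = 2000.0
    population_sigma: float = 1.0
    min_population: int = 50
    age_fractions: tuple[float, float, float, float] = DEFAULT_AGE_FRACTIONS
    age_concentration: float = 120.0
    corr_range_km: float = 50.0
    hospital_scale_pop: float = 40000.0
    facility_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FACILITY_RATES))
    field_specs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_SPECS)
    )
    # expected upper bound on max/min district population on default settings
    district_balance_factor: float = 60.0


@dataclass(frozen=True)
class CountryFixture:
    """A complete synthetic country: tables plus the travel network."""

    municipalities: pd.DataFrame
    districts: pd.DataFrame
    network: nx.Graph
    facilities: pd.DataFrame
    raw_values: pd.DataFrame
    seed: int | None = None

    @property
    def municipality_ids(self) -> list[str]:
        return list(self.municipalities["municipality_id"])

    @property
    def district_ids(self) -> list[str]:
        return list(self.districts["district_id"])

    def district_members(self) -> dict[str, list[str]]:
        """District id -> member municipality ids."""
        out: dict[str, list[str]] = {d: [] for d in self.district_ids}
        for mid, did in self.municipalities[["municipality_id", "district_id"]].itertuples(index=False):
            out[did].append(mid)
        return out

    def equals(self, other: "CountryFixture") -> bool:
        return (
            self.municipalities.equals(other.municipalities)
            and self.districts.equals(other.districts)
            and self.facilities.equals(other.facilities)
            and self.raw_values.equals(other.raw_values)
            and sorted(self.network.nodes) == sorted(other.network.nodes)
            and sorted(
                (min(u, v), max(u, v), d["minutes"]) for u, v, d in self.network.edges(data=True)
            )
            == sorted(
                (min(u, v), max(u, v), d["minutes"]) for u, v, d in other.network.edges(data=True)
            )
        )


def _municipality_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"M{i:0{width}d}" for i in range(1, n + 1)]


def _district_ids(n: int) -> list[str]:
    return [f"D{i:03d}" for i in range(1, n + 1)]


def _assign_districts(coords_m: np.ndarray, n_districts: int, seed: int) -> np.ndarray:
    """Partition municipalities into contiguous districts by planar k-means.

    Returns an integer district index per municipality; cluster indices are
    relabelled by centroid position (west to east) so ids are stable."""
    km = KMeans(n_clusters=n_districts, n_init=1, random_state=seed)
    labels = km.fit_predict(coords_m)
    order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
    relabel = np.empty(n_districts, dtype=int)
    relabel[order] = np.arange(n_districts)
    return relabel[labels]


def _knn_edges(coords_m: np.ndarray, k: int) -> list[tuple[int, int, float]]:
    tree = cKDTree(coords_m)
    k_eff = min(k + 1, len(coords_m))
    dists, idx = tree.query(coords_m, k=k_eff)
    edges: dict[tuple[int, int], float] = {}
    for i in range(len(coords_m)):
        for j_pos in range(1, k_eff):
            j = int(idx[i, j_pos])
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            edges.setdefault(key, float(dists[i, j_pos]))
    return sorted((u, v, d) for (u, v), d in edges.items())


def _connect_components(
    g: nx.Graph, coords_m: np.ndarray, ids: list[str]
) -> list[tuple[int, int, float]]:
    """Extra edges joining every component to the largest one (nearest pair)."""
    pos = {mid: i for i, mid in enumerate(ids)}
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    if len(comps) <= 1:
        return []
    main = sorted(comps[0])
    main_idx = np.array([pos[m] for m in main])
    tree = cKDTree(coords_m[main_idx])
    extra = []
    for comp in comps[1:]:
        comp_sorted = sorted(comp)
        comp_idx = np.array([pos[m] for m in comp_sorted])
        d, nearest = tree.query(coords_m[comp_idx])
        best = int(np.argmin(d))
        u = int(comp_idx[best])
        v = int(main_idx[int(nearest[best])])
        extra.append((min(u, v), max(u, v), float(d[best])))
    return sorted(extra)


def _correlated_fields(
    coords_m: np.ndarray, n_fields: int, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_fields`` standard-normal fields with exponential-decay spatial
    correlation exp(-d / range) over the municipality coordinates.

    One Cholesky factor of the covariance is shared by all fields; a small
    diagonal jitter keeps the factorisation stable."""
    d_km = distance_matrix(coords_m, coords_m) / 1000.0
    cov = np.exp(-d_km / range_km)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = linalg.cholesky(cov, lower=True)
    z = rng.standard_normal((len(coords_m), n_fields))
    return chol @ z


def generate_country(
    seed: int,
    n_municipalities: int = 2122,
    n_districts: int = 116,
    params: GeneratorParams | None = None,
    catalogue: Catalogue | None = None,
) -> CountryFixture:
    """Generate a deterministic synthetic country fixture.

    The fixture supplies every raw-value field the indicator catalogue
    references, for every municipality; supra-municipal fields are constant
    within a district.  Deterministic given ``(seed, params)``.
    """
    if n_municipalities <= 0 or n_districts <= 0:
        raise ValueError("n_municipalities and n_districts must be positive")
    if n_districts > n_municipalities:
        raise ValueError(
            f"n_districts ({n_districts}) must not exceed n_municipalities ({n_municipalities})"
        )
    params = params or GeneratorParams()
    catalogue = catalogue or load_catalogue("default")

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(7)
    rng_coords, rng_pop, rng_ages, rng_net, rng_fac, rng_fields, rng_equiv = (
        np.random.default_rng(s) for s in streams
    )
    kmeans_seed = int(ss.generate_state(1)[0] % (2**31 - 1))

    # --- coordinates and districts ---------------------------------------
    area_m2 = params.area_per_municipality_km2 * n_municipalities * 1e6
    width = math.sqrt(area_m2 * params.aspect_ratio)
    height = area_m2 / width
    coords = np.column_stack(
        [rng_coords.uniform(0, width, n_municipalities), rng_coords.uniform(0, height, n_municipalities)]
    )
    ids = _municipality_ids(n_municipalities)
    district_idx = _assign_districts(coords, n_districts, kmeans_seed)
    district_ids = _district_ids(n_districts)

    # --- populations ------------------------------------------------------
    pop = np.maximum(
        params.min_population,
        np.rint(
            rng_pop.lognormal(math.log(params.median_population), params.population_sigma, n_municipalities)
        ).astype(int),
    )
    base = np.asarray(params.age_fractions)
    probs = rng_ages.dirichlet(base * params.age_concentration, size=n_municipalities)
    bands = np.vstack([rng_ages.multinomial(int(p), probs[i]) for i, p in enumerate(pop)])

    municipalities = pd.DataFrame(
        {
            "municipality_id": ids,
            "name": [f"Municipality {mid[1:]}" for mid in ids],
            "district_id": [district_ids[i] for i in district_idx],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "pop_total": pop,
            "pop_lt15": bands[:, 0],
            "pop_15_64": bands[:, 1],
            "pop_65_74": bands[:, 2],
            "pop_75_plus": bands[:, 3],
        }
    )
    districts = pd.DataFrame(
        {"district_id": district_ids, "name": [f"District {d[1:]}" for d in district_ids]}
    )

    # --- road network -----------------------------------------------------
    edges_idx = _knn_edges(coords, params.knn_k)
    minutes_per_m = 60.0 / (params.speed_kmh * 1000.0)
    rows = []
    for u, v, dist in edges_idx:
        noise = math.exp(rng_net.normal(0.0, params.edge_noise_sigma))
        rows.append((ids[u], ids[v], dist * minutes_per_m * noise))
    g = build_network(pd.DataFrame(rows, columns=["from_id", "to_id", "minutes"]), ids)
    for u, v, dist in _connect_components(g, coords, ids):
        noise = math.exp(rng_net.normal(0.0, params.edge_noise_sigma))
        rows.append((ids[u], ids[v], dist * minutes_per_m * noise))
        g.add_edge(ids[u], ids[v], minutes=rows[-1][2])

    # --- facilities -------------------------------------------------------
    fac_rows: list[tuple[str, str, str]] = []
    counts: dict[str, np.ndarray] = {}
    for ftype in sorted(params.facility_rates):
        lam = pop * params.facility_rates[ftype]
        counts[ftype] = rng_fac.poisson(lam)
    p_hosp = 1.0 - np.exp(-pop / params.hospital_scale_pop)
    counts["hospital"] = (rng_fac.uniform(size=n_municipalities) < p_hosp).astype(int)
    # guarantee the indicator set is well-defined nationally
    for ftype in list(counts):
        if counts[ftype].sum() == 0:
            counts[ftype][int(np.argmax(pop))] = 1
    fid = 1
    for ftype in sorted(counts):
        for i, c in enumerate(counts[ftype]):
            for _ in range(int(c)):
                fac_rows.append((f"F{fid:06d}", ftype, ids[i]))
                fid += 1
    facilities = pd.DataFrame(fac_rows, columns=["facility_id", "facility_type", "municipality_id"])

    # --- indicator raw values --------------------------------------------
    field_names = sorted(params.field_specs)
    z = _correlated_fields(coords, len(field_names), params.corr_range_km, rng_fields)
    wide = pd.DataFrame(index=ids)
    wide.index.name = "municipality_id"
    for j, name in enumerate(field_names):
        mean, sd, lo, hi = params.field_specs[name]
        wide[name] = np.clip(mean + sd * z[:, j], lo, hi)
    # supra-municipal fields: one value per district, copied to members
    dist_series = pd.Series(municipalities["district_id"].values, index=ids)
    for name in SUPRA_MUNICIPAL_FIELDS:
        if name in wide:
            wide[name] = wide.groupby(dist_series)[name].transform("mean")
    # demographic fields derived from the population bands
    pop_f = pop.astype(float)
    wide["pop_total"] = pop_f
    wide["pop_under_15"] = bands[:, 0].astype(float)
    wide["pop_65_plus"] = (bands[:, 2] + bands[:, 3]).astype(float)
    wide["pct_under_15"] = bands[:, 0] / pop_f * 100.0
    wide["pct_65_plus"] = (bands[:, 2] + bands[:, 3]) / pop_f * 100.0
    wide["pct_75_plus"] = bands[:, 3] / pop_f * 100.0
    # facility-count fields and utilisation equivalents
    for ftype, fname in FACILITY_COUNT_FIELDS.items():
        wide[fname] = counts[ftype].astype(float)
    hosp = counts["hospital"].astype(float)
    wide["gp_equivalents"] = counts["general_practice"] * rng_equiv.uniform(0.8, 1.2, n_municipalities) + 0.5 * hosp
    wide["paediatric_equivalents"] = counts["paediatrics"] * rng_equiv.uniform(0.8, 1.2, n_municipalities) + 0.2 * hosp
    wide["internist_equivalents"] = counts["internal_medicine"] * rng_equiv.uniform(0.8, 1.2, n_municipalities) + 0.4 * hosp

    missing = [f for f in catalogue.required_fields if f not in wide.columns]
    if missing:
        raise ValueError(f"generator does not produce catalogue fields: {missing}")

    raw_values = (
        wide.reset_index()
        .melt(id_vars="municipality_id", var_name="field_name", value_name="value")
        .sort_values(["field_name", "municipality_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CountryFixture(
        municipalities=municipalities,
        districts=districts,
        network=g,
        facilities=facilities,
        raw_values=raw_values,
        seed=seed,
    )


# --------------------------------------------------------------------------
# serialization


def _geojson_points(municipalities: pd.DataFrame) -> dict:
    features = []
    for rec in municipalities.to_dict("records"):
        props = {k: v for k, v in rec.items() if k not in ("x", "y")}
        props = {k: (int(v) if isinstance(v, np.integer) else v) for k, v in props.items()}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(rec["x"]), float(rec["y"])]},
                "properties": props,
            }
        )
    return {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "synthetic local planar metres"}},
        "features": features,
    }


def write_fixture(fixture: CountryFixture, directory: str | Path) -> list[Path]:
    """Write the fixture as plain-text files; returns the paths written.

    Emits municipalities (CSV and GeoJSON points), districts, the edge list,
    facilities and the long-format raw value table.  ``read_fixture`` on the
    directory reproduces the fixture exactly.
    """
    if not str(directory):
        raise OSError("fixture directory must be a non-empty path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / name for name in FIXTURE_FILES]
    fixture.municipalities.to_csv(directory / "municipalities.csv", index=False, float_format="%.17g")
    (directory / "municipalities.geojson").write_text(
        json.dumps(_geojson_points(fixture.municipalities)), encoding="utf-8"
    )
    fixture.districts.to_csv(directory / "districts.csv", index=False)
    edges = pd.DataFrame(
        sorted(
            (min(u, v), max(u, v), d["minutes"]) for u, v, d in fixture.network.edges(data=True)
        ),
        columns=["from_id", "to_id", "minutes"],
    )
    edges.to_csv(directory / "edges.csv", index=False, float_format="%.17g")
    fixture.facilities.to_csv(directory / "facilities.csv", index=False)
    fixture.raw_values.to_csv(directory / "raw_values.csv", index=False, float_format="%.17g")
    return paths


def read_fixture(directory: str | Path) -> CountryFixture:
    """Load a fixture previously written by :func:`write_fixture`."""
    directory = Path(directory)
    municipalities = pd.read_csv(
        directory / "municipalities.csv",
        dtype={"municipality_id": str, "district_id": str},
        float_precision="round_trip",
    )
    districts = pd.read_csv(directory / "districts.csv", dtype={"district_id": str})
    edges = pd.read_csv(
        directory / "edges.csv", dtype={"from_id": str, "to_id": str}, float_precision="round_trip"
    )
    network = build_network(edges, list(municipalities["municipality_id"]))
    facilities = pd.read_csv(
        directory / "facilities.csv",
        dtype={"facility_id": str, "facility_type": str, "municipality_id": str},
    )
    raw_values = pd.read_csv(
        directory / "raw_values.csv",
        dtype={"municipality_id": str, "field_name": str},
        float_precision="round_trip",
    )
    return CountryFixture(
        municipalities=municipalities,
        districts=districts,
        network=network,
        facilities=facilities,
        raw_values=raw_values,
    )
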