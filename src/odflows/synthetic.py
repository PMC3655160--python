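"""Synthetic airports, scale-free flight networks and ground-truth OD flows.

Real schedule and itinerary data for this problem are purchased or
restricted, so every downstream stage is exercised on simulated worlds with
known generative parameters: airports with heavy-tailed city populations
(all above the 100,000 inclusion floor) and country-clustered coordinates, a
degree-preferential (hence scale-free) capacity-weighted network, and OD
flows drawn from the generative analogue of the lognormal mixed gravity
model — a log-scale linear predictor plus origin, destination and
degree-link-type random intercepts and lognormal noise, optionally thinned
to a 10% ticket sample and rescaled x10.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import network as net

#: Default true fixed effects for the generator, on the log-flow scale.
#: Calibrated once so that generated flows span the five magnitude
#: categories (1 to >1e5 annual passengers) like observed itinerary data.
DEFAULT_COEFFICIENTS = {
    "intercept": -23.0,
    "log_pop_i": 0.55, "log_pop_j": 0.55,
    "log_pda_i": 0.35, "log_pda_j": 0.35,
    "log_strength_i": 0.25, "log_strength_j": 0.25,
    "inv_distance": 400.0,
    "same_country": 0.8,
    "log_maxc": 0.3,
    "stops[1]": -0.6, "stops[2]": -1.2,
}


@dataclass
class GravityTruth:
    """Generative parameters: fixed effects and random-effect SDs (log scale)."""

    fixed_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    sigma_origin: float = 0.5
    sigma_dest: float = 0.5
    sigma_hierarchy: float = 0.3
    sigma_resid: float = 0.5
    sample_fraction: float = 1.0

    def __post_init__(self):
        for name in ("sigma_origin", "sigma_dest", "sigma_hierarchy", "sigma_resid"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GravityTruth":
        return cls(**json.loads(text))


@dataclass
class SyntheticWorld:
    """A fully specified simulated study system."""

    airports: pd.DataFrame
    edges: pd.DataFrame
    routes: pd.DataFrame
    true_params: GravityTruth
    flows: pd.DataFrame
    seed: int


def _codes(n: int):
    letters = string.ascii_uppercase
    out = ["".join(t) for t in itertools.islice(itertools.product(letters, repeat=3), n)]
    return out


def generate_airports(n: int, seed: int, population_range=(1e5, 2e7),
                      n_countries: int = 12) -> pd.DataFrame:
    """Airports with clustered coordinates and heavy-tailed populations.

    Populations are log-uniform over ``population_range`` (lower bound must
    respect the 100,000 city-population inclusion floor).  Countries are
    spatially clustered: each is a dispersion kernel around a random centre,
    so "same country" correlates with proximity.  PPP per capita has a
    country-level component; total PPP is per-capita PPP times a noisy
    population (the economic grid cell does not coincide with the city).
    """
    if n < 2:
        raise ValueError("need at least 2 airports")
    lo, hi = population_range
    if lo < 1e5:
        raise ValueError("population_range lower bound must be >= 100,000")
    if n_countries < 1:
        raise ValueError("n_countries must be positive")
    rng = np.random.default_rng(seed)
    centers_lat = rng.uniform(-50, 65, n_countries)
    centers_lon = rng.uniform(-180, 180, n_countries)
    country_mu = rng.normal(np.log(2e4), 0.6, n_countries)
    weights = rng.dirichlet(np.full(n_countries, 2.0))
    cidx = rng.choice(n_countries, size=n, p=weights)
    lat = np.clip(centers_lat[cidx] + rng.normal(0, 4.0, n), -89.0, 89.0)
    lon = (centers_lon[cidx] + rng.normal(0, 6.0, n) + 180.0) % 360.0 - 180.0
    population = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    pda = np.exp(country_mu[cidx] + rng.normal(0, 0.35, n))
    ppp = pda * population * np.exp(rng.normal(0, 0.4, n))
    codes = _codes(n)
    return pd.DataFrame({
        "code": codes,
        "lat": np.round(lat, 6),
        "lon": np.round(lon, 6),
        "city": [f"City-{c}" for c in codes],
        "country": [f"C{k:02d}" for k in cidx],
        "population": np.round(population).astype(np.int64),
        "ppp": ppp,
        "ppp_per_capita": pda,
    }).set_index("code", drop=False).rename_axis(None)


def generate_network(airports: pd.DataFrame, mean_degree: float = 8.0,
                     seed: int = 0, capacity_base: float = 2000.0,
                     capacity_exponent: float = 0.5) -> pd.DataFrame:
    """Connected scale-free flight network by degree-preferential attachment.

    Builds an undirected graph with ~``n * mean_degree / 2`` links (each
    emitted as two directed arcs): a seed clique, preferential attachment of
    each new node, then preferential densification up to the target edge
    count.  Per-link annual seat capacity grows with the endpoint degrees:
    ``capacity_base * (deg_u * deg_v) ** capacity_exponent``.
    """
    n = len(airports)
    if n < 3:
        raise ValueError("need at least 3 airports")
    if mean_degree <= 0 or mean_degree > n - 1:
        raise ValueError("mean_degree must be in (0, n-1]")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(mean_degree / 2.0)))
    target = int(round(n * mean_degree / 2.0))
    order = rng.permutation(n)
    adj = {i: set() for i in range(n)}
    deg = np.zeros(n, dtype=float)

    def add(u, v):
        adj[u].add(v)
        adj[v].add(u)
        deg[u] += 1
        deg[v] += 1

    seed_nodes = order[:m + 1]
    for a, b in itertools.combinations(seed_nodes, 2):
        add(a, b)
    attached = list(seed_nodes)
    for v in order[m + 1:]:
        w = deg[attached] + 1e-9
        k = min(m, len(attached))
        targets = rng.choice(attached, size=k, replace=False, p=w / w.sum())
        for t in targets:
            add(v, t)
        attached.append(v)
    n_edges = int(deg.sum() / 2)
    tries = 0
    while n_edges < target and tries < 50 * target:
        tries += 1
        w = deg + 1e-9
        u, v = rng.choice(n, size=2, replace=False, p=w / w.sum())
        if v in adj[u]:
            continue
        add(u, v)
        n_edges += 1
    codes = airports["code"].to_numpy()
    lat = airports["lat"].to_numpy()
    lon = airports["lon"].to_numpy()
    rows = []
    for u in range(n):
        for v in sorted(adj[u]):
            if u < v:
                dist = max(net.haversine_km(lat[u], lon[u], lat[v], lon[v]), 1.0)
                capv = max(1.0, round(capacity_base * (deg[u] * deg[v]) ** capacity_exponent))
                rows.append((codes[u], codes[v], dist, capv))
                rows.append((codes[v], codes[u], dist, capv))
    edges = pd.DataFrame(rows, columns=["origin", "dest", "distance_km", "capacity"])
    return edges.sort_values(["origin", "dest"]).reset_index(drop=True)


def true_linear_predictor(design: pd.DataFrame, coefficients: dict) -> np.ndarray:
    """Evaluate the generator's fixed-effect linear predictor on a design frame.

    Coefficient keys are either numeric column names or categorical-level
    indicators written ``column[level]``.
    """
    lp = np.zeros(len(design))
    for name, beta in coefficients.items():
        if name == "intercept":
            lp = lp + beta
        elif "[" in name:
            col, level = name[:-1].split("[", 1)
            if col not in design.columns:
                raise KeyError(f"generator covariate {col!r} missing from design")
            lp = lp + beta * (design[col].astype(str).to_numpy() == level)
        else:
            if name not in design.columns:
                raise KeyError(f"generator covariate {name!r} missing from design")
            lp = lp + beta * design[name].to_numpy(dtype=float)
    return lp


def generate_flows(airports: pd.DataFrame, edges: pd.DataFrame,
                   routes: pd.DataFrame, truth: GravityTruth,
                   seed: int, round_to_int: bool = True) -> pd.DataFrame:
    """Draw OD flows from the generative mixed gravity model.

    log flow = fixed linear predictor + origin intercept + destination
    intercept + degree-link-type intercept + N(0, sigma_resid) noise;
    flows are exponentiated, rounded half-up to whole passengers, and
    records below 1 passenger are dropped.  With ``sample_fraction`` f < 1
    each itinerary count is binomially thinned and rescaled by 1/f (the 10%
    ticket-sample emulation).  ``round_to_int=False`` keeps the exact
    continuous flows (used for exactness checks in the zero-noise limit;
    thinning requires integer flows and is skipped in that mode).
    """
    graph = net.build_graph(edges, airports)
    metrics = net.node_metrics(graph)
    scheme = cov.classify_hierarchies(airports, metrics)
    design = cov.build_design(routes, airports, metrics, scheme)
    lp = true_linear_predictor(design, truth.fixed_coefficients)
    rng = np.random.default_rng(seed)
    re_o = {c: rng.normal(0, truth.sigma_origin) for c in sorted(airports.index)}
    re_d = {c: rng.normal(0, truth.sigma_dest) for c in sorted(airports.index)}
    groups = sorted(design["degree_link_type"].astype(str).unique())
    re_h = {g: rng.normal(0, truth.sigma_hierarchy) for g in groups}
    log_flow = (lp
                + np.array([re_o[c] for c in design["origin"]])
                + np.array([re_d[c] for c in design["dest"]])
                + np.array([re_h[g] for g in design["degree_link_type"].astype(str)])
                + rng.normal(0, truth.sigma_resid, len(design)))
    passengers = np.exp(log_flow)
    if round_to_int:
        passengers = np.floor(passengers + 0.5)
    out = pd.DataFrame({"origin": design["origin"], "dest": design["dest"],
                        "passengers": passengers})
    out = out[out["passengers"] >= 1].reset_index(drop=True)
    f = truth.sample_fraction
    if f < 1.0 and round_to_int:
        thinned = rng.binomial(out["passengers"].astype(np.int64), f) / f
        out["passengers"] = thinned
        out = out[out["passengers"] >= 1].reset_index(drop=True)
    if round_to_int:
        out["passengers"] = out["passengers"].astype(np.int64)
    return out


def simulate_world(n_airports: int = 300, mean_degree: float = 8.0,
                   n_flows: int | None = 5000, truth: GravityTruth | None = None,
                   seed: int = 0, min_km: float = 200.0) -> SyntheticWorld:
    """End-to-end simulation: airports, network, routes and training flows.

    ``n_flows`` caps how many enumerated routes receive an observed training
    flow (observed itinerary data cover only part of the network); None
    keeps all routes.
    """
    truth = truth if truth is not None else GravityTruth()
    rng = np.random.default_rng(seed)
    airports = generate_airports(n_airports, seed=int(rng.integers(2**31)))
    edges = generate_network(airports, mean_degree=mean_degree,
                             seed=int(rng.integers(2**31)))
    graph = net.build_graph(edges, airports)
    routes = net.enumerate_routes(graph, airports, min_km=min_km)
    train_routes = routes
    if n_flows is not None and n_flows < len(routes):
        pick = np.sort(rng.choice(len(routes), size=n_flows, replace=False))
        train_routes = routes.iloc[pick].reset_index(drop=True)
    flows = generate_flows(airports, edges, train_routes, truth,
                           seed=int(rng.integers(2**31)))
    return SyntheticWorld(airports=airports, edges=edges, routes=routes,
                          true_params=truth, flows=flows, seed=seed)


def write_world(world: SyntheticWorld, outdir) -> dict:
    """Write airports.csv, edges.csv, flows.csv and truth.json; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "airports": outdir / "airports.csv",
        "edges": outdir / "edges.csv",
        "flows": outdir / "flows.csv",
        "truth": outdir / "truth.json",
    }
    world.airports.to_csv(paths["airports"], index=False)
    world.edges.to_csv(paths["edges"], index=False)
    world.flows.to_csv(paths["flows"], index=False)
    paths["truth"].write_text(world.true_params.to_json())
    return paths


def read_airports(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"code", "lat", "lon", "city", "country", "population",
                "ppp", "ppp_per_capita"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"airports table missing columns: {sorted(missing)}")
    return df.set_index("code", drop=False).rename_axis(None)
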