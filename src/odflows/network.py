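"""Flight-network construction, node metrics and k-stop route enumeration.

The air-travel network is a directed graph whose nodes are airports and whose
arcs are scheduled direct connections weighted by annual seat capacity.
Passengers are assumed to take the minimum-stop route found by breadth-first
search with a deterministic (lexicographic by airport code) neighbour order,
and never to use more than two stops.  Routes whose endpoint great-circle
distance is under a cutoff (200 km by default) are discarded, since such trips
are dominated by ground transport.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: stage-length class breaks, km: short <= 2000 < medium < 3500 <= long
SHORT_HAUL_MAX_KM = 2000.0
LONG_HAUL_MIN_KM = 3500.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between two points given in degrees.

    Accepts scalars or numpy arrays (broadcast).  Uses a spherical Earth of
    radius 6,371 km.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("longitude out of range [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if d.ndim == 0:
        return float(d)
    return d


def haul_type(distance_km: float) -> int:
    """Stage-length class: 1 short (<=2000 km), 2 medium, 3 long (>=3500 km)."""
    if distance_km <= 0:
        raise ValueError("distance must be positive")
    if distance_km <= SHORT_HAUL_MAX_KM:
        return 1
    if distance_km < LONG_HAUL_MIN_KM:
        return 2
    return 3


@dataclass(frozen=True)
class Route:
    """A minimum-stop itinerary between an ordered airport pair."""

    origin: str
    dest: str
    path: tuple
    stops: int
    gc_distance_km: float
    max_capacity: float
    haul_type: int
    n_alternatives: int
    same_country: bool | None = None


def build_graph(edges: pd.DataFrame, airports: pd.DataFrame | None = None) -> nx.DiGraph:
    """Build the directed flight graph from an edge table.

    ``edges`` must have columns origin, dest, distance_km, capacity.  If an
    airports table (indexed by code, with lat/lon/country) is given, those
    fields are attached as node attributes so route enumeration can compute
    great-circle distances and same-country flags.
    """
    required = {"origin", "dest", "capacity"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    g = nx.DiGraph()
    seen = set()
    for row in edges.itertuples(index=False):
        pair = (row.origin, row.dest)
        if pair in seen:
            raise ValueError(f"duplicate arc {pair[0]}->{pair[1]}")
        seen.add(pair)
        g.add_edge(row.origin, row.dest,
                   capacity=float(row.capacity),
                   distance_km=float(getattr(row, "distance_km", np.nan)))
    if airports is not None:
        for code in g.nodes:
            if code not in airports.index:
                raise ValueError(f"edge references unknown airport {code!r}")
            a = airports.loc[code]
            g.nodes[code].update(lat=float(a["lat"]), lon=float(a["lon"]),
                                 country=str(a["country"]))
    return g


def node_metrics(graph: nx.DiGraph) -> pd.DataFrame:
    """Degree, strength and centrality measures for every node.

    Returns a frame indexed by airport code with columns degree_out,
    degree_in, degree_total, strength, closeness, betweenness.

    * strength is the sum of capacities of all adjacent arcs (in + out);
    * closeness is the inverse mean hop-count geodesic distance from the node
      to the nodes it can reach (0 if it reaches none);
    * betweenness is the unnormalised shortest-path count with even split
      across equal-length geodesics.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    btw = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    for v in nodes:
        out_cap = sum(d["capacity"] for _, _, d in graph.out_edges(v, data=True))
        in_cap = sum(d["capacity"] for _, _, d in graph.in_edges(v, data=True))
        dists = nx.single_source_shortest_path_length(graph, v)
        reach = [d for u, d in dists.items() if u != v]
        closeness = (len(reach) / sum(reach)) if reach and sum(reach) > 0 else 0.0
        rows.append({
            "code": v,
            "degree_out": graph.out_degree(v),
            "degree_in": graph.in_degree(v),
            "degree_total": graph.out_degree(v) + graph.in_degree(v),
            "strength": out_cap + in_cap,
            "closeness": closeness,
            "betweenness": btw[v],
        })
    return pd.DataFrame(rows).set_index("code")


def _bfs(graph: nx.DiGraph, source: str, max_depth: int):
    """BFS with lexicographic neighbour order.

    Returns (dist, parent, npaths) dicts restricted to depth <= max_depth.
    ``parent`` gives the predecessor on the first-found (lexicographically
    smallest) shortest path; ``npaths`` counts distinct shortest paths.
    """
    dist = {source: 0}
    parent = {source: None}
    npaths = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] == max_depth:
            continue
        for v in sorted(graph.successors(u)):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                npaths[v] = npaths[u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                npaths[v] += npaths[u]
    return dist, parent, npaths


def _path_from_parent(parent: Mapping[str, str | None], dest: str) -> tuple:
    path = [dest]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return tuple(reversed(path))


def _route_from_search(graph, origin, dest, dist, parent, npaths) -> Route | None:
    if dest not in dist:
        return None
    path = _path_from_parent(parent, dest)
    max_cap = max(graph.edges[a, b]["capacity"] for a, b in zip(path, path[1:]))
    nd = graph.nodes
    if "lat" in nd[origin] and "lat" in nd[dest]:
        gc = haversine_km(nd[origin]["lat"], nd[origin]["lon"],
                          nd[dest]["lat"], nd[dest]["lon"])
        same = nd[origin].get("country") == nd[dest].get("country")
    else:
        gc = float("nan")
        same = None
    return Route(origin=origin, dest=dest, path=path, stops=dist[dest] - 1,
                 gc_distance_km=gc, max_capacity=max_cap,
                 haul_type=haul_type(gc) if gc == gc and gc > 0 else 0,
                 n_alternatives=npaths[dest], same_country=same)


def shortest_route(graph: nx.DiGraph, origin: str, dest: str,
                   max_stops: int = 2) -> Route | None:
    """First minimum-stop route found by lexicographic BFS, or None.

    ``stops`` is the number of intermediate airports (0 = direct).  Routes
    needing more than ``max_stops`` stops are treated as absent.
    """
    for code in (origin, dest):
        if code not in graph:
            raise KeyError(f"unknown airport code {code!r}")
    if origin == dest:
        raise ValueError("origin and destination must differ")
    dist, parent, npaths = _bfs(graph, origin, max_depth=max_stops + 1)
    return _route_from_search(graph, origin, dest, dist, parent, npaths)


def multi_airport_city_route(graph: nx.DiGraph,
                             origin_airports: Sequence[str],
                             dest_airports: Sequence[str],
                             metrics: pd.DataFrame | None = None,
                             max_stops: int = 2) -> Route | None:
    """Best route between two multi-airport cities.

    The minimum-stop route over all origin x destination airport pairs is
    chosen; ties on stop count are broken in favour of the pair with the
    larger combined node strength (passengers prefer the bigger hubs).
    ``metrics`` supplies the strength column; without it, ties break
    lexicographically.
    """
    if not origin_airports or not dest_airports:
        raise ValueError("airport lists must be nonempty")
    best = None
    best_key = None
    for o in sorted(origin_airports):
        for d in sorted(dest_airports):
            if o == d:
                continue
            r = shortest_route(graph, o, d, max_stops=max_stops)
            if r is None:
                continue
            strength = 0.0
            if metrics is not None:
                strength = float(metrics.loc[o, "strength"] + metrics.loc[d, "strength"])
            key = (r.stops, -strength)
            if best is None or key < best_key:
                best, best_key = r, key
    return best


def enumerate_routes(graph: nx.DiGraph, airports: pd.DataFrame,
                     max_stops: int = 2, min_km: float = 200.0) -> pd.DataFrame:
    """All-pairs minimum-stop routes with per-route covariates.

    One row per ordered airport pair reachable within ``max_stops`` stops and
    separated by at least ``min_km`` great-circle km.  Columns: origin, dest,
    stops, path ("|"-joined codes), gc_distance_km, max_capacity, haul_type,
    n_alternatives, same_country.
    """
    nodes = sorted(graph.nodes)
    lat = airports["lat"]
    lon = airports["lon"]
    country = airports["country"]
    rows = []
    for o in nodes:
        dist, parent, npaths = _bfs(graph, o, max_depth=max_stops + 1)
        if not dist:
            continue
        targets = [d for d in dist if d != o]
        if not targets:
            continue
        gcs = haversine_km(lat.loc[o], lon.loc[o],
                           lat.loc[targets].to_numpy(), lon.loc[targets].to_numpy())
        gcs = np.atleast_1d(gcs)
        for d, gc in zip(targets, gcs):
            if gc < min_km:
                continue
            path = _path_from_parent(parent, d)
            max_cap = max(graph.edges[a, b]["capacity"] for a, b in zip(path, path[1:]))
            rows.append((o, d, dist[d] - 1, "|".join(path), float(gc), max_cap,
                         haul_type(float(gc)), npaths[d],
                         country.loc[o] == country.loc[d]))
    return pd.DataFrame(rows, columns=["origin", "dest", "stops", "path",
                                       "gc_distance_km", "max_capacity",
                                       "haul_type", "n_alternatives",
                                       "same_country"])


def fit_power_law_exponent(degrees: Iterable[int]) -> float:
    """Power-law exponent of a degree distribution.

    Fits the empirical survival function S(k) = P(K >= k) on a log-log scale
    by least squares over the distinct observed degrees and returns the
    implied density exponent alpha (S(k) ~ k^{1-alpha} for a power law with
    p(k) ~ k^{-alpha}).  Requires at least 10 distinct positive degrees;
    degenerate sequences raise ``ValueError``.
    """
    k = np.asarray(list(degrees), dtype=float)
    if np.any(k <= 0):
        raise ValueError("degrees must be positive")
    uniq = np.unique(k)
    if uniq.size < 10:
        raise ValueError("degenerate degree sequence: need >= 10 distinct degrees")
    # survival at each distinct degree value
    surv = np.array([(k >= u).mean() for u in uniq])
    x = np.log(uniq)
    y = np.log(surv)
    slope = np.polyfit(x, y, 1)[0]
    return float(1.0 - slope)


def mean_degree(n_nodes: int, n_undirected_edges: int) -> float:
    """Average degree of an undirected graph: 2E / N."""
    if n_nodes <= 0 or n_undirected_edges < 0:
        raise ValueError("invalid counts")
    return 2.0 * n_undirected_edges / n_nodes
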