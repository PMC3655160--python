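import numpy as np
import pandas as pd
import pytest

import odflows as od


def edges_frame(links, capacity=1000.0, distance=500.0):
    """Directed edge table from (origin, dest) pairs; both-way helper below."""
    rows = []
    for link in links:
        o, d = link[0], link[1]
        cap = link[2] if len(link) > 2 else capacity
        rows.append({"origin": o, "dest": d, "distance_km": distance,
                     "capacity": cap})
    return pd.DataFrame(rows)


def mutual_edges(pairs, capacity=1000.0, distance=500.0):
    links = []
    for p in pairs:
        o, d = p[0], p[1]
        cap = p[2] if len(p) > 2 else capacity
        links.append((o, d, cap))
        links.append((d, o, cap))
    return edges_frame(links, distance=distance)


def design_for(world):
    """Training design for a synthetic world: covariate rows + observed flows."""
    graph = od.build_graph(world.edges, world.airports)
    metrics = od.node_metrics(graph)
    scheme = od.classify_hierarchies(world.airports, metrics)
    X = od.build_design(world.routes, world.airports, metrics, scheme)
    X = X.merge(world.flows, on=["origin", "dest"], how="inner")
    return X, X["passengers"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def small_world():
    """A 60-airport world with ~800 observed flows, shared across tests."""
    return od.simulate_world(n_airports=60, mean_degree=6, n_flows=800, seed=11)


@pytest.fixture(scope="session")
def small_design(small_world):
    return design_for(small_world)


@pytest.fixture(scope="session")
def toy_airports():
    """Five airports on a line of longitudes, two countries."""
    lons = {"AAA": 0.0, "BBB": 5.0, "CCC": 10.0, "DDD": 15.0, "EEE": 20.0}
    return pd.DataFrame({
        "code": list(lons),
        "lat": 0.0,
        "lon": list(lons.values()),
        "city": [f"City-{c}" for c in lons],
        "country": ["X", "X", "X", "Y", "Y"],
        "population": [2e5, 4e5, 8e5, 1.6e6, 3.2e6],
        "ppp": [1e9, 2e9, 4e9, 8e9, 1.6e10],
        "ppp_per_capita": [1e3, 2e3, 4e3, 8e3, 1.6e4],
    }).set_index("code", drop=False).rename_axis(None)
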