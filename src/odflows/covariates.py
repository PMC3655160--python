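"""Airport hierarchies, link types and the per-route covariate row.

Cities sit in a hierarchical network; flows between them are shaped by that
hierarchy.  Airports are classified into three economic levels (tertiles of
purchasing-power-parity per capita) and four service levels (quartiles of
network degree).  Each ordered route then carries an economic link type (one
of 9 ordered level pairs) and a degree link type (one of 16), alongside the
node metrics and route geometry, all log-transformed where quantitative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Route

log = logging.getLogger(__name__)

ECONOMIC_LEVEL_LABELS = ("L", "M", "H")
DEGREE_LEVEL_LABELS = ("1", "2", "3", "4")

#: quantitative design columns (natural-log transformed node/route measures)
NUMERIC_COLUMNS = [
    "log_pop_i", "log_pop_j", "log_ppp_i", "log_ppp_j",
    "log_pda_i", "log_pda_j", "log_strength_i", "log_strength_j",
    "log_degree_out_i", "log_degree_in_j",
    "log_closeness_i", "log_closeness_j",
    "log_betweenness_i", "log_betweenness_j",
    "inv_distance", "log_maxc", "n_alternatives", "same_country",
]
#: categorical design columns
CATEGORICAL_COLUMNS = ["stops", "haul_type", "degree_link_type", "economic_link_type"]


@dataclass
class HierarchyScheme:
    """Quantile-based airport classification.

    ``economic_breaks`` are the 33%/67% quantiles of ppp-per-capita;
    ``degree_breaks`` the 25/50/75% quantiles of (total) degree.  Level
    assignment sends a value equal to a break to the lower level.
    """

    economic_breaks: np.ndarray
    degree_breaks: np.ndarray
    economic_levels: dict = field(default_factory=dict)
    degree_levels: dict = field(default_factory=dict)


def _assign_levels(values: pd.Series, breaks: np.ndarray, labels) -> dict:
    idx = np.searchsorted(breaks, values.to_numpy(), side="left")
    return {code: labels[i] for code, i in zip(values.index, idx)}


def classify_hierarchies(airports: pd.DataFrame, metrics: pd.DataFrame,
                         degree_column: str = "degree_total") -> HierarchyScheme:
    """Classify airports into economic tertiles and degree quartiles.

    ``degree_column`` selects which degree the service hierarchy uses
    (total by default; out/in configurable).
    """
    if len(airports) < 4:
        raise ValueError("need at least 4 airports to form quartiles")
    pda = airports["ppp_per_capita"]
    deg = metrics.loc[airports.index, degree_column].astype(float)
    econ_breaks = np.quantile(pda.to_numpy(), [1 / 3, 2 / 3])
    deg_breaks = np.quantile(deg.to_numpy(), [0.25, 0.5, 0.75])
    if pda.nunique() == 1:
        warnings.warn("all airports share one ppp_per_capita value; "
                      "economic hierarchy is degenerate", stacklevel=2)
    if deg.nunique() == 1:
        warnings.warn("all airports share one degree value; "
                      "degree hierarchy is degenerate", stacklevel=2)
    return HierarchyScheme(
        economic_breaks=econ_breaks,
        degree_breaks=deg_breaks,
        economic_levels=_assign_levels(pda, econ_breaks, ECONOMIC_LEVEL_LABELS),
        degree_levels=_assign_levels(deg, deg_breaks, DEGREE_LEVEL_LABELS),
    )


def link_type(level_i: str, level_j: str) -> str:
    """Ordered-pair hierarchy label, e.g. ("L","H") -> "L-H".

    Direction is preserved: flows up and down the hierarchy get distinct
    labels.
    """
    known = set(ECONOMIC_LEVEL_LABELS) | set(DEGREE_LEVEL_LABELS)
    if level_i not in known or level_j not in known:
        raise ValueError(f"unknown hierarchy level: {level_i!r}/{level_j!r}")
    return f"{level_i}-{level_j}"


def build_design(routes: pd.DataFrame, airports: pd.DataFrame,
                 metrics: pd.DataFrame, scheme: HierarchyScheme) -> pd.DataFrame:
    """Assemble the model design frame: one covariate row per route.

    All quantitative covariates are natural-log transformed; betweenness,
    which can be 0, is offset by +1 before the log.  Inverse distance is
    1/gc_distance_km.  Categorical columns (stops, haul_type and the two
    link types) are carried as pandas ``category`` columns.
    """
    o = routes["origin"]
    d = routes["dest"]
    for codes, name in ((o, "origin"), (d, "dest")):
        unknown = set(codes) - set(airports.index)
        if unknown:
            raise KeyError(f"{name} airports missing from table: {sorted(unknown)[:5]}")

    def node(frame, col, codes):
        return frame[col].reindex(codes).to_numpy(dtype=float)

    df = pd.DataFrame({
        "origin": o.to_numpy(), "dest": d.to_numpy(),
        "log_pop_i": np.log(node(airports, "population", o)),
        "log_pop_j": np.log(node(airports, "population", d)),
        "log_ppp_i": np.log(node(airports, "ppp", o)),
        "log_ppp_j": np.log(node(airports, "ppp", d)),
        "log_pda_i": np.log(node(airports, "ppp_per_capita", o)),
        "log_pda_j": np.log(node(airports, "ppp_per_capita", d)),
        "log_strength_i": np.log(node(metrics, "strength", o)),
        "log_strength_j": np.log(node(metrics, "strength", d)),
        "log_degree_out_i": np.log(node(metrics, "degree_out", o)),
        "log_degree_in_j": np.log(node(metrics, "degree_in", d)),
        "log_closeness_i": np.log(node(metrics, "closeness", o)),
        "log_closeness_j": np.log(node(metrics, "closeness", d)),
        "log_betweenness_i": np.log1p(node(metrics, "betweenness", o)),
        "log_betweenness_j": np.log1p(node(metrics, "betweenness", d)),
        "inv_distance": 1.0 / routes["gc_distance_km"].to_numpy(dtype=float),
        "same_country": routes["same_country"].to_numpy(dtype=float),
        "n_alternatives": routes["n_alternatives"].to_numpy(dtype=float),
        "log_maxc": np.log(routes["max_capacity"].to_numpy(dtype=float)),
    })
    df["stops"] = pd.Categorical(routes["stops"].astype(str), categories=["0", "1", "2"])
    df["haul_type"] = pd.Categorical(routes["haul_type"].astype(str),
                                     categories=["1", "2", "3"])
    dlt = [link_type(scheme.degree_levels[a], scheme.degree_levels[b])
           for a, b in zip(o, d)]
    elt = [link_type(scheme.economic_levels[a], scheme.economic_levels[b])
           for a, b in zip(o, d)]
    dlt_levels = [f"{a}-{b}" for a in DEGREE_LEVEL_LABELS for b in DEGREE_LEVEL_LABELS]
    elt_levels = [f"{a}-{b}" for a in ECONOMIC_LEVEL_LABELS for b in ECONOMIC_LEVEL_LABELS]
    df["degree_link_type"] = pd.Categorical(dlt, categories=dlt_levels)
    df["economic_link_type"] = pd.Categorical(elt, categories=elt_levels)
    bad = [c for c in NUMERIC_COLUMNS if not np.all(np.isfinite(df[c].to_numpy(dtype=float)))]
    if bad:
        raise ValueError(f"non-finite covariates in columns {bad}; "
                         "check for zero metrics that need an offset")
    return df


def build_covariate_row(route: Route, metrics: pd.DataFrame,
                        scheme: HierarchyScheme, airports: pd.DataFrame) -> pd.Series:
    """Covariate row for a single :class:`~odflows.network.Route`."""
    routes = pd.DataFrame([{
        "origin": route.origin, "dest": route.dest, "stops": route.stops,
        "gc_distance_km": route.gc_distance_km, "max_capacity": route.max_capacity,
        "haul_type": route.haul_type, "n_alternatives": route.n_alternatives,
        "same_country": bool(route.same_country),
    }])
    return build_design(routes, airports, metrics, scheme).iloc[0]
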