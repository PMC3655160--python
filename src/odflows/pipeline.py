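"""Final OD-matrix assembly: capacity caps, itinerary caps, sub-1 removal.

A fitted model is applied to every enumerated route; the raw predictions are
then post-processed: predictions exceeding the route's maximum seat capacity
are replaced by that capacity; one-stop and two-stop predictions are capped
by the largest itinerary counts observed in mature markets (140,086 and
8,060 annual passengers by default); predictions below one passenger are
removed; and the result is rounded to whole passengers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ONE_STOP_CAP = 140_086
TWO_STOP_CAP = 8_060


def postprocess(predictions: pd.DataFrame, routes: pd.DataFrame,
                one_stop_cap: float = ONE_STOP_CAP,
                two_stop_cap: float = TWO_STOP_CAP,
                mode: str = "cap") -> pd.DataFrame:
    """Apply the post-prediction rules and return the final flow entries.

    ``predictions`` needs columns origin, dest, point; ``routes`` supplies
    stops and max_capacity per (origin, dest).  Rules, in order: (a) replace
    predictions above the route's max seat capacity by that capacity;
    (b) cap one-stop flows at ``one_stop_cap`` and two-stop flows at
    ``two_stop_cap`` (``mode="rescale"`` instead rescales each stop class
    proportionally so its maximum equals the cap, when it exceeds it);
    (c) drop entries below 1 passenger; then round half-up.  The operation
    is idempotent.
    """
    route_info = routes.set_index(["origin", "dest"])[["stops", "max_capacity"]]
    key = pd.MultiIndex.from_arrays([predictions["origin"], predictions["dest"]])
    try:
        info = route_info.loc[key]
    except KeyError as exc:
        raise ValueError(f"prediction for unknown route: {exc}") from exc
    stops = info["stops"].to_numpy()
    maxcap = info["max_capacity"].to_numpy(dtype=float)
    p = predictions["point"].to_numpy(dtype=float).copy()
    p = np.minimum(p, maxcap)
    if mode == "cap":
        p = np.where(stops == 1, np.minimum(p, one_stop_cap), p)
        p = np.where(stops == 2, np.minimum(p, two_stop_cap), p)
    elif mode == "rescale":
        for s, cap in ((1, one_stop_cap), (2, two_stop_cap)):
            m = stops == s
            if m.any() and p[m].max() > cap:
                p[m] = p[m] * (cap / p[m].max())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame({"origin": predictions["origin"].to_numpy(),
                        "dest": predictions["dest"].to_numpy(),
                        "stops": stops, "passengers": p})
    out = out[out["passengers"] >= 1.0].reset_index(drop=True)
    out["passengers"] = np.floor(out["passengers"] + 0.5).astype(np.int64)
    return out


def summarize_matrix(entries: pd.DataFrame, flow_threshold: float = 1e5,
                     incoming_threshold: float = 5e6) -> dict:
    """Headline counts for a predicted OD matrix.

    Per-stop route counts (and their total), distinct airports covered,
    routes above ``flow_threshold`` passengers, and airports whose total
    incoming passengers exceed ``incoming_threshold``.
    """
    if len(entries) == 0:
        raise ValueError("empty flow matrix")
    by_stops = entries.groupby("stops")["passengers"].size().to_dict()
    incoming = entries.groupby("dest")["passengers"].sum()
    big_in = incoming[incoming > incoming_threshold]
    return {
        "routes_by_stops": {int(k): int(v) for k, v in by_stops.items()},
        "total_routes": int(len(entries)),
        "n_airports": int(pd.unique(entries[["origin", "dest"]].to_numpy().ravel()).size),
        "routes_above_threshold": int((entries["passengers"] > flow_threshold).sum()),
        "flow_threshold": float(flow_threshold),
        "airports_above_incoming_threshold": sorted(big_in.index.tolist()),
        "incoming_threshold": float(incoming_threshold),
        "total_passengers": int(entries["passengers"].sum()),
    }
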