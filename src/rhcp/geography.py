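"""Travel times, isochrone catchments and nearest-facility distances.

Travel time between municipalities is modelled as the shortest path on a
weighted undirected graph whose nodes are municipalities and whose edge
weights are car-travel minutes between them (centroid to centroid).  A
catchment area is the isochrone membership set: every municipality reachable
from the location municipality within a minute cutoff.  Catchments are
deliberately not bound by district borders — they reflect the expected
clientele of a primary health care unit, not administrative geography.

The boundary is closed: a municipality whose travel time equals the cutoff
exactly is inside the catchment.  Unreachable municipalities are simply
absent; a disconnected network is legal input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

#: Marker for undefined travel times / indicator values (rendered as "n/a").
MISSING = math.nan

DEFAULT_CUTOFFS = (10.0, 15.0, 20.0)


class UnknownLocationError(KeyError):
    def __init__(self, location_id: str):
        super().__init__(f"unknown municipality: {location_id!r}")
        self.location_id = location_id


class UnknownFacilityTypeError(ValueError):
    def __init__(self, facility_type: str, known: tuple[str, ...]):
        super().__init__(
            f"unknown facility_type {facility_type!r}; known types: {sorted(known)}"
        )


def build_network(edges: pd.DataFrame, municipality_ids: list[str] | None = None) -> nx.Graph:
    """Build the travel network from an edge list.

    ``edges`` needs columns ``from_id``, ``to_id``, ``minutes``.  Weights must
    be positive and finite; self-loops are rejected.  ``municipality_ids``,
    if given, are added as (possibly isolated) nodes so that every
    municipality of the table appears in the network.
    """
    g = nx.Graph()
    if municipality_ids is not None:
        g.add_nodes_from(municipality_ids)
    for from_id, to_id, minutes in edges[["from_id", "to_id", "minutes"]].itertuples(index=False):
        w = float(minutes)
        if not math.isfinite(w) or w <= 0:
            raise ValueError(f"edge {from_id}-{to_id}: weight must be positive and finite, got {minutes}")
        if from_id == to_id:
            raise ValueError(f"self-loop on node {from_id}")
        g.add_edge(from_id, to_id, minutes=w)
    return g


def read_edge_list(path: str | Path, municipality_ids: list[str] | None = None) -> nx.Graph:
    """Read a travel network from an edge-list CSV or a GraphML file."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        raw = nx.read_graphml(path)
        edges = pd.DataFrame(
            [(u, v, d["minutes"]) for u, v, d in raw.edges(data=True)],
            columns=["from_id", "to_id", "minutes"],
        )
        nodes = list(raw.nodes)
        if municipality_ids is not None:
            nodes = municipality_ids
        return build_network(edges, nodes)
    return build_network(pd.read_csv(path, dtype={"from_id": str, "to_id": str}), municipality_ids)


def shortest_travel_times(net: nx.Graph, origin: str) -> dict[str, float]:
    """Exact shortest-path travel time (minutes) from ``origin`` to every
    reachable municipality.  The origin maps to 0; unreachable nodes are
    absent from the result."""
    if origin not in net:
        raise UnknownLocationError(origin)
    return dict(nx.single_source_dijkstra_path_length(net, origin, weight="minutes"))


@dataclass(frozen=True)
class Catchment:
    """Isochrone membership set around a location municipality.

    ``members`` maps each member municipality to its travel time from the
    location; the location itself is a member at time 0 and every member time
    is at most ``cutoff_minutes``.
    """

    location_id: str
    cutoff_minutes: float
    members: dict[str, float] = field(compare=True)

    def __post_init__(self) -> None:
        if self.members.get(self.location_id) != 0:
            raise ValueError("location must be a member with travel time 0")
        worst = max(self.members.values())
        if worst > self.cutoff_minutes:
            raise ValueError(f"member time {worst} exceeds cutoff {self.cutoff_minutes}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, municipality_id: str) -> bool:
        return municipality_id in self.members

    @property
    def member_ids(self) -> list[str]:
        return sorted(self.members)


def compute_catchment(net: nx.Graph, location: str, cutoff: float) -> Catchment:
    """Municipalities reachable from ``location`` within ``cutoff`` minutes
    (closed boundary: time == cutoff is inside)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    times = nx.single_source_dijkstra_path_length(
        net, location, cutoff=cutoff, weight="minutes"
    ) if location in net else None
    if times is None:
        raise UnknownLocationError(location)
    members = {m: t for m, t in times.items() if t <= cutoff}
    return Catchment(location_id=location, cutoff_minutes=float(cutoff), members=members)


def facility_municipalities(facilities: pd.DataFrame, facility_type: str) -> list[str]:
    """Municipality ids hosting at least one facility of the given type."""
    known = tuple(facilities["facility_type"].unique())
    if facility_type not in known:
        raise UnknownFacilityTypeError(facility_type, known)
    sel = facilities.loc[facilities["facility_type"] == facility_type, "municipality_id"]
    return sorted(set(sel))


def nearest_facility_time(
    net: nx.Graph, location: str, facilities: pd.DataFrame, facility_type: str
) -> float:
    """Minimum travel time from ``location`` to any municipality hosting a
    facility of ``facility_type``; 0 if the location hosts one itself, and
    the missing marker (NaN) if none is reachable."""
    if location not in net:
        raise UnknownLocationError(location)
    hosts = set(facility_municipalities(facilities, facility_type))
    if location in hosts:
        return 0.0
    if not hosts:
        return MISSING
    times = shortest_travel_times(net, location)
    reachable = [times[m] for m in hosts if m in times]
    return min(reachable) if reachable else MISSING


def nearest_facility_times_all(
    net: nx.Graph, facilities: pd.DataFrame, facility_type: str
) -> dict[str, float]:
    """Nearest-facility time for every municipality at once.

    A single multi-source Dijkstra from all hosting municipalities gives the
    same result as per-municipality queries (the network is undirected) at a
    fraction of the cost; used for district/national summaries and batch runs.
    """
    hosts = set(facility_municipalities(facilities, facility_type))
    out = {n: MISSING for n in net.nodes}
    if hosts:
        times = nx.multi_source_dijkstra_path_length(net, hosts & set(net.nodes), weight="minutes")
        out.update(times)
    return out
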