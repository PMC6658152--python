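"""Per-image network descriptors of the weighted vessel graph.

Three sample sets per image, each later histogrammed and compared across a
cohort:

* C-NDD — for every reachable non-central node, the weighted shortest-path
  distance ``d`` to the central node (the optic disc, through which all
  transported blood enters and leaves the network),
* CMWD — the mean link weight along that shortest path, ``d / hops``,
* WDD — every node's strength ``s_i = sum_j w_ij`` (sum of incident link
  weights; with the canonical exponents l=0, a=1 a link's weight is simply
  the vessel width).

The central node is excluded from C-NDD/CMWD (its distance is trivially 0
and its hop-mean undefined); nodes disconnected from the central component
are excluded from the path-based samples but kept in WDD, whose strengths
are purely local.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .vessel_graph import VesselGraph, WeightConfig

__all__ = [
    "DistanceProfile",
    "FeatureSamples",
    "BasicCounts",
    "central_distances",
    "cndd_samples",
    "cmwd_samples",
    "wdd_samples",
    "basic_counts",
]


@dataclass
class DistanceProfile:
    """Weighted distance and hop count to the central node, per node."""

    node_ids: np.ndarray  # reachable non-central nodes
    distances: np.ndarray  # sum of weights along the shortest path
    hops: np.ndarray  # number of links on that path
    unreachable: np.ndarray  # node ids in other components
    central: int
    weight_config: WeightConfig | None = None


@dataclass
class FeatureSamples:
    method: str  # cndd | cmwd | wdd
    values: np.ndarray
    l: float = 0.0
    a: float = 1.0

    @property
    def config_label(self) -> str:
        return f"{self.method}(l={self.l:g},a={self.a:g})"


@dataclass
class BasicCounts:
    nodes: int
    links: int
    endpoints: int
    bifurcations: int

    def as_dict(self) -> dict[str, int]:
        return {
            "nodes": self.nodes,
            "links": self.links,
            "endpoints": self.endpoints,
            "bifurcations": self.bifurcations,
        }


def central_distances(vgraph: VesselGraph) -> DistanceProfile:
    """Exact single-source weighted shortest paths from the central node."""
    if vgraph.central is None:
        raise ValueError("graph has no central node assigned")
    g = vgraph.graph
    dist, paths = nx.single_source_dijkstra(g, vgraph.central, weight="weight")
    ids, ds, hs = [], [], []
    for n in sorted(dist):
        if n == vgraph.central:
            continue
        ids.append(n)
        ds.append(dist[n])
        hs.append(len(paths[n]) - 1)
    unreachable = np.array(sorted(set(g.nodes) - set(dist)), dtype=int)
    return DistanceProfile(
        node_ids=np.array(ids, dtype=int),
        distances=np.array(ds, dtype=float),
        hops=np.array(hs, dtype=int),
        unreachable=unreachable,
        central=vgraph.central,
        weight_config=vgraph.weight_config,
    )


def _cfg(profile_or_graph) -> tuple[float, float]:
    cfg = profile_or_graph.weight_config
    return (cfg.l, cfg.a) if cfg is not None else (np.nan, np.nan)


def cndd_samples(profile: DistanceProfile) -> FeatureSamples:
    """One weighted central distance per reachable non-central node."""
    if len(profile.distances) == 0:
        raise ValueError("no nodes reachable from the central node")
    l, a = _cfg(profile)
    return FeatureSamples("cndd", profile.distances.copy(), l=l, a=a)


def cmwd_samples(profile: DistanceProfile) -> FeatureSamples:
    """Mean link weight along each node's shortest path to the center."""
    if len(profile.distances) == 0:
        raise ValueError("no nodes reachable from the central node")
    l, a = _cfg(profile)
    return FeatureSamples("cmwd", profile.distances / profile.hops, l=l, a=a)


def wdd_samples(vgraph: VesselGraph) -> FeatureSamples:
    """Node strengths s_i = sum of incident link weights (all nodes)."""
    g = vgraph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    strengths = np.array(
        [s for _, s in sorted(g.degree(weight="weight"))], dtype=float
    )
    l, a = _cfg(vgraph)
    return FeatureSamples("wdd", strengths, l=l, a=a)


def basic_counts(vgraph: VesselGraph) -> BasicCounts:
    """Nodes, links, endpoints (degree 1) and bifurcations (degree >= 3)."""
    deg = dict(vgraph.graph.degree())
    return BasicCounts(
        nodes=vgraph.n_nodes,
        links=vgraph.n_links,
        endpoints=sum(1 for d in deg.values() if d == 1),
        bifurcations=sum(1 for d in deg.values() if d >= 3),
    )
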