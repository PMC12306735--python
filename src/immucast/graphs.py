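"""Region adjacency graphs for sub-national (Admin-1) units.

A :class:`RegionGraph` holds the neighbourhood structure used by the
intrinsic-CAR family of spatial priors: nodes are Admin-1 regions tagged
with their country, edges join spatial neighbours.  Synthetic graphs are
rook-adjacency lattices per country, standing in for administrative
boundary polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["RegionGraph", "generate_region_graph", "read_edgelist", "write_edgelist"]


@dataclass(frozen=True)
class RegionGraph:
    """Admin-1 regions with country membership and adjacency.

    Parameters
    ----------
    nodes : list of (region_id, country_id)
        Unique region identifiers with the country each belongs to.
    edges : frozenset of frozenset pairs
        Unordered neighbour pairs; no self-loops.
    """

    nodes: tuple[tuple[str, str], ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [r for r, _ in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        known = set(ids)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not set(pair) <= known:
                raise ValueError(f"edge {pair} references unknown region")

    # -- views -------------------------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return [r for r, _ in self.nodes]

    @property
    def country_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, c in self.nodes:
            seen.setdefault(c)
        return list(seen)

    @property
    def region_country(self) -> pd.Series:
        return pd.Series({r: c for r, c in self.nodes}, name="country")

    @property
    def n_regions(self) -> int:
        return len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for r, c in self.nodes:
            g.add_node(r, country=c)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def components(self) -> list[set[str]]:
        """Connected components (isolated regions are singleton components)."""
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    def subgraph(self, country_id: str) -> "RegionGraph":
        keep = {r for r, c in self.nodes if c == country_id}
        return RegionGraph(
            nodes=tuple((r, c) for r, c in self.nodes if c == country_id),
            edges=frozenset(e for e in self.edges if set(e) <= keep),
        )

    def degrees(self) -> pd.Series:
        g = self.to_networkx()
        return pd.Series({r: g.degree(r) for r in self.region_ids})


def _lattice_shape(m: int) -> tuple[int, int]:
    ncols = int(math.ceil(math.sqrt(m)))
    nrows = int(math.ceil(m / ncols))
    return nrows, ncols


def generate_region_graph(
    n_countries: int,
    regions_per_country: int,
    seed: int = 0,
    cross_border: bool = False,
) -> RegionGraph:
    """Build a multi-country rook-adjacency lattice graph.

    Each country's regions fill a near-square grid row by row, with rook
    (4-neighbour) adjacency, so every country is internally connected.
    With ``cross_border=True`` one edge joins each consecutive country
    pair (mimicking a land border); by default countries are disjoint
    components and cross-country dependence is left to the hierarchical
    country level of the model.
    """
    if n_countries < 1 or regions_per_country < 1:
        raise ValueError("n_countries and regions_per_country must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: list[tuple[str, str]] = []
    edges: set[frozenset] = set()
    nrows, ncols = _lattice_shape(regions_per_country)
    for ci in range(n_countries):
        country = f"C{ci:02d}"
        rid = lambda k: f"{country}_R{k:02d}"  # noqa: E731
        for k in range(regions_per_country):
            nodes.append((rid(k), country))
        for k in range(regions_per_country):
            r, c = divmod(k, ncols)
            right = k + 1
            if c + 1 < ncols and right < regions_per_country:
                edges.add(frozenset((rid(k), rid(right))))
            down = k + ncols
            if r + 1 < nrows and down < regions_per_country:
                edges.add(frozenset((rid(k), rid(down))))
    if cross_border and n_countries > 1:
        for ci in range(n_countries - 1):
            a = rng.integers(regions_per_country)
            b = rng.integers(regions_per_country)
            edges.add(frozenset((f"C{ci:02d}_R{a:02d}", f"C{ci + 1:02d}_R{b:02d}")))
    return RegionGraph(nodes=tuple(nodes), edges=frozenset(edges))


# -- plain-text round trip ----------------------------------------------------

def write_edgelist(graph: RegionGraph, path) -> None:
    """Write nodes (``# region country`` header lines) and edges as text."""
    with open(path, "w") as fh:
        fh.write("# nodes\n")
        for r, c in graph.nodes:
            fh.write(f"node\t{r}\t{c}\n")
        fh.write("# edges\n")
        for e in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"edge\t{e[0]}\t{e[1]}\n")


def read_edgelist(path) -> RegionGraph:
    nodes: list[tuple[str, str]] = []
    edges: set[frozenset] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, *rest = line.split("\t")
            if kind == "node":
                nodes.append((rest[0], rest[1]))
            elif kind == "edge":
                edges.add(frozenset(rest[:2]))
            else:
                raise ValueError(f"unrecognised line in graph file: {line!r}")
    return RegionGraph(nodes=tuple(nodes), edges=frozenset(edges))
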