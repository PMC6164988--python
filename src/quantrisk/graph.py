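"""Areal adjacency structures.

A :class:`RegionGraph` holds the neighbourhood system of the study map:
region labels, symmetric irreflexive neighbour sets ``Omega_i`` and their
cardinalities ``n_i``.  It backs both the intrinsic CAR prior (pairwise
differences over edges) and the ICAR simulator (graph Laplacian).

Readers accept either a two-column edge list or a GAL-style neighbour file
(header with the region count, then alternating ``id degree`` / neighbour
lines).  One-directional edges are auto-symmetrized with a warning; self
loops and references to unknown regions are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["RegionGraph", "make_lattice_graph", "read_adjacency", "write_adjacency"]


@dataclass
class RegionGraph:
    """Symmetric, irreflexive region adjacency.

    ``region_ids`` fixes the ordering used by every array in the package.
    """

    region_ids: list
    neighbors: dict = field(repr=False)

    def __post_init__(self) -> None:
        ids = list(self.region_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        idset = set(ids)
        for i, nb in self.neighbors.items():
            if i not in idset:
                raise ValueError(f"neighbor entry for unknown region {i!r}")
            if i in nb:
                raise ValueError(f"self-loop at region {i!r}")
            for j in nb:
                if j not in idset:
                    raise ValueError(f"region {i!r} lists unknown neighbor {j!r}")
                if i not in self.neighbors.get(j, set()):
                    raise ValueError(f"asymmetric adjacency between {i!r} and {j!r}")
        self.region_ids = ids
        self.neighbors = {i: set(self.neighbors.get(i, set())) for i in ids}

    # -- basic structure ---------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def cardinality(self) -> np.ndarray:
        """Neighbour counts ``n_i`` in region order."""
        return np.array([len(self.neighbors[i]) for i in self.region_ids])

    def index_of(self) -> dict:
        return {r: k for k, r in enumerate(self.region_ids)}

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array of 0-based indices."""
        idx = self.index_of()
        out = sorted(
            (idx[i], idx[j])
            for i in self.region_ids
            for j in self.neighbors[i]
            if idx[i] < idx[j]
        )
        return np.array(out, dtype=int).reshape(-1, 2)

    def adjacency_matrix(self) -> np.ndarray:
        A = np.zeros((self.n_regions, self.n_regions))
        e = self.edges()
        A[e[:, 0], e[:, 1]] = 1.0
        A[e[:, 1], e[:, 0]] = 1.0
        return A

    def laplacian(self) -> np.ndarray:
        A = self.adjacency_matrix()
        return np.diag(A.sum(axis=1)) - A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for i in self.region_ids:
            g.add_edges_from((i, j) for j in self.neighbors[i])
        return g

    def is_connected(self) -> bool:
        if self.n_regions == 0:
            return False
        return nx.is_connected(self.to_networkx())

    def coloring(self) -> list[np.ndarray]:
        """Partition regions into independent sets (greedy graph coloring).

        Within a color class no two regions are neighbours, so elementwise
        Metropolis updates of an ICAR field can run vectorized per class.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        idx = self.index_of()
        ncol = max(colors.values(), default=0) + 1
        classes = [[] for _ in range(ncol)]
        for r, c in colors.items():
            classes[c].append(idx[r])
        return [np.array(sorted(c), dtype=int) for c in classes if c]


def make_lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacency ``rows x cols`` lattice.

    A connected desk-scale surrogate for a real county map; region ids are
    ``"r{i}c{j}"`` in row-major order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    g = nx.grid_2d_graph(rows, cols)
    label = {(i, j): f"r{i}c{j}" for i, j in g.nodes}
    ids = [label[(i, j)] for i in range(rows) for j in range(cols)]
    nbrs = {label[n]: {label[m] for m in g.neighbors(n)} for n in g.nodes}
    return RegionGraph(region_ids=ids, neighbors=nbrs)


def _symmetrize(ids: list, nbrs: dict) -> dict:
    missing = [
        (i, j) for i in ids for j in nbrs.get(i, set()) if i not in nbrs.get(j, set())
    ]
    if missing:
        warnings.warn(
            f"auto-symmetrized {len(missing)} one-directional edge(s)", stacklevel=3
        )
        for i, j in missing:
            nbrs.setdefault(j, set()).add(i)
    return nbrs


def read_adjacency(path) -> RegionGraph:
    """Read an edge-list or GAL-style neighbour file.

    Edge list: one ``id_a id_b`` pair per line ('#' comments allowed).
    GAL: first non-comment line is the region count, then for each region a
    ``id degree`` line followed by one line of neighbour ids (degree 0
    regions may omit the neighbour line or leave it blank).
    """
    with open(path) as fh:
        raw = [ln.strip() for ln in fh]
    lines = [ln for ln in raw if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty adjacency file: {path}")
    head = lines[0].split()
    # GAL headers are "n" alone or the common "0 n [shapefile id]" variant;
    # anything else is an edge list.
    if len(head) == 1 or (head[0] == "0" and len(head) >= 2):
        return _read_gal(lines)
    return _read_edgelist(lines)


def _read_edgelist(lines: list[str]) -> RegionGraph:
    ids: list = []
    nbrs: dict = {}

    def add(r):
        if r not in nbrs:
            nbrs[r] = set()
            ids.append(r)

    for ln in lines:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"edge-list line must have two ids: {ln!r}")
        i, j = parts
        if i == j:
            raise ValueError(f"self-loop rejected: {ln!r}")
        add(i)
        add(j)
        nbrs[i].add(j)
        nbrs[j].add(i)
    return RegionGraph(region_ids=sorted(ids), neighbors=nbrs)


def _read_gal(lines: list[str]) -> RegionGraph:
    head = lines[0].split()
    n = int(head[0]) if len(head) == 1 else int(head[1])
    ids: list = []
    nbrs: dict = {}
    k = 1
    for _ in range(n):
        if k >= len(lines):
            raise ValueError("truncated GAL file")
        rid, deg = lines[k].split()[:2]
        deg = int(deg)
        k += 1
        nb: set = set()
        if deg > 0:
            if k >= len(lines):
                raise ValueError("truncated GAL file")
            nb = set(lines[k].split())
            if len(nb) != deg:
                raise ValueError(f"region {rid!r}: degree {deg} but {len(nb)} neighbors")
            k += 1
        if rid in nb:
            raise ValueError(f"self-loop rejected at region {rid!r}")
        ids.append(rid)
        nbrs[rid] = nb
    unknown = {j for nb in nbrs.values() for j in nb} - set(ids)
    if unknown:
        raise ValueError(f"GAL file references unknown regions: {sorted(unknown)}")
    nbrs = _symmetrize(ids, nbrs)
    return RegionGraph(region_ids=sorted(ids), neighbors=nbrs)


def write_adjacency(graph: RegionGraph, path) -> None:
    """Write the graph as an edge list (one undirected edge per line)."""
    ids = graph.region_ids
    with open(path, "w") as fh:
        fh.write("# edge list\n")
        for a, b in graph.edges():
            fh.write(f"{ids[a]} {ids[b]}\n")
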