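"""Areal lattices: tract identifiers plus a symmetric neighborhood structure.

The lattice is the backbone of every spatial computation in this package:
it stores, for ``n`` areal units (census tracts), the set of adjacent units,
the neighbor counts ``m_i``, and derived linear-algebra objects (adjacency
matrix ``W``, graph Laplacian ``Q = D - W``) used by the intrinsic CAR prior
and by Moran's I.

Tract identifiers are sorted lexicographically once, at construction; every
array in the package follows that fixed order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["TractLattice", "read_adjacency", "make_grid_lattice"]


@dataclass(frozen=True)
class TractLattice:
    """Symmetric neighborhood structure over ``n`` areal units.

    Parameters
    ----------
    tract_ids
        Unique identifiers, lexicographically sorted.
    neighbors
        ``neighbors[i]`` is a sorted integer array of the indices adjacent
        to unit ``i``.  Symmetric, with no self-neighbors.
    """

    tract_ids: tuple[str, ...]
    neighbors: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.tract_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tract ids")
        if list(ids) != sorted(ids):
            raise ValueError("tract_ids must be lexicographically sorted")
        if len(self.neighbors) != len(ids):
            raise ValueError("neighbors length mismatch")
        nbr_sets = [set(a.tolist()) for a in self.neighbors]
        for i, js in enumerate(nbr_sets):
            if i in js:
                raise ValueError(f"self-neighbor at {ids[i]!r}")
            for j in js:
                if not (0 <= j < len(ids)):
                    raise ValueError("neighbor index out of range")
                if i not in nbr_sets[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {ids[i]!r} -> {ids[j]!r}"
                    )

    # -- basic attributes -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.tract_ids)

    @property
    def m(self) -> np.ndarray:
        """Neighbor counts ``m_i``."""
        return np.array([len(a) for a in self.neighbors], dtype=np.int64)

    def index(self, tract_id: str) -> int:
        return self.tract_ids.index(tract_id)

    def isolated(self) -> list[str]:
        """Ids of units with no neighbors."""
        return [t for t, a in zip(self.tract_ids, self.neighbors) if len(a) == 0]

    # -- derived structures ------------------------------------------------

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as index pairs ``(i, j)`` with ``i < j``."""
        out = []
        for i, a in enumerate(self.neighbors):
            out.extend((i, int(j)) for j in a if i < j)
        return out

    def adjacency_matrix(self) -> np.ndarray:
        """Dense binary adjacency matrix ``W``."""
        W = np.zeros((self.n, self.n))
        for i, a in enumerate(self.neighbors):
            W[i, a] = 1.0
        return W

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian ``Q = D - W``, the ICAR precision structure."""
        W = self.adjacency_matrix()
        return np.diag(W.sum(axis=1)) - W

    def neighbor_sum(self, x: np.ndarray) -> np.ndarray:
        """``(Wx)_i``, the sum of ``x`` over each unit's neighbors."""
        x = np.asarray(x, dtype=float)
        return np.array([x[a].sum() for a in self.neighbors])

    def neighbor_mean(self, x: np.ndarray) -> np.ndarray:
        """``s_bar_i``: mean of ``x`` over neighbors (nan for isolates)."""
        m = self.m
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.neighbor_sum(x) / np.where(m > 0, m, np.nan)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_graph())

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper coloring: groups of mutually non-adjacent units.

        Units in a color class have conditionally independent full
        conditionals under a CAR prior and can be updated simultaneously.
        """
        colors = nx.greedy_color(self.to_graph(), strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == cc), dtype=np.int64)
            for cc in range(k)
        ]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        tract_ids: Iterable[str],
        edges: Iterable[tuple[str, str]],
    ) -> "TractLattice":
        """Build a lattice from undirected id pairs.

        Self-pairs raise; edges referencing undeclared ids raise.
        """
        declared = list(tract_ids)
        if len(set(declared)) != len(declared):
            raise ValueError("duplicate tract ids")
        ids = sorted(declared)
        pos = {t: i for i, t in enumerate(ids)}
        nbrs: list[set[int]] = [set() for _ in ids]
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-neighbor edge ({a!r}, {b!r})")
            if a not in pos or b not in pos:
                missing = a if a not in pos else b
                raise ValueError(f"edge references undeclared tract {missing!r}")
            nbrs[pos[a]].add(pos[b])
            nbrs[pos[b]].add(pos[a])
        arrays = tuple(np.array(sorted(s), dtype=np.int64) for s in nbrs)
        return cls(tuple(ids), arrays)


def _read_edge_csv(path: Path) -> list[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"src", "dst"} <= set(reader.fieldnames):
            raise ValueError("edge-list CSV must have header columns src,dst")
        return [(row["src"], row["dst"]) for row in reader]


def _check_direction_convention(
    pairs: Sequence[tuple[str, str]], symmetrize: bool
) -> None:
    """An edge list may list each edge once (undirected convention) or in
    both directions; a mixture is ambiguous and rejected unless the caller
    passes ``symmetrize=True``."""
    seen = set(map(tuple, pairs))
    both = sum((b, a) in seen for a, b in seen)
    if 0 < both < len(seen) and not symmetrize:
        raise ValueError(
            "edge list mixes one-directional and bidirectional entries; "
            "pass symmetrize=True to take the symmetric closure"
        )


def read_adjacency(
    source: str | Path,
    mode: str = "edges",
    tract_ids: Iterable[str] | None = None,
    symmetrize: bool = False,
    id_property: str = "tract_id",
) -> tuple[TractLattice, list[str]]:
    """Read a :class:`TractLattice` from an edge-list CSV or a GeoJSON file.

    Parameters
    ----------
    source
        Path to a ``src,dst`` CSV (``mode="edges"``) or a GeoJSON
        FeatureCollection of tract polygons (``mode="queen-contiguity"`` or
        ``"rook-contiguity"``).
    tract_ids
        Optional explicit universe of ids (lets isolated tracts that appear
        in no edge be declared).
    symmetrize
        Accept edge lists that mix directional conventions by taking the
        symmetric closure.
    id_property
        GeoJSON feature property holding the tract id.

    Returns
    -------
    (lattice, warnings)
        ``warnings`` flags isolated tracts; they are permitted but most
        downstream spatial models require a connected lattice.
    """
    source = Path(source)
    if mode == "edges":
        pairs = _read_edge_csv(source)
        _check_direction_convention(pairs, symmetrize)
        universe = set(tract_ids) if tract_ids is not None else set()
        universe.update(a for a, _ in pairs)
        universe.update(b for _, b in pairs)
        lattice = TractLattice.from_edges(universe, pairs)
    elif mode in ("queen-contiguity", "rook-contiguity", "queen", "rook"):
        lattice = _lattice_from_geojson(source, mode.split("-")[0], id_property)
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    warnings = [f"tract {t!r} has no neighbors" for t in lattice.isolated()]
    return lattice, warnings


def _lattice_from_geojson(path: Path, rule: str, id_property: str) -> TractLattice:
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids, geoms = [], []
    for f in feats:
        try:
            ids.append(str(f["properties"][id_property]))
        except KeyError as e:
            raise ValueError(f"feature missing id property {id_property!r}") from e
        g = shape(f["geometry"])
        if not g.is_valid:
            raise ValueError(f"invalid geometry for tract {ids[-1]!r}")
        geoms.append(g)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tract ids in GeoJSON")
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            inter = geoms[i].intersection(geoms[j])
            if inter.is_empty:
                continue
            # queen: any shared point; rook: shared boundary of dimension >= 1
            if rule == "queen" or inter.length > 0 or inter.area > 0:
                edges.append((ids[i], ids[j]))
    return TractLattice.from_edges(ids, edges)


def make_grid_lattice(rows: int, cols: int, contiguity: str = "rook") -> TractLattice:
    """Regular ``rows x cols`` grid lattice, a stand-in for a real tract map.

    ``rook`` connects horizontal/vertical neighbors (interior ``m_i = 4``);
    ``queen`` adds diagonals (interior ``m_i = 8``).  Ids are zero-padded
    ``r{row}c{col}`` strings so lexicographic order matches grid order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if contiguity not in ("rook", "queen"):
        raise ValueError("contiguity must be 'rook' or 'queen'")
    rw, cw = len(str(rows - 1)), len(str(cols - 1))
    tid = lambda r, c: f"r{r:0{rw}d}c{c:0{cw}d}"  # noqa: E731
    ids = [tid(r, c) for r in range(rows) for c in range(cols)]
    steps = [(0, 1), (1, 0)]
    if contiguity == "queen":
        steps += [(1, 1), (1, -1)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            for dr, dc in steps:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    edges.append((tid(r, c), tid(r2, c2)))
    return TractLattice.from_edges(ids, edges)
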