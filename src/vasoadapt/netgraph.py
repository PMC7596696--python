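"""Graph representation of microvascular networks.

A microvascular network (MVN) is a graph whose edges are blood vessels
(straight-pipe surrogates with a diameter and a length) and whose nodes
are vessel junctions.  Pressure boundary conditions are attached to a
subset of nodes; inflow nodes additionally carry a prescribed inflow
tube haematocrit.

The module also provides a honeycomb-lattice generator (an idealized
capillary bed), plain-CSV persistence, and breadth-first "generation"
labelling of edge shells around an activated vessel set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VascularNetwork",
    "HexagonalLattice",
    "build_hexagonal_network",
    "read_network",
    "write_network",
    "read_activated",
    "write_activated",
    "label_generations",
]


@dataclass
class VascularNetwork:
    """Vascular graph with geometry and boundary conditions.

    Attributes
    ----------
    node_ids : (Nn,) int array of external node identifiers.
    coords : (Nn, 3) float array of positions in µm (NaN when absent).
    boundary : (Nn,) bool mask of boundary nodes.
    pressure : (Nn,) float array, fixed pressure in Pa at boundary
        nodes, NaN elsewhere.
    ht_in : (Nn,) float array, prescribed inflow tube haematocrit at
        inflow boundary nodes, NaN elsewhere.
    edge_ids : (Ne,) int array of external edge identifiers.
    edge_nodes : (Ne, 2) int array of node *indices* (stored
        orientation: signed quantities such as the flow rate refer to
        the first→second direction).
    diameter : (Ne,) float baseline diameters d0 in µm.
    length : (Ne,) float lengths in µm.
    edge_type : (Ne,) object array of optional vessel-type labels.
    """

    node_ids: np.ndarray
    coords: np.ndarray
    boundary: np.ndarray
    pressure: np.ndarray
    ht_in: np.ndarray
    edge_ids: np.ndarray
    edge_nodes: np.ndarray
    diameter: np.ndarray
    length: np.ndarray
    edge_type: np.ndarray

    _node_index: dict = field(default_factory=dict, repr=False)
    _edge_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.ht_in = np.asarray(self.ht_in, dtype=float)
        self.edge_ids = np.asarray(self.edge_ids, dtype=np.int64)
        self.edge_nodes = np.asarray(self.edge_nodes, dtype=np.int64).reshape(-1, 2)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.edge_type = np.asarray(self.edge_type, dtype=object)
        self._node_index = {int(n): i for i, n in enumerate(self.node_ids)}
        self._edge_index = {int(e): i for i, e in enumerate(self.edge_ids)}
        self.validate()

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    def node_index(self, node_id: int) -> int:
        return self._node_index[int(node_id)]

    def edge_index(self, edge_id: int) -> int:
        return self._edge_index[int(edge_id)]

    def edge_indices(self, edge_ids) -> np.ndarray:
        return np.asarray([self._edge_index[int(e)] for e in edge_ids], dtype=np.int64)

    @property
    def fixed_pressure_nodes(self) -> np.ndarray:
        """Indices of nodes with a Dirichlet pressure condition."""
        return np.flatnonzero(self.boundary & np.isfinite(self.pressure))

    @property
    def inflow_ht_nodes(self) -> np.ndarray:
        """Indices of boundary nodes with a prescribed inflow haematocrit."""
        return np.flatnonzero(self.boundary & np.isfinite(self.ht_in) & (self.ht_in > 0))

    def incident_edges(self) -> list[np.ndarray]:
        """Per-node arrays of incident edge indices."""
        incidence: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for e, (i, j) in enumerate(self.edge_nodes):
            incidence[i].append(e)
            incidence[j].append(e)
        return [np.asarray(v, dtype=np.int64) for v in incidence]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edge_nodes[:, 0], 1)
        np.add.at(deg, self.edge_nodes[:, 1], 1)
        return deg

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ne = self.n_edges
        nn = self.n_nodes
        if nn == 0 or ne == 0:
            raise ValueError("network must contain at least one node and one edge")
        if len(np.unique(self.node_ids)) != nn:
            raise ValueError("duplicate node ids")
        if len(np.unique(self.edge_ids)) != ne:
            raise ValueError("duplicate edge ids")
        if np.any(self.edge_nodes < 0) or np.any(self.edge_nodes >= nn):
            bad = np.flatnonzero(
                (self.edge_nodes < 0).any(axis=1) | (self.edge_nodes >= nn).any(axis=1)
            )
            raise ValueError(f"edges reference unknown nodes (rows {bad.tolist()})")
        if np.any(self.edge_nodes[:, 0] == self.edge_nodes[:, 1]):
            bad = np.flatnonzero(self.edge_nodes[:, 0] == self.edge_nodes[:, 1])
            raise ValueError(f"self-loop edges are not allowed (rows {bad.tolist()})")
        if np.any(self.diameter <= 0):
            bad = np.flatnonzero(self.diameter <= 0)
            raise ValueError(f"non-positive diameters (edge rows {bad.tolist()})")
        if np.any(self.length <= 0):
            bad = np.flatnonzero(self.length <= 0)
            raise ValueError(f"non-positive lengths (edge rows {bad.tolist()})")
        fixed = self.fixed_pressure_nodes
        if len(fixed) == 0:
            raise ValueError(
                "at least one boundary node with a fixed pressure is required"
            )
        if not np.all(np.isfinite(self.pressure[fixed])):
            raise ValueError("fixed pressures must be finite")
        ht = self.ht_in[np.isfinite(self.ht_in)]
        if np.any((ht < 0) | (ht >= 1)):
            raise ValueError("inflow tube haematocrit must lie in [0, 1)")
        # connectivity
        adj = coo_matrix(
            (np.ones(ne), (self.edge_nodes[:, 0], self.edge_nodes[:, 1])),
            shape=(nn, nn),
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(f"network is not connected ({n_comp} components)")

    # -- dataframe / file round-trip -----------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x_um": self.coords[:, 0],
                "y_um": self.coords[:, 1],
                "z_um": self.coords[:, 2],
                "is_boundary": self.boundary.astype(int),
                "pressure_pa": self.pressure,
                "ht_in": self.ht_in,
            }
        )
        edges = pd.DataFrame(
            {
                "edge_id": self.edge_ids,
                "node_a": self.node_ids[self.edge_nodes[:, 0]],
                "node_b": self.node_ids[self.edge_nodes[:, 1]],
                "diameter_um": self.diameter,
                "length_um": self.length,
                "type": ["" if t is None else str(t) for t in self.edge_type],
            }
        )
        return nodes, edges

    @classmethod
    def from_frames(
        cls, nodes: pd.DataFrame, edges: pd.DataFrame
    ) -> "VascularNetwork":
        node_cols = {"node_id", "is_boundary", "pressure_pa", "ht_in"}
        edge_cols = {"edge_id", "node_a", "node_b", "diameter_um", "length_um"}
        missing = node_cols - set(nodes.columns)
        if missing:
            raise ValueError(f"node table is missing columns: {sorted(missing)}")
        missing = edge_cols - set(edges.columns)
        if missing:
            raise ValueError(f"edge table is missing columns: {sorted(missing)}")
        node_ids = nodes["node_id"].to_numpy(dtype=np.int64)
        index = {int(n): i for i, n in enumerate(node_ids)}
        coords = np.full((len(node_ids), 3), np.nan)
        for k, col in enumerate(("x_um", "y_um", "z_um")):
            if col in nodes.columns:
                coords[:, k] = pd.to_numeric(nodes[col], errors="coerce").to_numpy()
        edge_nodes = np.empty((len(edges), 2), dtype=np.int64)
        for r, (na, nb) in enumerate(zip(edges["node_a"], edges["node_b"])):
            try:
                edge_nodes[r, 0] = index[int(na)]
                edge_nodes[r, 1] = index[int(nb)]
            except KeyError as err:
                raise ValueError(
                    f"edge table row {r} references unknown node id {err.args[0]}"
                ) from None
        etype = (
            edges["type"].fillna("").astype(str).to_numpy(dtype=object)
            if "type" in edges.columns
            else np.full(len(edges), "", dtype=object)
        )
        return cls(
            node_ids=node_ids,
            coords=coords,
            boundary=pd.to_numeric(nodes["is_boundary"]).to_numpy() != 0,
            pressure=pd.to_numeric(nodes["pressure_pa"], errors="coerce").to_numpy(),
            ht_in=pd.to_numeric(nodes["ht_in"], errors="coerce").to_numpy(),
            edge_ids=edges["edge_id"].to_numpy(dtype=np.int64),
            edge_nodes=edge_nodes,
            diameter=pd.to_numeric(edges["diameter_um"]).to_numpy(dtype=float),
            length=pd.to_numeric(edges["length_um"]).to_numpy(dtype=float),
            edge_type=etype,
        )


def write_network(network: VascularNetwork, nodes_path, edges_path) -> None:
    """Write ``nodes.csv`` / ``edges.csv`` (UTF-8, header row, 10 significant
    digits — the precision to which a round-trip is exact)."""
    nodes, edges = network.to_frames()
    nodes.to_csv(nodes_path, index=False, float_format="%.10g")
    edges.to_csv(edges_path, index=False, float_format="%.10g")


def read_network(nodes_path, edges_path) -> VascularNetwork:
    """Read a network from ``nodes.csv`` / ``edges.csv``."""
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    return VascularNetwork.from_frames(nodes, edges)


def write_activated(edge_ids, path) -> None:
    pd.DataFrame({"edge_id": np.asarray(edge_ids, dtype=np.int64)}).to_csv(
        path, index=False
    )


def read_activated(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "edge_id" not in df.columns:
        raise ValueError("activated table must have an 'edge_id' column")
    return df["edge_id"].to_numpy(dtype=np.int64)


# ---------------------------------------------------------------------------
# Honeycomb lattice generator
# ---------------------------------------------------------------------------


class HexagonalLattice:
    """Planar honeycomb lattice of hexagonal cells, an idealized capillary bed.

    Cells are laid out on an offset grid of ``n_rows`` × ``n_cols``
    pointy-top hexagons with side length ``l`` (every lattice edge is a
    vessel of length ``l`` and baseline diameter ``d0``).  Every
    interior vertex has degree 3.  One inlet and one outlet node on
    opposite lattice sides carry fixed-pressure boundary conditions; the
    inlet additionally carries the inflow tube haematocrit.

    The central "flower" of 7 cells (one cell plus its 6 neighbours)
    provides a 30-edge activated region well separated from the
    boundary.
    """

    def __init__(self, n_rows: int, n_cols: int, d0: float = 4.5, l: float = 75.0):
        if n_rows < 2 or n_cols < 2:
            raise ValueError("lattice needs at least 2 rows and 2 columns of cells")
        if d0 <= 0 or l <= 0:
            raise ValueError("d0 and l must be positive")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.d0 = d0
        self.l = l
        self._build_cells()

    # corners of a pointy-top hexagon, on the half-integer grid
    # (u, v) with x = u * sqrt(3)/2 * l and y = v * l / 2
    _CORNERS = ((1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1))

    def _cell_center(self, row: int, col: int) -> tuple[int, int]:
        # offset rows: odd rows shifted half a cell to the right
        u = 2 * col + (row % 2)
        v = 3 * row
        return u, v

    def _cell_corners(self, row: int, col: int) -> list[tuple[int, int]]:
        cu, cv = self._cell_center(row, col)
        return [(cu + du, cv + dv) for du, dv in self._CORNERS]

    def _build_cells(self) -> None:
        vertex_index: dict[tuple[int, int], int] = {}
        edges: dict[tuple[int, int], int] = {}
        cell_edges: dict[tuple[int, int], list[int]] = {}
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                corners = self._cell_corners(row, col)
                eids = []
                for k in range(6):
                    a, b = corners[k], corners[(k + 1) % 6]
                    for p in (a, b):
                        if p not in vertex_index:
                            vertex_index[p] = len(vertex_index)
                    key = (min(a, b), max(a, b))
                    if key not in edges:
                        edges[key] = len(edges)
                    eids.append(edges[key])
                cell_edges[(row, col)] = eids
        self._vertex_index = vertex_index
        self._edges = edges
        self.cell_edges = cell_edges

    @property
    def n_lattice_nodes(self) -> int:
        return len(self._vertex_index)

    @property
    def n_lattice_edges(self) -> int:
        return len(self._edges)

    def vertex_xy(self) -> np.ndarray:
        xy = np.empty((len(self._vertex_index), 2))
        for (u, v), i in self._vertex_index.items():
            xy[i, 0] = u * math.sqrt(3.0) / 2.0 * self.l
            xy[i, 1] = v * self.l / 2.0
        return xy

    def central_flower_edges(self) -> np.ndarray:
        """Edge ids of the central cell and its 6 neighbours (30 edges)."""
        if self.n_rows < 5 or self.n_cols < 5:
            raise ValueError(
                "lattice too small to contain a centered activated region: "
                "need at least 5x5 cells for the 7-cell central flower"
            )
        row_c, col_c = self.n_rows // 2, self.n_cols // 2
        # neighbours of a cell in offset coordinates (pointy-top, odd rows
        # shifted right)
        if row_c % 2 == 0:
            nbrs = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
        else:
            nbrs = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]
        cells = [(row_c, col_c)] + [(row_c + dr, col_c + dc) for dr, dc in nbrs]
        eids: set[int] = set()
        for cell in cells:
            eids.update(self.cell_edges[cell])
        return np.asarray(sorted(eids), dtype=np.int64)

    def network(
        self,
        pressure_drop: float | None = None,
        outlet_pressure: float = 0.0,
        ht_in: float = 0.3,
        pressure_per_edge: float = 200.0,
    ) -> VascularNetwork:
        """Assemble the :class:`VascularNetwork`.

        The inlet is the left-most vertex and the outlet the right-most
        vertex (ties broken by the lower y).  Dangling degree-1 vertices
        other than the inlet/outlet are trimmed.  When ``pressure_drop``
        is None it defaults to ``pressure_per_edge`` times the graph
        distance (in edges) between inlet and outlet, which yields
        baseline RBC velocities of order 0.5–1 mm/s.
        """
        xy = self.vertex_xy()
        n = len(xy)
        edge_list = sorted(self._edges.items(), key=lambda kv: kv[1])
        enodes = np.asarray(
            [[self._vertex_index[a], self._vertex_index[b]] for (a, b), _ in edge_list],
            dtype=np.int64,
        )
        order = np.lexsort((xy[:, 1], xy[:, 0]))
        inlet = int(order[0])
        outlet = int(order[-1])

        # trim dangling vertices (degree 1), keeping inlet and outlet
        keep_edges = np.ones(len(enodes), dtype=bool)
        while True:
            deg = np.zeros(n, dtype=np.int64)
            np.add.at(deg, enodes[keep_edges, 0], 1)
            np.add.at(deg, enodes[keep_edges, 1], 1)
            dangling = (deg == 1)
            dangling[[inlet, outlet]] = False
            if not dangling.any():
                break
            keep_edges &= ~(dangling[enodes[:, 0]] | dangling[enodes[:, 1]])

        used = np.zeros(n, dtype=bool)
        used[enodes[keep_edges].ravel()] = True
        node_map = -np.ones(n, dtype=np.int64)
        node_map[used] = np.arange(used.sum())
        nn = int(used.sum())

        if pressure_drop is None:
            hops = self._graph_distance(enodes[keep_edges], n, inlet, outlet)
            pressure_drop = pressure_per_edge * hops

        coords = np.full((nn, 3), np.nan)
        coords[:, :2] = xy[used]
        coords[:, 2] = 0.0
        boundary = np.zeros(nn, dtype=bool)
        pressure = np.full(nn, np.nan)
        ht = np.full(nn, np.nan)
        boundary[node_map[inlet]] = boundary[node_map[outlet]] = True
        pressure[node_map[inlet]] = outlet_pressure + pressure_drop
        pressure[node_map[outlet]] = outlet_pressure
        ht[node_map[inlet]] = ht_in

        keep_ids = np.flatnonzero(keep_edges)
        return VascularNetwork(
            node_ids=np.arange(nn),
            coords=coords,
            boundary=boundary,
            pressure=pressure,
            ht_in=ht,
            edge_ids=keep_ids,  # lattice edge ids survive trimming unchanged
            edge_nodes=node_map[enodes[keep_edges]],
            diameter=np.full(len(keep_ids), self.d0),
            length=np.full(len(keep_ids), self.l),
            edge_type=np.full(len(keep_ids), "C", dtype=object),
        )

    @staticmethod
    def _graph_distance(enodes: np.ndarray, n: int, src: int, dst: int) -> int:
        from scipy.sparse.csgraph import shortest_path

        adj = coo_matrix(
            (np.ones(len(enodes)), (enodes[:, 0], enodes[:, 1])), shape=(n, n)
        )
        dist = shortest_path(adj, directed=False, unweighted=True, indices=src)
        d = dist[dst]
        if not np.isfinite(d):
            raise ValueError("inlet and outlet are not connected")
        return int(d)


def build_hexagonal_network(
    n_rows: int,
    n_cols: int,
    d0: float = 4.5,
    l: float = 75.0,
    pressure_drop: float | None = None,
    outlet_pressure: float = 0.0,
    ht_in: float = 0.3,
    with_activated: bool = False,
):
    """Build a honeycomb capillary lattice.

    Returns the :class:`VascularNetwork`, or ``(network, activated_edge_ids)``
    when ``with_activated`` is True (the 30-edge central flower).
    """
    lat = HexagonalLattice(n_rows, n_cols, d0=d0, l=l)
    net = lat.network(
        pressure_drop=pressure_drop, outlet_pressure=outlet_pressure, ht_in=ht_in
    )
    if with_activated:
        return net, lat.central_flower_edges()
    return net


# ---------------------------------------------------------------------------
# Generation labelling
# ---------------------------------------------------------------------------


def label_generations(
    network: VascularNetwork, activated_edge_ids, max_gen: int = 5
) -> np.ndarray:
    """Breadth-first edge-adjacency shells around the activated set.

    Returns a per-edge integer array: 0 for activated ("Gen 0") edges,
    k for the k-th shell of edges sharing a node with the previous
    shell, and -1 for edges farther than ``max_gen`` shells away.
    """
    activated_edge_ids = np.asarray(activated_edge_ids)
    if len(activated_edge_ids) == 0:
        raise ValueError("activated edge set must not be empty")
    act = network.edge_indices(activated_edge_ids)
    labels = np.full(network.n_edges, -1, dtype=np.int64)
    labels[act] = 0
    incident = network.incident_edges()
    frontier = set(act.tolist())
    for gen in range(1, max_gen + 1):
        nodes = {n for e in frontier for n in network.edge_nodes[e]}
        shell = {
            int(e)
            for n in nodes
            for e in incident[n]
            if labels[e] < 0
        }
        if not shell:
            break
        labels[list(shell)] = gen
        frontier = shell
    return labels
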