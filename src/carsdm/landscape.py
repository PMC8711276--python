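"""Gridded covariate stacks, single-layer rasters and cell adjacency.

Rasters are stored row-major with row 0 at the northern edge, and
georeferenced by the lower-left corner plus a square cell size in decimal
degrees, mirroring the ESRI ASCII grid convention used for on-disk exchange.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RasterGrid",
    "CovariateStack",
    "NeighborGraph",
    "build_neighbor_graph",
    "read_ascii_grid",
    "write_ascii_grid",
]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single georeferenced layer; invalid cells are NaN."""

    values: np.ndarray  # (n_rows, n_cols) float
    cell_size_deg: float
    xll: float  # longitude of the lower-left corner, degrees
    yll: float  # latitude of the lower-left corner, degrees

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where the cell holds data)."""
        return np.isfinite(self.values)

    def cell_center_lon(self) -> np.ndarray:
        return self.xll + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg

    def cell_center_lat(self) -> np.ndarray:
        # row 0 is the top (northernmost) row
        top = self.yll + self.n_rows * self.cell_size_deg
        return top - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg

    def rowcol_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); points outside the grid get -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cell_size_deg).astype(int)
        top = self.yll + self.n_rows * self.cell_size_deg
        row = np.floor((top - lat) / self.cell_size_deg).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


@dataclass
class CovariateStack:
    """Aligned continuous predictor layers on a shared grid.

    ``data`` has shape (n_layers, n_rows, n_cols); ``mask`` is True on valid
    cells and is shared by every layer.
    """

    data: np.ndarray
    layer_names: list[str]
    cell_size_deg: float
    xll: float
    yll: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must have shape (layers, rows, cols)")
        if len(self.layer_names) != self.data.shape[0]:
            raise ValueError("layer_names length must match number of layers")
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.data), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match grid shape")

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_cols(self) -> int:
        return self.data.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def grid(self, layer: str | int) -> RasterGrid:
        idx = layer if isinstance(layer, int) else self.layer_names.index(layer)
        vals = self.data[idx].copy()
        vals[~self.mask] = np.nan
        return RasterGrid(vals, self.cell_size_deg, self.xll, self.yll)

    def empty_grid(self) -> RasterGrid:
        vals = np.full((self.n_rows, self.n_cols), np.nan)
        return RasterGrid(vals, self.cell_size_deg, self.xll, self.yll)

    def design_matrix(self, intercept: bool = True) -> np.ndarray:
        """Predictor matrix over valid cells in row-major order."""
        cols = [self.data[i][self.mask] for i in range(self.n_layers)]
        if intercept:
            cols.insert(0, np.ones(self.n_valid))
        return np.column_stack(cols)

    def valid_cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of the centers of valid cells, row-major order."""
        rows, cols = np.nonzero(self.mask)
        g = self.empty_grid()
        return g.cell_center_lon()[cols], g.cell_center_lat()[rows]

    def write_ascii_grids(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self.layer_names:
            p = out_dir / f"{name}.asc"
            write_ascii_grid(self.grid(name), p)
            paths.append(p)
        return paths

    @classmethod
    def read_ascii_grids(cls, in_dir: str | Path, layer_names: list[str] | None = None) -> "CovariateStack":
        in_dir = Path(in_dir)
        if layer_names is None:
            layer_names = sorted(p.stem for p in in_dir.glob("*.asc"))
        grids = [read_ascii_grid(in_dir / f"{n}.asc") for n in layer_names]
        g0 = grids[0]
        for g in grids[1:]:
            if g.values.shape != g0.values.shape:
                raise ValueError("layers disagree on grid shape")
        data = np.stack([g.values for g in grids])
        return cls(data, list(layer_names), g0.cell_size_deg, g0.xll, g0.yll)


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (text, NODATA_value -9999)."""
    vals = np.where(np.isfinite(grid.values), grid.values, _NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.xll!r}\n"
        f"yllcorner {grid.yll!r}\n"
        f"cellsize {grid.cell_size_deg!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    body = "\n".join(" ".join(repr(v) for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    text = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(text) and re.match(r"^[A-Za-z_]", text[i]):
        key, val = text[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    vals = np.loadtxt(text[i:], dtype=float)
    vals = np.atleast_2d(vals)
    nodata = hdr.get("nodata_value", _NODATA)
    vals[vals == nodata] = np.nan
    if vals.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError(f"grid body shape {vals.shape} disagrees with header")
    return RasterGrid(vals, hdr["cellsize"], hdr["xllcorner"], hdr["yllcorner"])


@dataclass
class NeighborGraph:
    """Adjacency over valid raster cells (row-major valid-cell indexing)."""

    n: int
    adjacency: list[np.ndarray]
    rows: np.ndarray  # grid row of each valid cell
    cols: np.ndarray  # grid col of each valid cell

    @property
    def n_j(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency])

    def laplacian(self) -> coo_matrix:
        """Graph Laplacian D - A as a sparse matrix."""
        i = np.concatenate([np.full(len(a), k) for k, a in enumerate(self.adjacency)] or [np.array([], int)])
        j = np.concatenate(self.adjacency or [np.array([], int)])
        off = coo_matrix((-np.ones(len(i)), (i, j)), shape=(self.n, self.n))
        deg = coo_matrix((self.n_j.astype(float), (np.arange(self.n), np.arange(self.n))), shape=(self.n, self.n))
        return (deg + off).tocoo()

    def edges(self) -> list[tuple[int, int]]:
        return [(i, int(j)) for i, a in enumerate(self.adjacency) for j in a if i < j]


_ROOK = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN = _ROOK + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def build_neighbor_graph(
    stack_or_mask: "CovariateStack | np.ndarray",
    scheme: str = "rook",
    keep_largest: bool = False,
) -> NeighborGraph:
    """Build the cell-adjacency graph over valid cells.

    Rook (4-neighbor) adjacency by default, queen (8-neighbor) via
    ``scheme="queen"``. A disconnected valid region raises unless
    ``keep_largest`` is set, in which case all but the largest connected
    component are dropped from the graph.
    """
    mask = stack_or_mask.mask if isinstance(stack_or_mask, CovariateStack) else np.asarray(stack_or_mask, bool)
    if mask.sum() < 1:
        raise ValueError("no valid cells")
    offsets = {"rook": _ROOK, "queen": _QUEEN}.get(scheme)
    if offsets is None:
        raise ValueError(f"unknown adjacency scheme {scheme!r}")

    index = np.full(mask.shape, -1, dtype=int)
    rows, cols = np.nonzero(mask)
    index[rows, cols] = np.arange(len(rows))
    nr, nc = mask.shape
    adjacency = []
    for r, c in zip(rows, cols):
        nbrs = []
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and index[rr, cc] >= 0:
                nbrs.append(index[rr, cc])
        adjacency.append(np.array(sorted(nbrs), dtype=int))

    n = len(rows)
    graph = NeighborGraph(n, adjacency, rows, cols)
    n_comp, labels = _components(graph)
    if n_comp > 1:
        sizes = np.bincount(labels)
        if not keep_largest:
            raise ValueError(
                f"valid region is disconnected: {n_comp} components with sizes "
                f"{sorted(sizes.tolist(), reverse=True)}; pass keep_largest=True to drop the rest"
            )
        keep = labels == int(np.argmax(sizes))
        sub_mask = np.zeros_like(mask)
        sub_mask[rows[keep], cols[keep]] = True
        return build_neighbor_graph(sub_mask, scheme=scheme)
    return graph


def _components(graph: NeighborGraph) -> tuple[int, np.ndarray]:
    lap = graph.laplacian().tocsr()
    adj = -lap.copy()
    adj.setdiag(0)
    adj.eliminate_zeros()
    if graph.n == 1:
        return 1, np.zeros(1, dtype=int)
    return connected_components(adj, directed=False)
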