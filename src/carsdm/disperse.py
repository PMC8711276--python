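"""MigClim-style dispersal-constrained colonization on suitability rasters.

Habitat suitability is carried on an integer 0-1000 scale; cells at or above
the configured threshold are suitable, below it unsuitable. Each step first
decolonizes occupied cells that have become unsuitable, then lets every
unoccupied suitable cell within the short-distance-dispersal radius of an
occupied cell colonize with a distance-indexed kernel probability.
"Strong" barrier cells can never be colonized and are opaque: colonization
distance is a breadth-first (rook) distance through non-barrier cells only.
Long-distance dispersal is deliberately absent. Runs are deterministic given
the config seed; candidate cells consume random draws in row-major order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import RasterGrid

__all__ = [
    "DispersalConfig",
    "DispersalSummary",
    "rescale_suitability",
    "run_dispersal",
    "count_reference_scenarios",
    "pick_best_worst",
]

_NODATA = -1


@dataclass(frozen=True)
class DispersalConfig:
    """Simulation knobs; defaults are the minimal short-distance setting
    (one-cell dispersal with certain colonization, one step per raster)."""

    threshold: int = 500  # on the 0-1000 suitability scale
    kernel: tuple[float, ...] = (1.0,)  # P(colonize) at BFS distance 1, 2, ...
    steps_per_period: int = 1
    barrier: np.ndarray | None = None  # True where dispersal is blocked
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1000:
            raise ValueError("threshold must lie in [0, 1000]")
        k = np.asarray(self.kernel, float)
        if k.size < 1 or np.any((k < 0) | (k > 1)):
            raise ValueError("kernel probabilities must lie in [0, 1]")
        if np.any(np.diff(k) > 0):
            raise ValueError("kernel must be non-increasing with distance")
        if self.steps_per_period < 1:
            raise ValueError("steps_per_period must be >= 1")

    @property
    def sdd_max_dist(self) -> int:
        return len(self.kernel)


@dataclass
class DispersalSummary:
    """The six standard counters of one simulation run."""

    no_dispersal_count: int
    unlimited_dispersal_count: int
    occupied_count: int
    absent_count: int
    total_colonized: int
    total_decolonized: int
    total_cells: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "no_dispersal_count": self.no_dispersal_count,
                    "unlimited_dispersal_count": self.unlimited_dispersal_count,
                    "occupied_count": self.occupied_count,
                    "absent_count": self.absent_count,
                    "total_colonized": self.total_colonized,
                    "total_decolonized": self.total_decolonized,
                }
            ]
        )


def rescale_suitability(suit: RasterGrid | np.ndarray) -> np.ndarray:
    """Probability surface [0, 1] -> integer 0-1000 grid (-1 marks NA)."""
    vals = suit.values if isinstance(suit, RasterGrid) else np.asarray(suit, float)
    finite = np.isfinite(vals)
    if np.any((vals[finite] < 0) | (vals[finite] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    out = np.full(vals.shape, _NODATA, dtype=int)
    out[finite] = np.rint(1000.0 * vals[finite]).astype(int)
    return out


def _as_int_grid(g: RasterGrid | np.ndarray) -> np.ndarray:
    if isinstance(g, RasterGrid):
        vals = g.values
        out = np.full(vals.shape, _NODATA, dtype=int)
        fin = np.isfinite(vals)
        out[fin] = np.rint(vals[fin]).astype(int)
        return out
    return np.asarray(g, dtype=int)


def _bfs_distance(occupied: np.ndarray, passable: np.ndarray, max_dist: int) -> np.ndarray:
    """Multi-source BFS (rook moves) from occupied cells through passable
    cells, truncated at max_dist; unreachable cells get max_dist + 1."""
    nr, nc = occupied.shape
    dist = np.full((nr, nc), max_dist + 1, dtype=int)
    dq: deque[tuple[int, int]] = deque()
    rs, cs = np.nonzero(occupied)
    for r, c in zip(rs, cs):
        dist[r, c] = 0
        dq.append((r, c))
    while dq:
        r, c = dq.popleft()
        d = dist[r, c]
        if d >= max_dist:
            continue
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < nr and 0 <= cc < nc and passable[rr, cc] and dist[rr, cc] > d + 1:
                dist[rr, cc] = d + 1
                dq.append((rr, cc))
    return dist


def _prepare(initial, suit_series, cfg):
    init = _as_int_grid(initial) > 0
    series = [_as_int_grid(s) for s in suit_series]
    if not series:
        raise ValueError("suitability series is empty")
    shape = init.shape
    for s in series:
        if s.shape != shape:
            raise ValueError("suitability grids are not aligned with the initial map")
    barrier = (
        np.zeros(shape, bool) if cfg.barrier is None else np.asarray(cfg.barrier, bool)
    )
    if barrier.shape != shape:
        raise ValueError("barrier mask is not aligned")
    valid = series[0] != _NODATA
    init = init & valid & ~barrier
    return init, series, barrier, valid


def run_dispersal(
    initial: RasterGrid | np.ndarray,
    suit_series: list[RasterGrid | np.ndarray],
    cfg: DispersalConfig,
) -> tuple[np.ndarray, DispersalSummary, pd.DataFrame]:
    """Run the colonization simulation over a time-ordered suitability series.

    Returns the final occupied boolean grid, the six-counter summary, and a
    per-step log. Decolonized cells may recolonize if they become suitable
    again; barrier cells neither colonize nor transmit.
    """
    init, series, barrier, valid = _prepare(initial, suit_series, cfg)
    occupied = init.copy()
    rng = np.random.default_rng(cfg.seed)
    total_col = 0
    total_dec = 0
    log_rows = []
    step_no = 0
    for period, suit in enumerate(series):
        suitable = (suit >= cfg.threshold) & valid
        for _ in range(cfg.steps_per_period):
            step_no += 1
            # 1. decolonize cells no longer suitable
            dec = occupied & ~suitable
            n_dec = int(dec.sum())
            occupied &= suitable
            # 2. colonize suitable unoccupied cells near occupied ones
            dist = _bfs_distance(occupied, ~barrier, cfg.sdd_max_dist)
            cand = (~occupied) & suitable & ~barrier & (dist >= 1) & (dist <= cfg.sdd_max_dist)
            rows, cols = np.nonzero(cand)  # row-major order
            n_col = 0
            for r, c in zip(rows, cols):
                p = cfg.kernel[dist[r, c] - 1]
                if rng.random() < p:
                    occupied[r, c] = True
                    n_col += 1
            total_col += n_col
            total_dec += n_dec
            log_rows.append(
                {
                    "step": step_no,
                    "period": period,
                    "occupied": int(occupied.sum()),
                    "colonized": n_col,
                    "decolonized": n_dec,
                }
            )

    no_disp, unlim = count_reference_scenarios(init, series, cfg)
    n_total = int(valid.sum())
    summary = DispersalSummary(
        no_dispersal_count=no_disp,
        unlimited_dispersal_count=unlim,
        occupied_count=int(occupied.sum()),
        absent_count=n_total - int(occupied.sum()),
        total_colonized=total_col,
        total_decolonized=total_dec,
        total_cells=n_total,
    )
    return occupied, summary, pd.DataFrame(log_rows)


def count_reference_scenarios(
    initial: RasterGrid | np.ndarray,
    suit_series: list[RasterGrid | np.ndarray],
    cfg: DispersalConfig,
) -> tuple[int, int]:
    """(no-dispersal, unlimited-dispersal) cell counts at the final period.

    No dispersal: initially occupied cells that stay suitable through every
    period (without dispersal a cell lost to unsuitability cannot be
    regained, so survival requires suitability throughout).
    Unlimited dispersal: every suitable non-barrier cell at the end.
    """
    init, series, barrier, valid = _prepare(initial, suit_series, cfg)
    always_suitable = valid.copy()
    for s in series:
        always_suitable &= s >= cfg.threshold
    final_suitable = (series[-1] >= cfg.threshold) & valid
    no_disp = int((init & always_suitable).sum())
    unlim = int((final_suitable & ~barrier).sum())
    return no_disp, unlim


def pick_best_worst(summaries: list[DispersalSummary]) -> tuple[int, int]:
    """Best / worst scenario indices under the lexicographic rule:
    most occupied, then fewest absent, then largest unlimited-dispersal,
    then largest no-dispersal count; worst is the reverse ordering.
    Ties return the lowest index."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to rank")

    def key(s: DispersalSummary):
        return (
            -s.occupied_count,
            s.absent_count,
            -s.unlimited_dispersal_count,
            -s.no_dispersal_count,
        )

    order = sorted(range(len(summaries)), key=lambda i: (key(summaries[i]), i))
    rev = sorted(range(len(summaries)), key=lambda i: (tuple(-v for v in key(summaries[i])), i))
    return order[0], rev[0]
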