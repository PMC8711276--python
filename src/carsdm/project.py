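"""Projection of the fitted occupancy surface, max-SSS binarization,
change classification and equal-area accounting.

Future suitability is the posterior median of inverse-logit(X beta + rho)
on a (possibly reduced) covariate stack; the continuous surface is
binarized at the threshold that maximizes sensitivity + specificity
(max SSS) against the observed presence/background vector; present and
future binary maps are cross-classified into gain / loss / no-change /
no-occupancy, and areas are accumulated in km^2 under a South American
Albers equal-area conic projection (spherical formulas, mean Earth radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icar import IcarFit
from .landscape import CovariateStack, RasterGrid
from .screen import EARTH_RADIUS_KM

__all__ = [
    "NO_OCCUPANCY",
    "GAIN",
    "LOSS",
    "NO_CHANGE",
    "CHANGE_LABELS",
    "AlbersParams",
    "predict_suitability",
    "max_sss_threshold",
    "binarize",
    "classify_change",
    "albers_xy",
    "cell_areas_km2",
    "area_km2",
]

NO_OCCUPANCY, GAIN, LOSS, NO_CHANGE = 0, 1, 2, 3
CHANGE_LABELS = {
    NO_OCCUPANCY: "no_occupancy",
    GAIN: "gain",
    LOSS: "loss",
    NO_CHANGE: "no_change",
}


def predict_suitability(
    fit: IcarFit,
    stack: CovariateStack,
    spatial_effect: str = "reuse",
    allow_dropped: bool = False,
) -> RasterGrid:
    """Posterior-median presence-probability surface on ``stack``.

    Stack layers are matched to fit coefficients by name. Coefficients with
    no matching layer (e.g. anthropogenic predictors with no future
    projection) are zeroed only when ``allow_dropped`` is set, otherwise the
    call errors. ``spatial_effect="reuse"`` adds the fitted rho draws
    (requires the fitting grid); ``"zero"`` omits them, which is the
    default-documented behavior for novel grids.
    """
    coef_cov = fit.coef_names[1:]  # intercept first by contract
    missing_coefs = [c for c in coef_cov if c not in stack.layer_names]
    unknown_layers = [l for l in stack.layer_names if l not in coef_cov]
    if unknown_layers:
        raise ValueError(f"stack layers not among fit coefficients: {unknown_layers}")
    if missing_coefs and not allow_dropped:
        raise ValueError(
            f"fit coefficients with no stack layer: {missing_coefs}; "
            "pass allow_dropped=True to zero them"
        )
    if spatial_effect not in ("reuse", "zero"):
        raise ValueError("spatial_effect must be 'reuse' or 'zero'")

    n = stack.n_valid
    cols = [np.ones(n)]
    beta_idx = [0]
    for j, c in enumerate(coef_cov, start=1):
        if c in stack.layer_names:
            cols.append(stack.data[stack.layer_names.index(c)][stack.mask])
            beta_idx.append(j)
    Xs = np.column_stack(cols)
    B = fit.beta_draws[:, beta_idx]  # (draws, kept coefs)

    psi = B @ Xs.T  # (draws, cells)
    if spatial_effect == "reuse":
        if fit.rho.shape[-1] != n:
            raise ValueError(
                "spatial_effect='reuse' needs the fitting grid "
                f"({fit.rho.shape[-1]} cells != {n} valid cells)"
            )
        psi = psi + fit.rho_draws
    prob = 1.0 / (1.0 + np.exp(-psi))
    med = np.median(prob, axis=0)
    grid = stack.empty_grid()
    grid.values[stack.mask] = med
    return grid


def max_sss_threshold(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; classification is
    ``score >= t``. Ties are broken toward the smallest threshold (the more
    inclusive predicted range). Returns (threshold, max sens+spec).
    """
    scores = np.asarray(scores, float).ravel()
    y = np.asarray(y, float).ravel()
    if scores.size != y.size:
        raise ValueError("scores and y differ in length")
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in y")
    best_t, best_v = None, -np.inf
    for t in np.unique(scores):  # ascending, so first max is the smallest t
        pred = scores >= t
        sens = np.count_nonzero(pred & pos) / n_pos
        spec = np.count_nonzero(~pred & ~pos) / n_neg
        if sens + spec > best_v + 1e-12:
            best_v = sens + spec
            best_t = float(t)
    return best_t, float(best_v)


def binarize(suit: RasterGrid, threshold: float) -> RasterGrid:
    """Presence (1) where suitability >= threshold, absence (0) below; NA kept."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = np.where(np.isfinite(suit.values), (suit.values >= threshold).astype(float), np.nan)
    return RasterGrid(vals, suit.cell_size_deg, suit.xll, suit.yll)


def _check_same_grid(a: RasterGrid, b: RasterGrid) -> None:
    if a.values.shape != b.values.shape or a.cell_size_deg != b.cell_size_deg or (
        a.xll,
        a.yll,
    ) != (b.xll, b.yll):
        raise ValueError("grids are not aligned")


def classify_change(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Cross-classify two binary maps into the four change categories."""
    _check_same_grid(current, future)
    c, f = current.values, future.values
    out = np.full(c.shape, np.nan)
    valid = np.isfinite(c) & np.isfinite(f)
    code = np.where(
        (c == 0) & (f == 1),
        GAIN,
        np.where((c == 1) & (f == 0), LOSS, np.where((c == 1) & (f == 1), NO_CHANGE, NO_OCCUPANCY)),
    )
    out[valid] = code[valid]
    return RasterGrid(out, current.cell_size_deg, current.xll, current.yll)


@dataclass(frozen=True)
class AlbersParams:
    """South American Albers equal-area conic (spherical form).

    Defaults: central meridian -60, latitude of origin -32, standard
    parallels -5 and -42 (the common South America parameter set).
    """

    lon0: float = -60.0
    lat0: float = -32.0
    sp1: float = -5.0
    sp2: float = -42.0
    radius_km: float = EARTH_RADIUS_KM


def albers_xy(lon, lat, params: AlbersParams = AlbersParams()) -> tuple[np.ndarray, np.ndarray]:
    """Forward Albers equal-area conic projection (km)."""
    lon = np.radians(np.asarray(lon, float))
    lat = np.radians(np.asarray(lat, float))
    lon0, lat0 = np.radians(params.lon0), np.radians(params.lat0)
    phi1, phi2 = np.radians(params.sp1), np.radians(params.sp2)
    n = (np.sin(phi1) + np.sin(phi2)) / 2.0
    C = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
    rho = params.radius_km / n * np.sqrt(C - 2.0 * n * np.sin(lat))
    rho0 = params.radius_km / n * np.sqrt(C - 2.0 * n * np.sin(lat0))
    theta = n * (lon - lon0)
    return rho * np.sin(theta), rho0 - rho * np.cos(theta)


def cell_areas_km2(grid: RasterGrid, params: AlbersParams = AlbersParams()) -> np.ndarray:
    """Projected area of every cell (km^2), via the shoelace formula on the
    Albers-projected cell corners."""
    cs = grid.cell_size_deg
    lon_edges = grid.xll + np.arange(grid.n_cols + 1) * cs
    lat_top = grid.yll + grid.n_rows * cs
    lat_edges = lat_top - np.arange(grid.n_rows + 1) * cs
    LON, LAT = np.meshgrid(lon_edges, lat_edges)
    x, y = albers_xy(LON, LAT, params)
    # corners per cell: (r,c), (r,c+1), (r+1,c+1), (r+1,c)
    x00, y00 = x[:-1, :-1], y[:-1, :-1]
    x01, y01 = x[:-1, 1:], y[:-1, 1:]
    x11, y11 = x[1:, 1:], y[1:, 1:]
    x10, y10 = x[1:, :-1], y[1:, :-1]
    area = 0.5 * np.abs(
        x00 * y01 - x01 * y00 + x01 * y11 - x11 * y01 + x11 * y10 - x10 * y11 + x10 * y00 - x00 * y10
    )
    return area


def area_km2(
    grid: RasterGrid,
    params: AlbersParams = AlbersParams(),
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-category cell counts and km^2 areas of a categorical raster."""
    vals = grid.values
    if not np.isfinite([grid.cell_size_deg, grid.xll, grid.yll]).all():
        raise ValueError("grid is not georeferenced")
    areas = cell_areas_km2(grid, params)
    valid = np.isfinite(vals)
    cats = np.unique(vals[valid]).astype(int)
    rows = []
    for cat in cats:
        sel = valid & (vals == cat)
        rows.append(
            {
                "category": labels.get(cat, str(cat)) if labels else str(cat),
                "code": int(cat),
                "cell_count": int(sel.sum()),
                "area_km2": float(areas[sel].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["projection"] = params
    return out
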