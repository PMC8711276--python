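"""Occurrence thinning and predictor collinearity screening.

Spatial thinning enforces a minimum great-circle distance between retained
records (greedy, first-come retention in input order — the retained count is
therefore order-dependent). Collinearity is screened by the variance
inflation factor, VIF_j = 1 / (1 - R_j^2), with stepwise elimination of the
worst predictor until every VIF falls below the threshold (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "thin_occurrences",
    "VifReport",
    "vif",
    "select_predictors",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

_EXACT_R2_TOL = 1e-10  # R^2 above 1 - tol counts as exact collinearity


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _validate_coords(occ: pd.DataFrame) -> None:
    lon = occ["lon"].to_numpy(float)
    lat = occ["lat"].to_numpy(float)
    bad = np.nonzero(~(np.isfinite(lon) & np.isfinite(lat) & (np.abs(lon) <= 180) & (np.abs(lat) <= 90)))[0]
    if len(bad):
        raise ValueError(f"invalid coordinates at rows {bad.tolist()}")


def thin_occurrences(occ: pd.DataFrame, min_dist_km: float) -> pd.DataFrame:
    """Greedy spatial filter: keep a record iff it is at least
    ``min_dist_km`` from every already-kept record (input order preserved)."""
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be > 0")
    _validate_coords(occ)
    lon = occ["lon"].to_numpy(float)
    lat = occ["lat"].to_numpy(float)
    kept: list[int] = []
    for i in range(len(occ)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lon[kept], lat[kept], lon[i], lat[i])
        if np.all(d >= min_dist_km):
            kept.append(i)
    return occ.iloc[kept].reset_index(drop=True)


@dataclass
class VifReport:
    """Per-predictor VIFs plus the retained set under a threshold."""

    vifs: dict[str, float]  # inf flags exact collinearity
    retained: list[str]
    dropped: list[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.vifs),
                "vif": list(self.vifs.values()),
                "retained": [n in self.retained for n in self.vifs],
            }
        )


def _vif_values(X: np.ndarray, names: list[str]) -> dict[str, float]:
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictor columns")
    if n <= p:
        raise ValueError(f"VIF needs more rows ({n}) than columns ({p})")
    sd = X.std(axis=0)
    const = [names[j] for j in range(p) if sd[j] == 0]
    if const:
        raise ValueError(f"constant columns have undefined VIF: {const}")
    out = {}
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[names[j]] = np.inf if r2 > 1.0 - _EXACT_R2_TOL else 1.0 / (1.0 - r2)
    return out


def vif(design: pd.DataFrame | np.ndarray, names: list[str] | None = None, threshold: float = 10.0) -> VifReport:
    """Variance inflation factors for a predictor matrix.

    Exactly collinear columns are flagged with ``inf`` (undefined VIF).
    The ``retained`` list contains the predictors already below the
    threshold; no elimination is performed here (see
    :func:`select_predictors`).
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
        names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    vals = _vif_values(X, names)
    retained = [nm for nm, v in vals.items() if v < threshold]
    dropped = [nm for nm in vals if nm not in retained]
    return VifReport(vals, retained, dropped, threshold)


def select_predictors(
    design: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
    threshold: float = 10.0,
) -> VifReport:
    """Stepwise VIF elimination: drop the worst predictor, recompute, repeat
    until every remaining VIF is below the threshold. Ties on the maximum
    VIF drop the later column (stable for duplicated predictors)."""
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
        names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    current = list(names)
    Xc = X.copy()
    drop_sequence: list[str] = []
    vals = _vif_values(Xc, current)
    while max(vals.values()) >= threshold and len(current) > 2:
        worst = max(range(len(current)), key=lambda j: (vals[current[j]], j))
        drop_sequence.append(current[worst])
        del current[worst]
        Xc = np.delete(Xc, worst, axis=1)
        vals = _vif_values(Xc, current)
    if max(vals.values()) >= threshold and len(current) == 2:
        # a perfectly collinear final pair cannot be resolved symmetrically;
        # drop the second member
        drop_sequence.append(current[1])
        current = current[:1]
        vals = {current[0]: 1.0}
    return VifReport(vals, list(current), drop_sequence, threshold)
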