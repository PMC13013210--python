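"""Station-to-surface interpolation with an elevation covariate.

Regression-kriging: an ordinary-least-squares drift on elevation (the
lapse rate, for temperature) plus ordinary kriging of the residuals
under a fitted variogram model. The covariate lets the surface track
topography in areas with sparse station coverage — the reason an
elevation-aware interpolator beats plain distance-weighting in
mountainous terrain.

Distances are planar in the working CRS; geographic (lon/lat) rasters
must be projected before interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import enum

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .grid import Grid, _is_geographic

__all__ = [
    "StationRecord",
    "DriftModel",
    "VariogramEstimate",
    "VariogramModel",
    "VariogramKind",
    "KrigingResult",
    "InterpolationConfig",
    "DegenerateDesignError",
    "fit_drift",
    "empirical_variogram",
    "fit_variogram",
    "krige_point",
    "interpolate_surface",
    "leave_one_out",
    "dedupe_stations",
    "load_stations_csv",
]


class DegenerateDesignError(ValueError):
    """Too few stations, or no elevation contrast, for the drift fit."""


@dataclass(frozen=True)
class StationRecord:
    """One point observation: map coordinates, elevation (m), value."""

    x: float
    y: float
    elevation: float
    value: float

    def __post_init__(self):
        if not all(np.isfinite([self.x, self.y, self.elevation, self.value])):
            raise ValueError(f"non-finite station record: {self}")


@dataclass(frozen=True)
class DriftModel:
    """Linear trend value = intercept + elevation_coef * elevation."""

    intercept: float
    elevation_coef: float

    def predict(self, elevation):
        return self.intercept + self.elevation_coef * np.asarray(elevation, dtype=float)


@dataclass(frozen=True)
class VariogramEstimate:
    """Binned Matheron semivariogram: gamma(h) per distance lag."""

    lag_centers: np.ndarray
    semivariances: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray


class VariogramKind(enum.Enum):
    SPHERICAL = "spherical"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram: nugget + partial sill saturating at range.

    ``range_param`` is the correlation length for exponential/gaussian
    kinds (gamma reaches ~95% of the sill near 3x / 1.7x that length) and
    the exact range for the spherical kind. gamma(0) = 0 by convention.
    """

    kind: VariogramKind
    nugget: float
    partial_sill: float
    range_param: float

    def __post_init__(self):
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ValueError("variogram parameters must be nonnegative (range > 0)")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        r = self.range_param
        if self.kind is VariogramKind.SPHERICAL:
            hn = np.minimum(h / r, 1.0)
            struct = 1.5 * hn - 0.5 * hn**3
        elif self.kind is VariogramKind.EXPONENTIAL:
            struct = 1.0 - np.exp(-h / r)
        else:  # GAUSSIAN
            struct = 1.0 - np.exp(-((h / r) ** 2))
        gamma = np.where(h > 0.0, self.nugget + self.partial_sill * struct, 0.0)
        return gamma if gamma.ndim else float(gamma)


@dataclass(frozen=True)
class KrigingResult:
    prediction: float
    variance: float
    weights: np.ndarray


@dataclass
class InterpolationConfig:
    """Knobs for the interpolation pipeline.

    Defaults: exponential variogram, 12 lags out to half the domain
    diagonal, 16-nearest-station neighborhood (global solve when the
    network is that small), elevation drift on for both temperature and
    humidity.
    """

    variogram_kind: VariogramKind = VariogramKind.EXPONENTIAL
    n_lags: int = 12
    max_dist: float | None = None  # default: half the station-domain diagonal
    neighborhood: int = 16
    use_elevation_drift: bool = True


def dedupe_stations(stations: list[StationRecord]) -> list[StationRecord]:
    """Average records sharing exact coordinates (with a warning)."""
    seen: dict[tuple[float, float], list[StationRecord]] = {}
    for s in stations:
        seen.setdefault((s.x, s.y), []).append(s)
    if len(seen) == len(stations):
        return list(stations)
    warnings.warn(
        f"{len(stations) - len(seen)} duplicate station coordinate(s) averaged",
        stacklevel=2,
    )
    return [
        StationRecord(x, y, float(np.mean([s.elevation for s in grp])),
                      float(np.mean([s.value for s in grp])))
        for (x, y), grp in seen.items()
    ]


def fit_drift(stations: list[StationRecord]) -> tuple[DriftModel, np.ndarray]:
    """OLS fit of value ~ intercept + coef * elevation; returns residuals too."""
    if len(stations) < 3:
        raise DegenerateDesignError(f"need >= 3 stations to fit a drift, got {len(stations)}")
    elev = np.array([s.elevation for s in stations])
    vals = np.array([s.value for s in stations])
    if np.ptp(elev) == 0.0:
        raise DegenerateDesignError("all stations at the same elevation; drift is unidentifiable")
    design = np.column_stack([np.ones_like(elev), elev])
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    model = DriftModel(float(coef[0]), float(coef[1]))
    return model, vals - design @ coef


def _coords(stations) -> np.ndarray:
    return np.array([(s.x, s.y) for s in stations], dtype=float)


def empirical_variogram(
    stations: list[StationRecord],
    residuals: np.ndarray,
    n_lags: int = 12,
    max_dist: float | None = None,
) -> VariogramEstimate:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)), binned.

    Empty bins are retained with count 0 and NaN semivariance.
    """
    xy = _coords(stations)
    z = np.asarray(residuals, dtype=float)
    iu, ju = np.triu_indices(len(xy), k=1)
    d = np.hypot(*(xy[iu] - xy[ju]).T)
    if max_dist is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        max_dist = float(np.hypot(*span)) / 2.0
    keep = d <= max_dist
    if not keep.any():
        raise ValueError("no station pairs within max_dist")
    d, sq = d[keep], 0.5 * (z[iu] - z[ju])[keep] ** 2
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    counts = np.bincount(which, minlength=n_lags)
    sums = np.bincount(which, weights=sq, minlength=n_lags)
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramEstimate(centers, gamma, counts)


def fit_variogram(
    est: VariogramEstimate,
    kind: VariogramKind = VariogramKind.EXPONENTIAL,
) -> VariogramModel:
    """Weighted least squares (weights = pair counts) over nugget, partial
    sill and range, with nonnegativity enforced by bounded optimisation."""
    ok = (est.pair_counts > 0) & np.isfinite(est.semivariances)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 non-empty lag bins to fit a variogram, got {int(ok.sum())}")
    h = est.lag_centers[ok]
    g = est.semivariances[ok]
    w = np.sqrt(est.pair_counts[ok].astype(float))
    if np.allclose(g, 0.0):
        # pure drift: no residual spatial structure
        return VariogramModel(kind, 0.0, 0.0, float(h.max()))

    def resid(p):
        m = VariogramModel(kind, p[0], p[1], p[2])
        return w * (m(h) - g)

    sill0 = float(np.nanmean(g[-max(1, len(g) // 3):]))
    x0 = [min(g[0], sill0) * 0.1, max(sill0, 1e-12), max(h.max() / 3.0, 1e-9)]
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"variogram fit failed: {sol.message}; last iterate {sol.x}")
    return VariogramModel(kind, float(sol.x[0]), float(sol.x[1]), float(sol.x[2]))


def _ok_system(xy: np.ndarray, model: VariogramModel) -> np.ndarray:
    """(n+1)x(n+1) ordinary-kriging matrix with Lagrange row/column."""
    n = len(xy)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model(d)
    a[n, :n] = a[:n, n] = 1.0
    a[n, n] = 0.0
    return a


def krige_point(
    target: tuple[float, float],
    stations: list[StationRecord],
    residuals: np.ndarray,
    model: VariogramModel,
    neighborhood: int = 16,
) -> KrigingResult:
    """Ordinary-kriging prediction of the residual field at one point.

    Solves the (n+1)-equation system over the ``neighborhood`` nearest
    stations; the Lagrange multiplier enforces unit-sum weights. With a
    zero nugget the predictor is exact at station locations.
    """
    xy = _coords(stations)
    z = np.asarray(residuals, dtype=float)
    if len(xy) < 2:
        raise ValueError("kriging needs at least 2 stations")
    if len(np.unique(xy, axis=0)) != len(xy):
        dupes = [tuple(c) for c, n in zip(*np.unique(xy, axis=0, return_counts=True)) if n > 1]
        raise ValueError(f"duplicate station coordinates {dupes}; dedupe_stations() first")
    if len(xy) > neighborhood:
        _, idx = cKDTree(xy).query(np.asarray(target, dtype=float), k=neighborhood)
        xy, z = xy[idx], z[idx]
    n = len(xy)
    a = _ok_system(xy, model)
    b = np.empty(n + 1)
    b[:n] = model(np.hypot(*(xy - np.asarray(target, dtype=float)).T))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular kriging system at target {target}: {exc}") from exc
    w = sol[:n]
    pred = float(w @ z)
    var = float(max(b[:n] @ w + sol[n], 0.0))
    return KrigingResult(pred, var, w)


def _krige_grid(
    xy: np.ndarray,
    z: np.ndarray,
    targets: np.ndarray,
    model: VariogramModel,
    neighborhood: int,
) -> np.ndarray:
    """Vectorized residual kriging at many targets (batched solves)."""
    n = len(xy)
    if model.partial_sill == 0.0 and model.nugget == 0.0:
        return np.zeros(len(targets))
    if n <= neighborhood:
        a = _ok_system(xy, model)
        d = np.hypot(*(targets[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        b = np.concatenate([model(d), np.ones((len(targets), 1))], axis=1)
        sol = np.linalg.solve(a, b.T).T  # (m, n+1)
        return sol[:, :n] @ z
    tree = cKDTree(xy)
    _, idx = tree.query(targets, k=neighborhood)  # (m, k)
    k = neighborhood
    nb = xy[idx]  # (m, k, 2)
    dmat = np.linalg.norm(nb[:, :, None, :] - nb[:, None, :, :], axis=-1)
    a = np.empty((len(targets), k + 1, k + 1))
    a[:, :k, :k] = model(dmat)
    a[:, k, :k] = a[:, :k, k] = 1.0
    a[:, k, k] = 0.0
    b = np.empty((len(targets), k + 1))
    b[:, :k] = model(np.linalg.norm(nb - targets[:, None, :], axis=-1))
    b[:, k] = 1.0
    sol = np.linalg.solve(a, b[..., None])[..., 0]
    return np.einsum("mk,mk->m", sol[:, :k], z[idx])


def interpolate_surface(
    stations: list[StationRecord],
    dem: Grid,
    config: InterpolationConfig | None = None,
) -> Grid:
    """Regression-kriged surface on the DEM's grid.

    Output = drift(DEM elevation) + ordinary-kriged residual surface;
    nodata wherever the DEM is nodata. Values are stored float32 (the
    raster storage dtype) so in-memory and file-based pipelines agree
    exactly.
    """
    config = config or InterpolationConfig()
    if _is_geographic(dem.crs):
        raise ValueError(
            f"DEM CRS {dem.crs!r} looks geographic; project to planar coordinates first"
        )
    stations = dedupe_stations(stations)
    x0, px, _, y0, _, py = dem.transform
    xs = np.array([s.x for s in stations])
    ys = np.array([s.y for s in stations])
    rows, cols = dem.shape
    inside = (
        (xs >= x0) & (xs <= x0 + cols * px)
        & (ys <= y0) & (ys >= y0 + rows * py)
    )
    if not inside.any():
        raise ValueError("all stations fall outside the DEM bounds")

    if config.use_elevation_drift:
        drift, resid = fit_drift(stations)
    else:
        vals = np.array([s.value for s in stations])
        drift = DriftModel(float(vals.mean()), 0.0)
        resid = vals - vals.mean()

    if np.allclose(resid, 0.0):
        model = VariogramModel(config.variogram_kind, 0.0, 0.0, 1.0)
    else:
        est = empirical_variogram(stations, resid, config.n_lags, config.max_dist)
        model = fit_variogram(est, config.variogram_kind)

    valid = dem.valid_mask
    cx, cy = dem.cell_centers()
    targets = np.column_stack([cx[valid], cy[valid]])
    xy = _coords(stations)
    kriged = _krige_grid(xy, np.asarray(resid), targets, model, config.neighborhood)

    out = np.full(dem.shape, -9999.0)
    out[valid] = drift.predict(dem.values[valid]) + kriged
    return Grid(out.astype(np.float32), dem.transform, dem.crs, nodata=-9999.0)


def leave_one_out(
    stations: list[StationRecord],
    config: InterpolationConfig | None = None,
) -> np.ndarray:
    """Leave-one-out predictions at every station (diagnostic helper)."""
    config = config or InterpolationConfig()
    preds = np.empty(len(stations))
    for i in range(len(stations)):
        rest = stations[:i] + stations[i + 1:]
        if config.use_elevation_drift:
            drift, resid = fit_drift(rest)
        else:
            v = np.array([s.value for s in rest])
            drift, resid = DriftModel(float(v.mean()), 0.0), v - v.mean()
        est = empirical_variogram(rest, resid, config.n_lags, config.max_dist)
        model = fit_variogram(est, config.variogram_kind)
        res = krige_point((stations[i].x, stations[i].y), rest, resid, model,
                          config.neighborhood)
        preds[i] = drift.predict(stations[i].elevation) + res.prediction
    return preds


def load_stations_csv(path) -> list[StationRecord]:
    """Read stations from a CSV with columns x, y, elev, value."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    try:
        return [
            StationRecord(float(r[cols["x"]]), float(r[cols["y"]]),
                          float(r[cols["elev"]]), float(r[cols["value"]]))
            for _, r in df.iterrows()
        ]
    except KeyError as exc:
        raise ValueError(f"stations CSV missing column {exc}") from exc
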