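"""EA-level poverty aggregation and ordinary kriging of poverty surfaces.

The adjusted headcount is aggregated to enumeration-area level (the weighted
mean censored deprivation score within each EA), an empirical semivariogram
is estimated from the EA point values, a parametric variogram model
(exponential by default, spherical or gaussian selectable) is fitted by
weighted least squares, and ordinary kriging produces a smoothed surface on
a regular grid.

Ordinary kriging solves, at every prediction node, the system

    [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu     ] = [ 1       ]

where Gamma holds pairwise semivariances between data points and gamma_0 the
semivariances from data to the node; the unbiasedness constraint forces the
weights lambda to sum to one.  With a zero nugget the predictor interpolates
the data exactly.  Distances are planar Euclidean (the districts mapped here
are small enough that a planar approximation is standard).  Raw predictions
may leave [0, 1]; a clamped copy is kept alongside for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, cdist, squareform

from .af_core import AFParams, _identify_exact, _score_numerators
from .deprivation import DeprivationMatrix
from .errors import ValidationError

__all__ = [
    "VariogramModel",
    "KrigedSurface",
    "aggregate_by_ea",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "ok_weights",
    "semivariance",
    "points_to_geojson",
    "grid_to_geojson",
]

_FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass
class VariogramModel:
    """Parametric semivariogram: nugget + partial sill shaped by the range."""

    model: str = "exponential"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_param: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in _FAMILIES:
            raise ValidationError(f"model must be one of {_FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ValidationError(
                "nugget and partial_sill must be >= 0 and range_param > 0"
            )

    def __call__(self, d) -> np.ndarray:
        return semivariance(self, d)


def semivariance(model: VariogramModel, d) -> np.ndarray:
    """Evaluate the semivariogram; gamma(0) = 0 by convention."""
    d = np.asarray(d, dtype=float)
    h = d / model.range_param
    if model.model == "exponential":
        g = 1.0 - np.exp(-h)
    elif model.model == "gaussian":
        g = 1.0 - np.exp(-(h**2))
    else:  # spherical
        hc = np.minimum(h, 1.0)
        g = 1.5 * hc - 0.5 * hc**3
    out = model.nugget + model.partial_sill * g
    return np.where(d == 0, 0.0, out)


def aggregate_by_ea(
    m: DeprivationMatrix,
    params: AFParams = AFParams(),
    ea_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-EA adjusted headcount: weighted mean censored score within EA.

    Population-share weighted EA values recombine to the overall M0.  When
    ``ea_table`` (with ea_id, x, y) is given, planar coordinates are joined.
    """
    num, lcd = _score_numerators(m)
    poor = _identify_exact(m, params).astype(float)
    ck = (num / lcd) * poor
    s = m.design["sampling_weight"].to_numpy(float)
    df = pd.DataFrame({"ea_id": m.design["ea_id"].to_numpy(), "s": s, "sck": s * ck})
    grp = df.groupby("ea_id", sort=True)
    out = pd.DataFrame(
        {
            "ea_id": grp.size().index,
            "m0": (grp["sck"].sum() / grp["s"].sum()).to_numpy(),
            "n_households": grp.size().to_numpy(),
            "weight": grp["s"].sum().to_numpy(),
        }
    )
    if ea_table is not None:
        cols = [c for c in ("x", "y", "district", "stratum") if c in ea_table.columns]
        out = out.merge(ea_table[["ea_id"] + cols], on="ea_id", how="left")
        if out["x"].isna().any():
            raise ValidationError("some EAs in the data are absent from ea_table")
    return out


def empirical_variogram(
    points, values, n_bins: int = 15, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariogram: mean of squared half-differences.

    Returns a frame with bin-mean distance, semivariance and pair count;
    empty bins are dropped.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValidationError("need at least two points")
    if len(v) != len(pts):
        raise ValidationError("values must align with points")
    d = pdist(pts)
    if d.max() == 0:
        raise ValidationError("all points are coincident")
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    if max_dist <= 0:
        raise ValidationError("max_dist must be > 0")
    dv = pdist(v[:, None]) ** 2 / 2.0  # (v_i - v_j)^2 / 2
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    rows = []
    for b in range(n_bins):
        mask = keep & (idx == b)
        npairs = int(mask.sum())
        if npairs == 0:
            continue
        rows.append(
            {
                "dist": float(d[mask].mean()),
                "gamma": float(dv[mask].mean()),
                "n_pairs": npairs,
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(
    empirical: pd.DataFrame,
    model_family: str = "exponential",
    weighting: str = "cressie",
) -> VariogramModel:
    """Weighted least-squares fit of (nugget, partial sill, range).

    The default weights are N_j / h_j^2 (pair count over squared lag, the
    classic geostatistical default), which anchors the fit at short lags
    where the model carries range information; ``weighting="npairs"`` uses
    pair counts alone.  Non-negativity is enforced by bounds.  A fit that
    degenerates (no resolvable spatial structure) falls back to a
    nugget-only model with a warning.
    """
    if model_family not in _FAMILIES:
        raise ValidationError(f"model_family must be one of {_FAMILIES}")
    if weighting not in ("cressie", "npairs"):
        raise ValidationError("weighting must be 'cressie' or 'npairs'")
    if len(empirical) < 3:
        raise ValidationError("need at least 3 non-empty variogram bins")
    d = empirical["dist"].to_numpy(float)
    g = empirical["gamma"].to_numpy(float)
    w = np.sqrt(empirical["n_pairs"].to_numpy(float))
    if weighting == "cressie":
        w = w / np.maximum(d, 1e-12 * max(d.max(), 1.0))
    dmax = float(d.max())
    gmax = float(g.max())
    if gmax == 0:  # constant field
        return VariogramModel(model_family, 0.0, 0.0, dmax)

    def resid(x):
        mdl = VariogramModel(model_family, x[0], x[1], x[2])
        return w * (semivariance(mdl, d) - g)

    best = None
    for r0 in (dmax / 10.0, dmax / 3.0, dmax):
        try:
            sol = least_squares(
                resid,
                x0=[0.0, gmax, r0],
                bounds=([0.0, 0.0, 1e-9 * dmax], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        warnings.warn("variogram fit degenerated; using nugget-only model")
        return VariogramModel(model_family, float(np.average(g, weights=w**2)), 0.0, dmax)
    nug, psill, rng_ = best.x
    if psill <= 1e-12 * gmax:
        warnings.warn("no spatial structure resolved; using nugget-only model")
        return VariogramModel(model_family, float(nug + psill), 0.0, dmax)
    return VariogramModel(model_family, float(nug), float(psill), float(rng_))


def ok_weights(points, model: VariogramModel, targets):
    """Ordinary-kriging weights and Lagrange multipliers for target points.

    Returns ``(lam, mu, gamma0)`` with ``lam`` of shape (n_targets, n_data);
    each row sums to one.
    """
    pts = np.asarray(points, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValidationError("ordinary kriging needs at least 2 data points")
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = semivariance(model, squareform(pdist(pts)))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        lu = lu_factor(a)
    except Exception:
        a[:n, :n] += 1e-10 * np.eye(n)
        lu = lu_factor(a)  # ridge jitter, single retry

    g0 = semivariance(model, cdist(tgt, pts))
    b = np.empty((n + 1, len(tgt)))
    b[:n, :] = g0.T
    b[n, :] = 1.0
    sol = lu_solve(lu, b)
    return sol[:n, :].T, sol[n, :], g0


@dataclass
class KrigedSurface:
    """Kriged grid with predictions, kriging variance and diagnostics."""

    grid: pd.DataFrame
    model: VariogramModel
    max_weight_dev: float  # max |sum(weights) - 1| over nodes

    def write_csv(self, path) -> None:
        self.grid.to_csv(path, index=False)


def krige(
    eas: pd.DataFrame,
    model: VariogramModel,
    grid_spec=None,
    value_col: str = "m0",
) -> KrigedSurface:
    """Ordinary kriging of an EA-level metric onto a regular grid.

    ``grid_spec`` is ``(nx, ny)`` or ``(nx, ny, (x0, y0, x1, y1))``; default
    100 x 100 over the EA bounding box.  An explicit (t, 2) array of target
    points is also accepted.  Predictions are kept raw in ``m0_pred`` and
    clamped to [0, 1] in ``m0_pred_clamped``; kriging variance is floored at
    zero.
    """
    for c in ("x", "y", value_col):
        if c not in eas.columns:
            raise ValidationError(f"EA table lacks column '{c}'")
    pts = eas[["x", "y"]].to_numpy(float)
    vals = eas[value_col].to_numpy(float)

    if grid_spec is None:
        grid_spec = (100, 100)
    if isinstance(grid_spec, np.ndarray) or (
        isinstance(grid_spec, (list, tuple))
        and len(grid_spec) > 0
        and not np.isscalar(grid_spec[0])
        and not isinstance(grid_spec[-1], tuple)
    ):
        targets = np.asarray(grid_spec, dtype=float)
    else:
        if len(grid_spec) == 3:
            nx, ny, bbox = grid_spec
        else:
            nx, ny = grid_spec
            bbox = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
        gx = np.linspace(bbox[0], bbox[2], int(nx))
        gy = np.linspace(bbox[1], bbox[3], int(ny))
        mx, my = np.meshgrid(gx, gy)
        targets = np.column_stack([mx.ravel(), my.ravel()])

    lam, mu, g0 = ok_weights(pts, model, targets)
    pred = lam @ vals
    var = np.maximum(0.0, np.sum(lam * g0, axis=1) + mu)
    if not np.isfinite(pred).all():
        raise ValidationError("kriging produced non-finite predictions")
    grid = pd.DataFrame(
        {
            "x": targets[:, 0],
            "y": targets[:, 1],
            "m0_pred": pred,
            "m0_pred_clamped": np.clip(pred, 0.0, 1.0),
            "ok_variance": var,
        }
    )
    dev = float(np.max(np.abs(lam.sum(axis=1) - 1.0)))
    return KrigedSurface(grid=grid, model=model, max_weight_dev=dev)


def points_to_geojson(df: pd.DataFrame, props, x: str = "x", y: str = "y") -> dict:
    """RFC 7946 FeatureCollection of point rows with selected properties."""
    feats = []
    for _, row in df.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row[x]), float(row[y])],
                },
                "properties": {
                    k: (row[k].item() if hasattr(row[k], "item") else row[k])
                    for k in props
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def grid_to_geojson(surface: KrigedSurface) -> dict:
    """Kriged grid as GeoJSON points with prediction and variance."""
    return points_to_geojson(
        surface.grid, props=["m0_pred", "m0_pred_clamped", "ok_variance"]
    )
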