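"""Variance-dependent shrinkage and heteroscedastic ordinary kriging of area risks.

Small-area SIR and AAPC estimates are noisy in inverse proportion to the
local population. Maps built from raw values are dominated by that noise,
so stabilization runs in two stages:

1. **Shrinkage toward the null** - each area's value is pulled toward the
   null (1 for SIR, 0 for AAPC) with weight ``tau^2 / (tau^2 + sigma_i^2)``,
   where ``sigma_i^2`` is its sampling variance and ``tau^2`` a
   method-of-moments between-area variance. Areas with small populations
   (large ``sigma_i^2``) are shrunk heavily; large areas barely move.
2. **Ordinary kriging with measurement error** - the shrunken values are
   interpolated to a regular grid from a fitted semivariogram, with the
   residual post-shrinkage noise ``e_i^2 = w_i * sigma_i^2`` added to the
   data-data covariance diagonal only, so the surface smooths rather than
   interpolates noisy points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from shapely.ops import unary_union

from .core_tables import AreaGeometry, ValidationError

__all__ = [
    "Variogram",
    "StabilizedValue",
    "KrigedSurface",
    "estimate_tau2",
    "shrink_to_null",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "make_grid",
    "classify_values",
    "classify_surface",
    "render_map",
    "stabilize_and_krige",
]


@dataclass(frozen=True)
class Variogram:
    """Parametric semivariogram: nugget, partial sill, range."""

    model: str = "exponential"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_: float = 1.0

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValidationError("variogram parameters must be nonnegative, range > 0")
        if self.model not in ("exponential", "spherical"):
            raise ValidationError(f"unknown variogram model {self.model!r}")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / self.range_)
        else:  # spherical
            u = np.clip(h / self.range_, 0.0, 1.0)
            struct = 1.5 * u - 0.5 * u ** 3
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h > 0, gamma, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); the nugget is
        carried only at h = 0 exactly."""
        h = np.asarray(h, dtype=float)
        sill = self.nugget + self.partial_sill
        return np.where(h > 0, sill - self.semivariance(h), sill)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


@dataclass
class StabilizedValue:
    """One area's raw and shrunken value with its shrinkage weight."""

    area_id: str
    raw: float
    null: float
    variance: float
    weight: float
    stabilized: float
    degenerate: bool = False


@dataclass
class KrigedSurface:
    """Gridded kriging predictions with variances and tri-class labels."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    variances: np.ndarray
    classes: np.ndarray | None = None
    null: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y, "value": self.values,
                           "variance": self.variances})
        if self.classes is not None:
            df["class"] = self.classes
        return df


# ---------------------------------------------------------------------------
# Shrinkage
# ---------------------------------------------------------------------------

def estimate_tau2(values, variances, null: float) -> float:
    """Method-of-moments between-area variance about the null.

    tau^2 = max(0, mean((v - null)^2) - mean(sigma^2)); zero is legal and
    means total shrinkage to the null.
    """
    v = np.asarray(values, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 areas to estimate tau^2")
    return float(max(0.0, np.mean((v - null) ** 2) - np.mean(s2)))


def shrink_to_null(value: float, variance: float, tau2: float, null: float) -> StabilizedValue:
    """Pull one noisy estimate toward the null with weight tau^2/(tau^2+sigma^2)."""
    if variance < 0 or tau2 < 0:
        raise ValidationError("variances must be nonnegative")
    if variance == 0 and tau2 == 0:
        return StabilizedValue("", value, null, variance, 0.0, null, degenerate=True)
    w = tau2 / (tau2 + variance)
    return StabilizedValue("", value, null, variance, w, null + w * (value - null))


def shrink_table(df: pd.DataFrame, value_col: str, var_col: str,
                 null: float, tau2: float | None = None) -> pd.DataFrame:
    """Vectorized shrinkage over an area table; adds weight/stabilized columns."""
    out = df.copy()
    if tau2 is None:
        tau2 = estimate_tau2(out[value_col], out[var_col], null)
    sv = [shrink_to_null(v, s2, tau2, null)
          for v, s2 in zip(out[value_col], out[var_col])]
    out["weight"] = [s.weight for s in sv]
    out["stabilized"] = [s.stabilized for s in sv]
    out.attrs["tau2"] = tau2
    return out


# ---------------------------------------------------------------------------
# Variogram estimation
# ---------------------------------------------------------------------------

def empirical_variogram(coords, values, n_bins: int = 15,
                        max_dist: float | None = None) -> pd.DataFrame:
    """Matheron estimator of the semivariogram on distance bins.

    gamma_hat(h_k) = sum over pairs in bin k of (z_i - z_j)^2 / (2 N_k);
    empty bins are dropped. Default max distance is half the largest
    pairwise distance (the usual rule of thumb).
    """
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValidationError("need at least 2 points for a variogram")
    d = pdist(coords)
    if d.max() == 0:
        raise ValidationError("all points coincident")
    if max_dist is None:
        max_dist = d.max() / 2.0
    if max_dist <= 0:
        raise ValidationError("max_dist must be positive")
    sq = pdist(z[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges) - 1
    rows = []
    for k in range(n_bins):
        sel = which == k
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            continue
        rows.append({
            "h": float(d[sel].mean()),
            "gamma": float(sq[sel].sum() / (2.0 * n_pairs)),
            "n_pairs": n_pairs,
        })
    return pd.DataFrame(rows)


def fit_variogram(binned: pd.DataFrame, model: str = "exponential") -> Variogram:
    """Weighted least squares fit with Cressie weights N_k / gamma(h_k)^2."""
    if len(binned) < 3:
        raise ValidationError("need at least 3 nonempty bins to fit a variogram")
    h = binned["h"].to_numpy(dtype=float)
    g = binned["gamma"].to_numpy(dtype=float)
    n = binned["n_pairs"].to_numpy(dtype=float)
    h_max = h.max()
    g_mean = max(g.mean(), 1e-12)

    def residuals(params):
        c0, c1, phi = params
        vg = Variogram(model=model, nugget=c0, partial_sill=c1, range_=phi)
        mod = np.maximum(vg.semivariance(h), 1e-12 * g_mean)
        return np.sqrt(n) * (g - mod) / mod

    x0 = np.array([0.1 * g_mean, max(g_mean, 1e-12), h_max / 3.0])
    result = least_squares(
        residuals, x0,
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, h_max]),
    )
    if not result.success:
        raise RuntimeError(
            f"variogram fit failed: {result.message}; input bins:\n{binned}"
        )
    c0, c1, phi = result.x
    return Variogram(model=model, nugget=float(c0), partial_sill=float(c1),
                     range_=float(max(phi, 1e-9)))


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def krige(coords, values, error_variances, vario: Variogram, grid_points,
          return_weights: bool = False):
    """Ordinary kriging with per-point measurement error.

    The (n+1) augmented system enforces unit-sum weights. Measurement-error
    variances enter only the data-data covariance diagonal, never the
    data-prediction covariances, so noisy points are smoothed through
    rather than reproduced.
    """
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(values, dtype=float)
    e2 = np.zeros(len(z)) if error_variances is None \
        else np.asarray(error_variances, dtype=float)
    gp = np.asarray(grid_points, dtype=float)
    if gp.size == 0:
        raise ValidationError("empty prediction grid")
    n = len(z)
    D = squareform(pdist(coords))
    if np.any(D[np.triu_indices(n, 1)] == 0):
        i, j = np.argwhere((D == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValidationError(f"coincident centroids at rows {i} and {j}")
    K = vario.covariance(D)
    K[np.diag_indices(n)] = vario.sill + e2
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        lu = lu_factor(A)
    except Exception as exc:  # pragma: no cover
        raise ValidationError(f"singular kriging system: {exc}") from exc

    d0 = cdist(gp, coords)
    B = np.empty((n + 1, len(gp)))
    B[:n] = vario.covariance(d0).T
    B[n] = 1.0
    sol = lu_solve(lu, B)
    lam, mu_l = sol[:n], sol[n]
    wsum = lam.sum(axis=0)
    if np.any(np.abs(wsum - 1.0) > 1e-6):
        raise RuntimeError("kriging weights failed to sum to one")
    pred = lam.T @ z
    var = vario.sill - np.einsum("ij,ij->j", lam, B[:n]) - mu_l
    var = np.maximum(var, 0.0)
    surface = KrigedSurface(x=gp[:, 0], y=gp[:, 1], values=pred, variances=var)
    if return_weights:
        return surface, lam.T
    return surface


def make_grid(geoms: list[AreaGeometry], resolution: float) -> np.ndarray:
    """Regular grid of points at ``resolution`` spacing inside the polygon union."""
    if not geoms:
        raise ValidationError("empty geometry set")
    union = unary_union([g.polygon for g in geoms])
    minx, miny, maxx, maxy = union.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    XX, YY = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(union, XX.ravel(), YY.ravel())
    return np.column_stack([XX.ravel()[inside], YY.ravel()[inside]])


# ---------------------------------------------------------------------------
# Classification and rendering
# ---------------------------------------------------------------------------

def classify_values(values, null: float, tolerance: float,
                    scale: str | None = None) -> np.ndarray:
    """Tri-class labels about the null: above / near / below.

    ``scale='multiplicative'`` (natural for SIR, null 1) calls a value
    above if v > null*(1+t); ``'additive'`` (AAPC, null 0) if v > null+t.
    Default picks multiplicative for a nonzero null.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be nonnegative")
    if scale is None:
        scale = "multiplicative" if null != 0 else "additive"
    v = np.asarray(values, dtype=float)
    if scale == "multiplicative":
        hi, lo = null * (1 + tolerance), null * (1 - tolerance)
    else:
        hi, lo = null + tolerance, null - tolerance
    out = np.where(v > hi, "above", np.where(v < lo, "below", "near"))
    return out


def classify_surface(surface: KrigedSurface, null: float, tolerance: float,
                     scale: str | None = None) -> KrigedSurface:
    surface.classes = classify_values(surface.values, null, tolerance, scale)
    surface.null = null
    return surface


def render_map(surface: KrigedSurface, geoms: list[AreaGeometry], path,
               contour_levels=None, title: str | None = None,
               excluded_area_ids: list[str] | None = None) -> None:
    """Tri-color (red/white/blue) filled map with contour lines, clipped to
    the mapped polygons; deterministic for fixed inputs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    if not geoms:
        raise ValidationError("empty geometry set")
    if surface.classes is None:
        raise ValidationError("classify the surface before rendering")

    fig, ax = plt.subplots(figsize=(7, 7))
    class_num = np.select(
        [surface.classes == "below", surface.classes == "near",
         surface.classes == "above"],
        [0.0, 1.0, 2.0])
    tric = ax.tricontourf(surface.x, surface.y, class_num,
                          levels=[-0.5, 0.5, 1.5, 2.5],
                          colors=["#4575b4", "#ffffff", "#d73027"])
    if contour_levels is not None:
        lo, hi = surface.values.min(), surface.values.max()
        levels = sorted(l for l in contour_levels if lo < l < hi)
        if levels:
            cs = ax.tricontour(surface.x, surface.y, surface.values,
                               levels=levels, colors="black", linewidths=0.6)
            ax.clabel(cs, fontsize=6, fmt="%.2f")

    union = unary_union([g.polygon for g in geoms])
    polys = [union] if union.geom_type == "Polygon" else list(union.geoms)
    verts, codes = [], []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = np.asarray(ring.coords)
            verts.extend(pts)
            codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2)
                         + [MplPath.CLOSEPOLY])
    clip = PathPatch(MplPath(verts, codes), transform=ax.transData,
                     facecolor="none", edgecolor="black", linewidth=0.8)
    ax.add_patch(clip)
    for coll in tric.collections if hasattr(tric, "collections") else [tric]:
        coll.set_clip_path(clip)

    excluded = set(excluded_area_ids or [])
    for g in geoms:
        if g.area_id in excluded:
            xs, ys = np.asarray(g.polygon.exterior.coords).T
            ax.fill(xs, ys, facecolor="none", edgecolor="grey", hatch="///",
                    linewidth=0.3)
    if title:
        ax.set_title(title)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=150, metadata={"Software": "apcmap"})
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def stabilize_and_krige(area_table: pd.DataFrame, geoms: list[AreaGeometry],
                        value_col: str, var_col: str, null: float,
                        resolution: float = 1.0, n_bins: int = 15,
                        model: str = "exponential",
                        tolerance: float = 0.05,
                        error_mode: str = "post_shrinkage",
                        scale: str | None = None):
    """Shrink, fit a variogram, krige, classify: the full mapping stage.

    ``error_mode='post_shrinkage'`` uses e_i^2 = w_i * sigma_i^2 (the
    residual uncertainty after shrinkage); ``'raw'`` uses sigma_i^2.
    Returns (shrunken table, Variogram, classified KrigedSurface).
    """
    geo_ids = {g.area_id for g in geoms}
    tab = area_table[area_table["area_id"].isin(geo_ids)].reset_index(drop=True)
    shrunk = shrink_table(tab, value_col, var_col, null)
    cent = {g.area_id: (g.centroid.x, g.centroid.y) for g in geoms}
    coords = np.array([cent[a] for a in shrunk["area_id"]])
    z = shrunk["stabilized"].to_numpy()
    emp = empirical_variogram(coords, z, n_bins=n_bins)
    vario = fit_variogram(emp, model=model)
    if error_mode == "post_shrinkage":
        e2 = (shrunk["weight"] * shrunk[var_col]).to_numpy()
    elif error_mode == "raw":
        e2 = shrunk[var_col].to_numpy()
    else:
        raise ValidationError(f"unknown error_mode {error_mode!r}")
    grid = make_grid(geoms, resolution)
    surface = krige(coords, z, e2, vario, grid)
    classify_surface(surface, null, tolerance, scale=scale)
    return shrunk, vario, surface
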