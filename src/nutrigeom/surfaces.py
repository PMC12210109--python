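"""Bivariate intake response surfaces over protein and nonprotein energy axes.

The model is ``intake_i = beta0 + f(x_i, z_i) + eps_i`` with x the
dietary protein energy density (kJ per g of diet), z the nonprotein
(carbohydrate + fat) energy density, and f a penalized thin-plate
smooth whose flexibility is chosen from the data. A flat surface is the
null hypothesis for f: a significant smooth term means intake varies
with diet composition.

Implementation: a thin-plate regression spline. Radial basis functions
eta(r) = r^2 log r are centred on the distinct diet design points
(thinned to at most ``k`` knots by farthest-point sampling), the
polynomial null space [1, x, z] is unpenalized, and the wiggliness
penalty is the thin-plate bending energy restricted to the constraint
subspace. The smoothing parameter minimizes generalized
cross-validation (GCV). The significance of the smooth is the exact
F-test of the unpenalized spline basis against the intercept-only
model — exactly calibrated under Gaussian errors, which is the property
the flat-null check demands — while the reported surface, effective
degrees of freedom and residual variance come from the penalized fit.

Surfaces are only evaluated inside the convex hull of the observed
design points; the designs sample an irregular region of nutrient
space and extrapolated cells would be meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial
import scipy.stats

from .diets import DEFAULT_FACTORS, DietSpec, EnergyFactors, diets_to_frame

__all__ = ["SurfaceFit", "fit_surface", "surface_summary", "fit_surface_by_group"]

logger = logging.getLogger(__name__)

_RESPONSE_COLUMNS = {"food": "food_intake_g", "energy": "energy_intake_kj"}


class SurfaceError(ValueError):
    pass


class CollinearAxesError(SurfaceError):
    """Raised when the protein and nonprotein axes covary too strongly to separate."""


def _eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis in 2D, with eta(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _farthest_point_thin(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling subset of k rows of pts."""
    n = len(pts)
    if n <= k:
        return np.arange(n)
    center = pts.mean(axis=0)
    chosen = [int(np.argmin(((pts - center) ** 2).sum(axis=1)))]
    d = ((pts - pts[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, ((pts - pts[nxt]) ** 2).sum(axis=1))
    return np.array(sorted(chosen))


@dataclass
class SurfaceFit:
    """A fitted penalized intake surface and its evaluation grid."""

    response: str
    beta0: float
    smooth_edf: float
    p_smooth: float
    sigma2: float
    lam: float
    gcv: float
    n: int
    n_design_points: int
    grid: pd.DataFrame  # columns x, z, fitted (NaN outside hull), in_hull
    group: str | None = None
    scale: tuple[float, float] | None = None  # shared color range for grouped fits
    _predict: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def predict(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Evaluate the fitted surface at arbitrary (x, z), without hull masking."""
        if self._predict is None:
            raise SurfaceError("this SurfaceFit carries no predictor (deserialized?)")
        return self._predict(np.asarray(x, float), np.asarray(z, float))

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "group": self.group,
            "beta0": self.beta0,
            "smooth_edf": self.smooth_edf,
            "p_smooth": self.p_smooth,
            "sigma2": self.sigma2,
            "lambda": self.lam,
            "gcv": self.gcv,
            "n": self.n,
            "n_design_points": self.n_design_points,
        }


def fit_surface(
    obs: pd.DataFrame,
    diets: Sequence[DietSpec],
    response: str = "food",
    factors: EnergyFactors = DEFAULT_FACTORS,
    k: int = 25,
    grid_size: int = 40,
    collinearity_limit: float = 0.95,
    group: str | None = None,
) -> SurfaceFit:
    """Fit the penalized bivariate smooth of intake on (protein, nonprotein) kJ/g."""
    if response not in _RESPONSE_COLUMNS:
        raise SurfaceError(f"response must be one of {sorted(_RESPONSE_COLUMNS)}")
    dt = diets_to_frame(diets, factors)
    df = obs.merge(
        dt[["diet_id", "protein_energy_axis", "nonprotein_energy_axis"]],
        on="diet_id",
        how="left",
    )
    if df["protein_energy_axis"].isna().any():
        missing = sorted(df.loc[df["protein_energy_axis"].isna(), "diet_id"].unique())
        raise SurfaceError(f"observations reference unknown diets: {missing}")
    y = df[_RESPONSE_COLUMNS[response]].to_numpy(float)
    x = df["protein_energy_axis"].to_numpy(float)
    z = df["nonprotein_energy_axis"].to_numpy(float)
    n = len(y)

    design_pts = np.unique(np.round(np.column_stack([x, z]), 9), axis=0)
    m_design = len(design_pts)
    if m_design < 10:
        raise SurfaceError(
            f"need at least 10 distinct (protein, nonprotein) design points, got {m_design}"
        )
    r_xz = float(np.corrcoef(design_pts[:, 0], design_pts[:, 1])[0, 1])
    if abs(r_xz) >= collinearity_limit:
        raise CollinearAxesError(
            f"protein and nonprotein axes are collinear across the design "
            f"(|r| = {abs(r_xz):.3f} >= {collinearity_limit}); the axes cannot be "
            "separated — the same confound that ties percent fat to energy density "
            "in fat-manipulation designs"
        )

    # standardized coordinates for a scale-free radial basis
    mu = design_pts.mean(axis=0)
    sd = design_pts.std(axis=0)
    sd[sd == 0] = 1.0

    def _std(px: np.ndarray, pz: np.ndarray) -> np.ndarray:
        return np.column_stack([(px - mu[0]) / sd[0], (pz - mu[1]) / sd[1]])

    knots = design_pts[_farthest_point_thin(_std(design_pts[:, 0], design_pts[:, 1]), k)]
    kn = _std(knots[:, 0], knots[:, 1])
    m = len(kn)

    E_kk = _eta(scipy.spatial.distance.cdist(kn, kn))
    T_k = np.column_stack([np.ones(m), kn])
    Z = scipy.linalg.null_space(T_k.T)  # m x (m-3)
    S_gamma = Z.T @ E_kk @ Z
    S_gamma = (S_gamma + S_gamma.T) / 2.0
    # bending energy is PSD on the constraint subspace up to basis sign
    if np.trace(S_gamma) < 0:
        S_gamma = -S_gamma
    w_s, V_s = np.linalg.eigh(S_gamma)
    S_gamma = (V_s * np.clip(w_s, 0.0, None)) @ V_s.T

    obs_std = _std(x, z)
    E_nk = _eta(scipy.spatial.distance.cdist(obs_std, kn))
    X = np.column_stack([np.ones(n), obs_std, E_nk @ Z])
    q = X.shape[1]
    S = np.zeros((q, q))
    S[3:, 3:] = S_gamma

    XtX = X.T @ X
    Xty = X.T @ y
    ridge = 1e-10 * np.trace(XtX) / q
    R = np.linalg.cholesky(XtX + ridge * np.eye(q))
    Rinv = scipy.linalg.solve_triangular(R, np.eye(q), lower=True)
    M = Rinv @ S @ Rinv.T
    M = (M + M.T) / 2.0
    d, Q = np.linalg.eigh(M)
    d = np.clip(d, 0.0, None)
    u = Q.T @ (Rinv @ Xty)

    d_pos = d[d > 1e-12]
    scale0 = 1.0 / np.median(d_pos) if len(d_pos) else 1.0
    # descending lambda grid: on GCV ties the smoother fit wins
    lams = np.concatenate([np.logspace(10, -8, 91) * scale0, [0.0]])
    best = None
    for lam in lams:
        shrink = 1.0 / (1.0 + lam * d)
        b = Rinv.T @ (Q @ (shrink * u))
        resid = y - X @ b
        rss = float(resid @ resid)
        edf = float(shrink.sum())
        if n - edf <= 0:
            continue
        gcv = n * rss / (n - edf) ** 2
        # prefer the smoother fit on GCV ties
        if best is None or gcv < best[0] * (1 - 1e-10):
            best = (gcv, lam, b, edf, rss)
    if best is None:
        raise SurfaceError("GCV search failed: model saturates the data at every lambda")
    gcv, lam, b, edf, rss = best
    sigma2 = rss / max(n - edf, 1e-12)
    smooth_edf = max(edf - 3.0, 0.0)

    # exact F-test of the unpenalized basis against a flat surface
    rank = int(np.linalg.matrix_rank(X))
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta_ols) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 1e-12 * max(1.0, float(y @ y)):
        p_smooth = 1.0  # data are flat to numerical precision
    elif n - rank <= 0 or rss1 <= 0:
        p_smooth = float("nan")
        logger.warning("smooth-term test undefined: basis saturates the observations")
    else:
        F = ((rss0 - rss1) / (rank - 1)) / (rss1 / (n - rank))
        p_smooth = float(scipy.stats.f.sf(F, rank - 1, n - rank))

    def _predict(px: np.ndarray, pz: np.ndarray) -> np.ndarray:
        pts = _std(np.atleast_1d(px), np.atleast_1d(pz))
        basis = np.column_stack(
            [np.ones(len(pts)), pts, _eta(scipy.spatial.distance.cdist(pts, kn)) @ Z]
        )
        return basis @ b

    beta0 = float(_predict(np.array([mu[0]]), np.array([mu[1]]))[0])

    # a lattice cell counts as inside when its region touches the hull, i.e.
    # its center is within half a cell diagonal of the hull boundary; cells
    # wholly outside the hull of observed design points are never evaluated
    hull = scipy.spatial.ConvexHull(design_pts)
    gx = np.linspace(design_pts[:, 0].min(), design_pts[:, 0].max(), grid_size)
    gz = np.linspace(design_pts[:, 1].min(), design_pts[:, 1].max(), grid_size)
    GX, GZ = np.meshgrid(gx, gz)
    flat_x, flat_z = GX.ravel(), GZ.ravel()
    pts = np.column_stack([flat_x, flat_z])
    # qhull facet equations a.p + b <= 0 inside, with |a| = 1
    outside_dist = np.max(pts @ hull.equations[:, :2].T + hull.equations[:, 2], axis=1)
    half_cell = 0.5 * np.hypot(gx[1] - gx[0], gz[1] - gz[0]) if grid_size > 1 else 0.0
    inside = outside_dist <= half_cell
    fitted = np.full(flat_x.shape, np.nan)
    if inside.any():
        fitted[inside] = _predict(flat_x[inside], flat_z[inside])
    grid = pd.DataFrame({"x": flat_x, "z": flat_z, "fitted": fitted, "in_hull": inside})

    return SurfaceFit(
        response=response,
        beta0=beta0,
        smooth_edf=smooth_edf,
        p_smooth=p_smooth,
        sigma2=sigma2,
        lam=float(lam),
        gcv=float(gcv),
        n=n,
        n_design_points=m_design,
        grid=grid,
        group=group,
        _predict=_predict,
    )


def surface_summary(fit: SurfaceFit, isoline_quantiles: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9)) -> dict:
    """Argmax/argmin cells, fitted range, and isoline levels of a fitted surface."""
    inhull = fit.grid[fit.grid["in_hull"]]
    if inhull.empty:
        raise SurfaceError("fitted grid has no in-hull cells")
    vals = inhull["fitted"].to_numpy()
    imax = int(np.argmax(vals))
    imin = int(np.argmin(vals))
    argmax = inhull.iloc[imax]
    argmin = inhull.iloc[imin]
    return {
        "argmax": {"x": float(argmax["x"]), "z": float(argmax["z"]), "fitted": float(argmax["fitted"])},
        "argmin": {"x": float(argmin["x"]), "z": float(argmin["z"]), "fitted": float(argmin["fitted"])},
        "range": float(vals.max() - vals.min()),
        "isolines": [float(v) for v in np.quantile(vals, isoline_quantiles)],
    }


_GROUP_COLUMNS = {"strain": "strain", "sex": "sex", "study": "study_id"}


def fit_surface_by_group(
    obs: pd.DataFrame,
    diets: Sequence[DietSpec],
    response: str = "food",
    group: str = "study",
    factors: EnergyFactors = DEFAULT_FACTORS,
    **kwargs,
) -> list[SurfaceFit]:
    """Independent surface fits per group, with shared color scaling metadata.

    Groups that fail the fit preconditions (too few design points,
    collinear axes) are skipped with a logged reason; the others
    proceed.
    """
    if group not in _GROUP_COLUMNS:
        raise SurfaceError(f"group must be one of {sorted(_GROUP_COLUMNS)}")
    col = _GROUP_COLUMNS[group]
    fits: list[SurfaceFit] = []
    for level, sub in obs.groupby(col, sort=True):
        try:
            fit = fit_surface(sub, diets, response=response, factors=factors, group=str(level), **kwargs)
        except SurfaceError as exc:
            logger.warning("skipping group %s=%r: %s", group, level, exc)
            continue
        fits.append(fit)
    if fits:
        lo = min(np.nanmin(f.grid["fitted"]) for f in fits)
        hi = max(np.nanmax(f.grid["fitted"]) for f in fits)
        for f in fits:
            f.scale = (float(lo), float(hi))
    return fits
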