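"""Isolation-by-distance model comparison.

Pairwise genetic differentiation, linearized as ``F/(1-F)``, is regressed
on candidate geographic predictors — minimum oceanographic transport time
from the stepping-stone matrix, and shortest over-sea (marine) distance —
with ordinary least squares; models are ranked by AIC and adjusted R².
Pairwise distances are not independent; the plain linear fits mirror the
standard seascape workflow and a Mantel permutation option is available
for the slope's significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .regions import SteppingStoneMatrix
from .seascape import SeascapeGrid
from .seqstats import great_circle_km

__all__ = [
    "ModelFit",
    "marine_distance",
    "linearize_fst",
    "fit_ibd",
    "compare_models",
    "upper_triangle",
    "site_transport_matrix",
    "snap_to_cells",
]


class IBDError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Marine distances
# ---------------------------------------------------------------------------

def _sea_graph(grid: SeascapeGrid) -> tuple[csr_matrix, np.ndarray]:
    """Sparse 8-connected graph over sea cells with km edge lengths."""
    ny, nx_ = grid.shape
    idx = -np.ones((ny, nx_), dtype=int)
    sea = np.argwhere(grid.mask)
    idx[sea[:, 0], sea[:, 1]] = np.arange(len(sea))
    rows, cols, vals = [], [], []
    ys0, xs0 = np.nonzero(grid.mask)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        yt, xt = ys0 + dy, xs0 + dx
        ok = (yt >= 0) & (yt < ny) & (xt >= 0) & (xt < nx_)
        ys, xs, yt, xt = ys0[ok], xs0[ok], yt[ok], xt[ok]
        ok = grid.mask[yt, xt]
        ys, xs, yt, xt = ys[ok], xs[ok], yt[ok], xt[ok]
        ia, ib = idx[ys, xs], idx[yt, xt]
        if grid.mode == "cartesian":
            length = grid.cell_size * (np.sqrt(2.0) if dy and dx else 1.0)
            w = np.full(ia.size, length)
        else:
            w = great_circle_km(grid.y[ys], grid.x[xs], grid.y[yt], grid.x[xt])
        rows.append(ia)
        cols.append(ib)
        vals.append(w)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    n = len(sea)
    G = csr_matrix((np.concatenate([v, v]),
                    (np.concatenate([r, c]), np.concatenate([c, r]))),
                   shape=(n, n))
    return G, sea


def snap_to_cells(grid: SeascapeGrid, sites: pd.DataFrame,
                  max_radius_cells: float = 5.0) -> np.ndarray:
    """Snap each site to its nearest sea cell (error beyond the radius).

    ``sites`` columns: ``x``/``y`` (cartesian km) or ``lon``/``lat``.
    """
    sea = np.argwhere(grid.mask)
    if grid.mode == "cartesian":
        cx = grid.x[sea[:, 1]]
        cy = grid.y[sea[:, 0]]
        sx = sites["x"].to_numpy(float)
        sy = sites["y"].to_numpy(float)
        d = np.hypot(cx[None, :] - sx[:, None], cy[None, :] - sy[:, None])
        limit = max_radius_cells * grid.cell_size
    else:
        cy = grid.y[sea[:, 0]]
        cx = grid.x[sea[:, 1]]
        sy = sites["lat"].to_numpy(float)
        sx = sites["lon"].to_numpy(float)
        d = great_circle_km(sy[:, None], sx[:, None], cy[None, :], cx[None, :])
        limit = max_radius_cells * grid.cell_size * 111.132
    nearest = d.argmin(axis=1)
    if (d[np.arange(len(sites)), nearest] > limit).any():
        bad = np.flatnonzero(d[np.arange(len(sites)), nearest] > limit)
        raise IBDError(f"sites {bad.tolist()} do not snap to a sea cell "
                       f"within {max_radius_cells} cells")
    return nearest  # indices into the sea-cell list


def marine_distance(grid: SeascapeGrid, sites: pd.DataFrame,
                    max_radius_cells: float = 5.0) -> pd.DataFrame:
    """Shortest over-sea path length (km) between sites, by Dijkstra on the
    8-connected sea graph (diagonal steps cost sqrt(2) of a cell).

    Unreachable pairs are inf with a warning.
    """
    G, _ = _sea_graph(grid)
    snapped = snap_to_cells(grid, sites, max_radius_cells)
    D = dijkstra(G, directed=False, indices=snapped)
    out = D[:, snapped]
    out = (out + out.T) / 2.0  # symmetric up to float error
    if np.isinf(out).any():
        warnings.warn("some site pairs are unreachable over sea", stacklevel=2)
    labels = (sites["pop_id"].tolist() if "pop_id" in sites.columns
              else list(range(len(sites))))
    return pd.DataFrame(out, index=labels, columns=labels)


def site_transport_matrix(S: SteppingStoneMatrix, grid: SeascapeGrid,
                          sites: pd.DataFrame,
                          max_radius_cells: float = 20.0) -> pd.DataFrame:
    """Minimum stepping-stone transport time between sites (days).

    Each site snaps to the nearest coastal cell; the unordered-pair value
    is the minimum of the two directed path times.
    """
    centres = grid.coastal_centres()
    if grid.mode == "cartesian":
        sx = sites["x"].to_numpy(float)
        sy = sites["y"].to_numpy(float)
        d = np.hypot(centres[None, :, 0] - sx[:, None],
                     centres[None, :, 1] - sy[:, None])
    else:
        sy = sites["lat"].to_numpy(float)
        sx = sites["lon"].to_numpy(float)
        d = great_circle_km(sy[:, None], sx[:, None],
                            centres[None, :, 1], centres[None, :, 0])
    cells = d.argmin(axis=1)
    sub = S.S[np.ix_(cells, cells)]
    sym = np.minimum(sub, sub.T)
    labels = (sites["pop_id"].tolist() if "pop_id" in sites.columns
              else list(range(len(sites))))
    return pd.DataFrame(sym, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def linearize_fst(F) -> np.ndarray:
    """``F/(1-F)`` element-wise; negative F passes through; F = 1 -> inf
    (flagged with a warning)."""
    F = np.asarray(F, dtype=float)
    if np.any(F == 1):
        warnings.warn("F = 1 linearizes to infinity", stacklevel=2)
    with np.errstate(divide="ignore"):
        return F / (1.0 - F)


def upper_triangle(M) -> np.ndarray:
    """Vectorize a symmetric pairwise matrix: each unordered pair once."""
    M = np.asarray(M, dtype=float)
    return M[np.triu_indices(M.shape[0], 1)]


@dataclass
class ModelFit:
    predictor: str
    slope: float
    intercept: float
    r2_adj: float
    aic: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)
    mantel_p: float | None = None


def fit_ibd(y, x, predictor: str = "x", mantel_perms: int = 0,
            seed: int = 0) -> ModelFit:
    """OLS of linearized genetic distances on one predictor.

    ``y`` and ``x`` are vectors over unordered population pairs (use
    :func:`upper_triangle`).  Reports the slope, intercept, adjusted R²
    and Gaussian AIC.  ``mantel_perms > 0`` adds a Mantel-style permutation
    p-value for the slope (off by default; the reference analysis fits the
    plain linear model).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise IBDError("y and x must be the same length")
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise IBDError("need >= 3 pairs for a defined adjusted R^2")
    if np.ptp(x) == 0:
        raise IBDError("zero-variance predictor")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    fit = ModelFit(
        predictor=predictor,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        aic=float(res.aic),
        n=int(y.size),
        residuals=np.asarray(res.resid),
    )
    if mantel_perms:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A]))
        obs = abs(fit.slope)
        count = 0
        for _ in range(mantel_perms):
            perm = rng.permutation(y.size)
            r = sm.OLS(y[perm], X).fit()
            if abs(r.params[1]) >= obs - 1e-15:
                count += 1
        fit.mantel_p = (count + 1) / (mantel_perms + 1)
    return fit


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits of the same response by AIC (with delta AIC and adj. R²)."""
    if len(fits) < 2:
        raise IBDError("need >= 2 fits to compare")
    if len({f.n for f in fits}) != 1:
        raise IBDError("fits use different numbers of pairs")
    df = pd.DataFrame(
        [{"predictor": f.predictor, "slope": f.slope, "aic": f.aic,
          "r2_adj": f.r2_adj, "n": f.n} for f in fits]
    ).sort_values(["aic", "predictor"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df.aic - df.aic.min()
    return df
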