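"""Synthetic seascapes: gridded coastal domains and daily velocity fields.

A :class:`SeascapeGrid` is a regular cell grid with a land/sea mask from
which coastal cells (sea cells touching land) are extracted.  A
:class:`VelocityField` holds daily surface-current components ``u``/``v``
over the grid for one or more years.  Synthetic fields are composed from
analytic ingredients (uniform drift, zonal jets, streamfunction-derived
gyres, seeded noise) so that dispersal barriers with known ground truth can
be planted in test domains.

Two coordinate modes are supported.  ``"cartesian"`` grids are in km with
Euclidean geometry and are the work-horse for tests; ``"geographic"`` grids
are in degrees with zonal displacements scaled by ``cos(latitude)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "SeascapeGrid",
    "VelocityField",
    "make_seascape",
    "make_velocity_series",
    "M_PER_DEG_LAT",
]

#: metres per degree of latitude (spherical Earth, WGS84 mean)
M_PER_DEG_LAT = 111_132.0


class SeascapeError(ValueError):
    """Raised for invalid seascape specifications."""


def _decode_attr(value):
    return value.decode() if isinstance(value, bytes) else value


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass
class SeascapeGrid:
    """Regular grid with a land/sea mask and extracted coastal cells.

    Parameters
    ----------
    x, y :
        Cell-centre coordinate vectors (km in cartesian mode, degrees of
        longitude/latitude in geographic mode), strictly increasing and
        evenly spaced.
    cell_size :
        Grid spacing in the coordinate units.
    mask :
        Boolean ``(ny, nx)`` array, ``True`` for sea cells.
    mode :
        ``"cartesian"`` or ``"geographic"``.

    Attributes
    ----------
    coastal_cells :
        ``(n, 2)`` integer array of ``(iy, ix)`` indices of coastal cells
        (sea cells with at least one land cell among their 8 neighbours),
        in row-major scan order.  Coastal cell *ids* are the row indices
        ``0..n-1`` of this array and are stable across the pipeline.
    """

    x: np.ndarray
    y: np.ndarray
    cell_size: float
    mask: np.ndarray
    mode: str = "cartesian"
    coastal_cells: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mode not in ("cartesian", "geographic"):
            raise SeascapeError(f"unknown mode {self.mode!r}")
        if self.mask.shape != (self.y.size, self.x.size):
            raise SeascapeError(
                f"mask shape {self.mask.shape} does not match axes "
                f"({self.y.size}, {self.x.size})"
            )
        self.coastal_cells = _coastal_cells(self.mask)
        if len(self.coastal_cells) == 0:
            raise SeascapeError("seascape has no coastal cells")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_coastal(self) -> int:
        return len(self.coastal_cells)

    def cell_index(self, x, y):
        """Map positions to ``(iy, ix)`` cell indices (-1 outside the domain).

        A cell spans half a ``cell_size`` either side of its centre.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = self.cell_size
        ix = np.floor((x - (self.x[0] - d / 2)) / d).astype(int)
        iy = np.floor((y - (self.y[0] - d / 2)) / d).astype(int)
        bad = (ix < 0) | (ix >= self.x.size) | (iy < 0) | (iy >= self.y.size)
        ix = np.where(bad, -1, ix)
        iy = np.where(bad, -1, iy)
        return iy, ix

    def coastal_id_of(self, iy: int, ix: int) -> int:
        """Coastal id of a cell, or -1 if the cell is not coastal."""
        hits = np.flatnonzero(
            (self.coastal_cells[:, 0] == iy) & (self.coastal_cells[:, 1] == ix)
        )
        return int(hits[0]) if hits.size else -1

    def coastal_lookup(self) -> np.ndarray:
        """Dense ``(ny, nx)`` map of coastal ids (-1 off the coast)."""
        out = np.full(self.shape, -1, dtype=int)
        for cid, (iy, ix) in enumerate(self.coastal_cells):
            out[iy, ix] = cid
        return out

    def coastal_centres(self) -> np.ndarray:
        """``(n, 2)`` array of (x, y) centres of the coastal cells."""
        return np.column_stack(
            [self.x[self.coastal_cells[:, 1]], self.y[self.coastal_cells[:, 0]]]
        )


def _coastal_cells(mask: np.ndarray) -> np.ndarray:
    """Sea cells with >=1 land 8-neighbour, in row-major order."""
    land = ~mask
    near_land = np.zeros_like(mask)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifted = np.zeros_like(mask)
            ys = slice(max(dy, 0), mask.shape[0] + min(dy, 0))
            yd = slice(max(-dy, 0), mask.shape[0] + min(-dy, 0))
            xs = slice(max(dx, 0), mask.shape[1] + min(dx, 0))
            xd = slice(max(-dx, 0), mask.shape[1] + min(-dx, 0))
            shifted[yd, xd] = land[ys, xs]
            near_land |= shifted
    coastal = mask & near_land
    iy, ix = np.nonzero(coastal)  # row-major scan order
    return np.column_stack([iy, ix])


def make_seascape(spec: dict) -> SeascapeGrid:
    """Build a :class:`SeascapeGrid` from a domain descriptor.

    ``spec`` keys: ``nx``, ``ny`` (>= 8 each), ``cell_size`` (default 1.0),
    ``mode``, ``origin`` (x0, y0 of the first cell centre, default (0, 0)),
    and either an explicit boolean ``mask`` (True = sea) or a named
    ``template``:

    - ``"island"``: all sea with a single land cell at the centre;
    - ``"left_land"``: left half of the columns is land (straight vertical
      coastline);
    - ``"south_coast"``: the bottom ``land_rows`` rows (default 2) are land;
    - ``"two_bay"``: a south coast with two rectangular bays carved into it.
    """
    nx, ny = int(spec["nx"]), int(spec["ny"])
    if nx < 8 or ny < 8:
        raise SeascapeError("domain must be at least 8x8 cells")
    cell = float(spec.get("cell_size", 1.0))
    mode = spec.get("mode", "cartesian")
    x0, y0 = spec.get("origin", (0.0, 0.0))
    x = x0 + cell * np.arange(nx)
    y = y0 + cell * np.arange(ny)

    if "mask" in spec:
        mask = np.asarray(spec["mask"], dtype=bool)
    else:
        template = spec.get("template", "island")
        mask = np.ones((ny, nx), dtype=bool)
        if template == "island":
            mask[ny // 2, nx // 2] = False
        elif template == "left_land":
            mask[:, : nx // 2] = False
        elif template == "south_coast":
            rows = int(spec.get("land_rows", 2))
            mask[:rows, :] = False
        elif template == "two_bay":
            rows = int(spec.get("land_rows", 3))
            mask[:rows, :] = False
            w = max(nx // 6, 1)
            for cx in (nx // 4, 3 * nx // 4):
                mask[rows - 1, cx - w // 2 : cx + w // 2 + 1] = True
        else:
            raise SeascapeError(f"unknown template {template!r}")
    if mask.all() or not mask.any():
        raise SeascapeError("domain needs at least one land and one sea cell")
    return SeascapeGrid(x=x, y=y, cell_size=cell, mask=mask, mode=mode)


# ---------------------------------------------------------------------------
# Velocity fields
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Daily ``u``/``v`` surface currents over a :class:`SeascapeGrid`.

    ``u`` and ``v`` have shape ``(time, ny, nx)``; land cells are NaN.
    ``units`` is ``"m/s"`` (default) or ``"km/day"`` (cartesian mode only).
    """

    time: np.ndarray  # np.datetime64[D], strictly increasing, daily
    u: np.ndarray
    v: np.ndarray
    grid: SeascapeGrid
    units: str = "m/s"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[D]")
        if self.u.shape != (self.time.size, *self.grid.shape):
            raise SeascapeError("u shape does not match time axis and grid")
        if self.v.shape != self.u.shape:
            raise SeascapeError("u and v shapes differ")
        if np.any(np.diff(self.time).astype(int) <= 0):
            raise SeascapeError("time axis must be strictly increasing")
        sea = self.grid.mask
        if not (np.isfinite(self.u[:, sea]).all() and np.isfinite(self.v[:, sea]).all()):
            raise SeascapeError("velocities not finite on sea cells")
        if self.units == "km/day" and self.grid.mode != "cartesian":
            raise SeascapeError("km/day units require cartesian mode")

    # -- I/O ----------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "u": (("time", "y", "x"), self.u, {"units": self.units}),
                "v": (("time", "y", "x"), self.v, {"units": self.units}),
                "mask": (("y", "x"), self.grid.mask.astype(np.int8),
                         {"long_name": "sea mask (1=sea)"}),
            },
            coords={"time": self.time.astype("datetime64[ns]"),
                    "y": self.grid.y, "x": self.grid.x},
            # "coord_mode", not "mode": scipy's netCDF3 writer mirrors global
            # attributes onto the file object, where "mode" is reserved
            attrs={"coord_mode": self.grid.mode,
                   "cell_size": self.grid.cell_size},
        )
        return ds

    def save(self, path) -> None:
        # netCDF3 via the scipy engine: self-describing, text-tool friendly
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityField":
        grid = SeascapeGrid(
            x=ds["x"].values, y=ds["y"].values,
            cell_size=float(ds.attrs["cell_size"]),
            mask=ds["mask"].values.astype(bool),
            mode=_decode_attr(ds.attrs.get("coord_mode", "cartesian")),
        )
        return cls(
            time=ds["time"].values.astype("datetime64[D]"),
            u=np.asarray(ds["u"].values, dtype=float),
            v=np.asarray(ds["v"].values, dtype=float),
            grid=grid,
            units=ds["u"].attrs.get("units", "m/s"),
        )

    @classmethod
    def load(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def _component_uv(comp: dict, X: np.ndarray, Y: np.ndarray, x: np.ndarray,
                  y: np.ndarray, amp_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Static (u, v) of one analytic component evaluated on cell centres."""
    kind = comp.get("kind")
    if kind == "uniform":
        u = np.full(X.shape, float(comp.get("u", 0.0)) * amp_scale)
        v = np.full(X.shape, float(comp.get("v", 0.0)) * amp_scale)
        return u, v
    if kind == "jet":
        # Zonal jet: u depends on y only, v = 0 -> divergence-free by design.
        y0 = float(comp["center_y"])
        w = float(comp.get("width", 1.0))
        speed = float(comp["speed"]) * amp_scale
        u = speed * np.exp(-((Y - y0) ** 2) / (2 * w ** 2))
        return u, np.zeros_like(u)
    if kind == "gyre":
        # Gaussian streamfunction psi; u = dpsi/dy, v = -dpsi/dx by central
        # differences, so the discrete divergence vanishes on interior cells.
        x0, y0 = comp["center"]
        sigma = float(comp.get("sigma", 1.0))
        strength = float(comp["strength"]) * amp_scale
        psi = strength * sigma * np.exp(
            -((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sigma ** 2)
        )
        u = np.gradient(psi, y, axis=0)
        v = -np.gradient(psi, x, axis=1)
        return u, v
    raise SeascapeError(f"unknown velocity component kind {comp.get('kind')!r}")


def make_velocity_series(
    grid: SeascapeGrid,
    field_spec: list[dict],
    years: int = 1,
    seed: int = 0,
    days_per_year: int = 365,
    start_year: int = 2002,
    units: str = "m/s",
) -> VelocityField:
    """Compose a multi-year daily velocity series from analytic components.

    ``field_spec`` is a list of component dicts with a ``kind`` key drawn
    from ``{"uniform", "jet", "gyre", "noise"}``.  Deterministic components
    may carry ``annual_jitter`` (fractional amplitude modulation drawn once
    per year from the seeded RNG).  ``noise`` components
    (``{"kind": "noise", "amplitude": a}``) add zero-mean Gaussian cell
    noise redrawn every day.  Identical ``(grid, field_spec, years, seed)``
    give bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA]))
    ny, nx = grid.shape
    X, Y = np.meshgrid(grid.x, grid.y)
    noise_comps = [c for c in field_spec if c.get("kind") == "noise"]
    det_comps = [c for c in field_spec if c.get("kind") != "noise"]
    for c in det_comps:  # validate kinds up front
        if c.get("kind") not in ("uniform", "jet", "gyre"):
            raise SeascapeError(f"unknown velocity component kind {c.get('kind')!r}")

    times, us, vs = [], [], []
    for yr in range(years):
        u_static = np.zeros((ny, nx))
        v_static = np.zeros((ny, nx))
        for comp in det_comps:
            jitter = float(comp.get("annual_jitter", 0.0))
            amp = 1.0 + jitter * rng.standard_normal() if jitter else 1.0
            cu, cv = _component_uv(comp, X, Y, grid.x, grid.y, amp)
            u_static += cu
            v_static += cv
        t0 = np.datetime64(f"{start_year + yr}-01-01", "D")
        t_year = t0 + np.arange(days_per_year)
        u_year = np.broadcast_to(u_static, (days_per_year, ny, nx)).copy()
        v_year = np.broadcast_to(v_static, (days_per_year, ny, nx)).copy()
        for comp in noise_comps:
            a = float(comp["amplitude"])
            u_year += a * rng.standard_normal(u_year.shape)
            v_year += a * rng.standard_normal(v_year.shape)
        times.append(t_year)
        us.append(u_year)
        vs.append(v_year)

    u = np.concatenate(us)
    v = np.concatenate(vs)
    land = ~grid.mask
    u[:, land] = np.nan
    v[:, land] = np.nan
    return VelocityField(time=np.concatenate(times), u=u, v=v, grid=grid,
                         units=units)
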