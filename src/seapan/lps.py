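"""Lagrangian particle simulation of passive larval drift.

Particles are released from coastal cells on a fixed cadence inside a
spawning window, advected hourly through the daily velocity field by
explicit Euler (RK4 optional), and terminate by beaching in a coastal cell
(after a grace period so a particle does not instantly re-beach at its
origin), leaving the domain, or expiring at the maximum drift duration.

Conventions the source procedure leaves open, made explicit here:

- velocity nodes on land are filled with zero before bilinear
  interpolation (conservative: slows particles near shore and promotes
  beaching);
- a particle whose step would land inside a land cell is beached at the
  nearest coastal cell instead (during the grace period the step is
  cancelled and the particle holds position);
- the transport time of a beached particle is its first-entry hour / 24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seascape import M_PER_DEG_LAT, SeascapeGrid, VelocityField

__all__ = [
    "ReleaseSchedule",
    "Trajectory",
    "TrajectorySet",
    "LPSParams",
    "bilinear_velocity",
    "advect_particle",
    "run_simulation",
    "make_release_schedule",
    "OutOfDomainError",
]

HOURS_PER_DAY = 24


class OutOfDomainError(ValueError):
    """Query outside the gridded domain (distinct from a land query)."""


class LPSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters / schedule
# ---------------------------------------------------------------------------

@dataclass
class LPSParams:
    """Integration parameters; defaults mirror the reference procedure
    (hourly positions, 30-day maximum drift) with an explicit 12 h beaching
    grace period."""

    dt_hours: float = 1
    max_days: int = 30
    grace_hours: int = 12
    integrator: str = "euler"    # "euler" (reference behaviour) or "rk4"
    store_paths: bool = False

    def __post_init__(self) -> None:
        if abs(HOURS_PER_DAY / self.dt_hours
               - round(HOURS_PER_DAY / self.dt_hours)) > 1e-9:
            raise LPSError("dt must divide 24 h")
        if self.integrator not in ("euler", "rk4"):
            raise LPSError(f"unknown integrator {self.integrator!r}")


@dataclass
class ReleaseSchedule:
    """Release cells (coastal ids), datetimes, and particles per release."""

    cells: np.ndarray                  # coastal ids
    times: np.ndarray                  # datetime64, within the field span
    particles_per_release: int = 1

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        self.times = np.asarray(self.times, dtype="datetime64[h]")
        if self.cells.size == 0 or self.times.size == 0:
            raise LPSError("empty release schedule")


def make_release_schedule(
    field: VelocityField,
    grid: SeascapeGrid,
    window: tuple[str, str] = ("02-01", "06-30"),
    cadence_hours: int = 12,
    particles_per_release: int = 1,
    cells: np.ndarray | None = None,
) -> ReleaseSchedule:
    """Every ``cadence_hours`` within the ``(MM-DD, MM-DD)`` window of each
    year covered by the field, from all coastal cells by default.

    Release times whose full drift window would outrun the field are kept;
    drift simply ends at the field edge (treated as expiry there).
    """
    years = np.unique(field.time.astype("datetime64[Y]"))
    times = []
    t_end = field.time[-1] + 1  # exclusive end of last day
    for y in years:
        y_str = str(y.astype("datetime64[Y]"))
        start = np.datetime64(f"{y_str}-{window[0]}", "h")
        stop = np.datetime64(f"{y_str}-{window[1]}", "h") + 24
        t = start
        while t < stop:
            if field.time[0].astype("datetime64[h]") <= t < t_end.astype("datetime64[h]"):
                times.append(t)
            t += np.timedelta64(cadence_hours, "h")
    if not times:
        raise LPSError("release window does not overlap the velocity field")
    if cells is None:
        cells = np.arange(grid.n_coastal)
    return ReleaseSchedule(cells=np.asarray(cells), times=np.array(times),
                           particles_per_release=particles_per_release)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _day_index(field: VelocityField, t) -> int:
    """Index of the field day containing t (t floored to the daily step).

    The time axis is daily within years but may have gaps between years;
    searchsorted keeps the mapping correct either way.
    """
    day = np.asarray(t, dtype="datetime64[h]").astype("datetime64[D]")
    idx = int(np.searchsorted(field.time, day, side="right")) - 1
    if idx >= 0 and field.time[idx] != day:
        return -1  # inside a gap between years
    return idx


def _bilinear(grid: SeascapeGrid, comp: np.ndarray, x, y):
    """Bilinear interpolation of one zero-filled component at positions."""
    xv, yv = grid.x, grid.y
    d = grid.cell_size
    fx = np.clip((np.asarray(x, float) - xv[0]) / d, 0.0, xv.size - 1.0)
    fy = np.clip((np.asarray(y, float) - yv[0]) / d, 0.0, yv.size - 1.0)
    ix = np.minimum(fx.astype(int), xv.size - 2)
    iy = np.minimum(fy.astype(int), yv.size - 2)
    tx = fx - ix
    ty = fy - iy
    c00 = comp[iy, ix]
    c10 = comp[iy, ix + 1]
    c01 = comp[iy + 1, ix]
    c11 = comp[iy + 1, ix + 1]
    return (c00 * (1 - tx) * (1 - ty) + c10 * tx * (1 - ty)
            + c01 * (1 - tx) * ty + c11 * tx * ty)


def bilinear_velocity(field: VelocityField, x, y, t):
    """(u, v) at position(s) and time by bilinear interpolation in space on
    the day's field (t floored to the daily step); land nodes contribute
    zero.  Raises :class:`OutOfDomainError` outside the domain."""
    grid = field.grid
    half = grid.cell_size / 2
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any((x < grid.x[0] - half) | (x > grid.x[-1] + half)
              | (y < grid.y[0] - half) | (y > grid.y[-1] + half)):
        raise OutOfDomainError("position outside the gridded domain")
    day = _day_index(field, t)
    if np.any((day < 0) | (day >= field.time.size)):
        raise OutOfDomainError("time outside the velocity field span")
    uf = np.nan_to_num(field.u[int(day)])
    vf = np.nan_to_num(field.v[int(day)])
    return _bilinear(grid, uf, x, y), _bilinear(grid, vf, x, y)


def _velocity_to_step(field: VelocityField, u, v, y, dt_hours: float):
    """Convert velocities to per-step displacements in grid units."""
    if field.grid.mode == "cartesian":
        if field.units == "m/s":
            f = 3.6 * dt_hours  # km per step: u[m/s] * 3.6 (km/h)/(m/s) * h
            return u * f, v * f
        # km/day
        return u * dt_hours / 24.0, v * dt_hours / 24.0
    # geographic: degrees; zonal scaled by cos(latitude)
    m_per_deg_lon = M_PER_DEG_LAT * np.cos(np.radians(y))
    dx = u * 3600.0 * dt_hours / m_per_deg_lon
    dy = v * 3600.0 * dt_hours / M_PER_DEG_LAT
    return dx, dy


def _step_km(grid: SeascapeGrid, x0, y0, x1, y1):
    if grid.mode == "cartesian":
        return np.hypot(x1 - x0, y1 - y0)
    from .seqstats import great_circle_km
    return great_circle_km(y0, x0, y1, x1)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    particle_id: int
    origin_cell: int
    fate: str                    # "beached" | "lost_offshore" | "expired"
    dest_cell: int | None
    transport_days: float | None
    drift_km: float
    year: int
    positions: np.ndarray | None = field(default=None, repr=False)


@dataclass
class TrajectorySet:
    """Tabular summary of trajectories plus run metadata.

    ``table`` columns: particle_id, origin_cell, fate, dest_cell,
    transport_days, drift_km, year.
    """

    table: pd.DataFrame
    meta: dict
    paths: list[np.ndarray] | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "TrajectorySet":
        return cls(table=pd.read_csv(path), meta=meta or {})

    def summary(self) -> dict:
        t = self.table
        beached = t[t.fate == "beached"]
        return {
            "n_particles": len(t),
            "n_beached": len(beached),
            "mean_drift_km": float(t.drift_km.mean()) if len(t) else np.nan,
            "max_drift_km": float(t.drift_km.max()) if len(t) else np.nan,
            "mean_transport_days": (float(beached.transport_days.mean())
                                    if len(beached) else np.nan),
        }


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------

def _advect_batch(field, grid, params, x, y, t0, origins, pid0, rng=None):
    """Advance one batch of particles released simultaneously.

    Returns a list of :class:`Trajectory`.  Vectorized over particles;
    positions are updated hourly until every particle has a fate.
    """
    n = x.size
    lookup = grid.coastal_lookup()
    centres = grid.coastal_centres()
    iy0, ix0 = grid.cell_index(x, y)
    prev_cell = iy0 * grid.shape[1] + ix0  # flat cell index per particle
    alive = np.ones(n, dtype=bool)
    fate = np.array(["expired"] * n, dtype=object)
    dest = np.full(n, -1)
    tdays = np.full(n, np.nan)
    drift = np.zeros(n)
    steps = int(params.max_days * HOURS_PER_DAY / params.dt_hours)
    dt = params.dt_hours
    paths = ([np.full((steps + 1, 2), np.nan) for _ in range(n)]
             if params.store_paths else None)
    if paths is not None:
        for i in range(n):
            paths[i][0] = (x[i], y[i])
    half = grid.cell_size / 2
    t_last = field.time[-1].astype("datetime64[h]") + 24

    def vel(px, py, t):
        day = _day_index(field, t)
        uf = np.nan_to_num(field.u[day])
        vf = np.nan_to_num(field.v[day])
        return _bilinear(grid, uf, px, py), _bilinear(grid, vf, px, py)

    for step in range(1, steps + 1):
        if not alive.any():
            break
        t = t0 + np.timedelta64(int(round((step - 1) * dt * 60)), "m")
        if t >= t_last or _day_index(field, t) < 0:
            # field exhausted (end of span or inter-year gap): per-year runs
            # are independent, so the remaining particles expire here
            break
        idx = np.flatnonzero(alive)
        px, py = x[idx], y[idx]
        if params.integrator == "euler":
            u, v = vel(px, py, t)
            dx, dy = _velocity_to_step(field, u, v, py, dt)
        else:  # RK4 in space on the (piecewise-daily) field
            u1, v1 = vel(px, py, t)
            k1x, k1y = _velocity_to_step(field, u1, v1, py, dt)
            u2, v2 = vel(px + k1x / 2, py + k1y / 2, t)
            k2x, k2y = _velocity_to_step(field, u2, v2, py + k1y / 2, dt)
            u3, v3 = vel(px + k2x / 2, py + k2y / 2, t)
            k3x, k3y = _velocity_to_step(field, u3, v3, py + k2y / 2, dt)
            u4, v4 = vel(px + k3x, py + k3y, t)
            k4x, k4y = _velocity_to_step(field, u4, v4, py + k3y, dt)
            dx = (k1x + 2 * k2x + 2 * k3x + k4x) / 6
            dy = (k1y + 2 * k2y + 2 * k3y + k4y) / 6
        nx_, ny_ = px + dx, py + dy
        hours = step * dt
        in_grace = hours <= params.grace_hours

        out = ((nx_ < grid.x[0] - half) | (nx_ > grid.x[-1] + half)
               | (ny_ < grid.y[0] - half) | (ny_ > grid.y[-1] + half))
        iy, ix = grid.cell_index(np.where(out, px, nx_), np.where(out, py, ny_))
        on_land = ~out & (iy >= 0) & ~grid.mask[iy, ix]
        cid = np.where((iy >= 0) & ~on_land & ~out, lookup[iy, ix], -1)
        flat_cell = iy * grid.shape[1] + ix

        for j, gi in enumerate(idx):
            if out[j]:
                fate[gi] = "lost_offshore"
                alive[gi] = False
                continue
            if on_land[j]:
                if in_grace:
                    continue  # hold position, do not enter land
                # beach at the nearest coastal cell
                dists = _step_km(grid, nx_[j], ny_[j],
                                 centres[:, 0], centres[:, 1])
                near = int(np.argmin(dists))
                fate[gi] = "beached"
                dest[gi] = near
                tdays[gi] = hours / HOURS_PER_DAY
                drift[gi] += _step_km(grid, px[j], py[j], nx_[j], ny_[j])
                alive[gi] = False
                continue
            drift[gi] += _step_km(grid, px[j], py[j], nx_[j], ny_[j])
            x[gi], y[gi] = nx_[j], ny_[j]
            if paths is not None:
                paths[gi][step] = (nx_[j], ny_[j])
            entered = flat_cell[j] != prev_cell[gi]
            prev_cell[gi] = flat_cell[j]
            # beaching is an entry event: a particle that never leaves its
            # cell keeps drifting (and finally expires) rather than
            # re-beaching at its origin
            if cid[j] >= 0 and entered and not in_grace:
                fate[gi] = "beached"
                dest[gi] = cid[j]
                tdays[gi] = hours / HOURS_PER_DAY
                alive[gi] = False

    year = int(str(t0.astype("datetime64[Y]")))
    out_traj = []
    for i in range(n):
        out_traj.append(Trajectory(
            particle_id=pid0 + i,
            origin_cell=int(origins[i]),
            fate=str(fate[i]),
            dest_cell=int(dest[i]) if dest[i] >= 0 else None,
            transport_days=float(tdays[i]) if np.isfinite(tdays[i]) else None,
            drift_km=float(drift[i]),
            year=year,
            positions=paths[i] if paths is not None else None,
        ))
    return out_traj


def advect_particle(field: VelocityField, grid: SeascapeGrid, origin: int,
                    t0, params: LPSParams | None = None) -> Trajectory:
    """Advect a single particle released at a coastal cell centre."""
    params = params or LPSParams(store_paths=True)
    if not 0 <= origin < grid.n_coastal:
        raise LPSError(f"origin {origin} is not a coastal cell id")
    cx, cy = grid.coastal_centres()[origin]
    t0 = np.datetime64(t0, "h")
    trajs = _advect_batch(field, grid, params,
                          np.array([cx], float), np.array([cy], float),
                          t0, np.array([origin]), 0)
    return trajs[0]


def run_simulation(field: VelocityField, grid: SeascapeGrid,
                   schedule: ReleaseSchedule, params: LPSParams | None = None,
                   seed: int = 0) -> TrajectorySet:
    """Run the full particle release programme.

    Particles are released ``particles_per_release`` at a time from every
    schedule cell at every schedule datetime, each with a uniform seeded
    within-cell offset.  Batches are keyed by release time so per-year runs
    are independent and order-insensitive.
    """
    params = params or LPSParams()
    if (schedule.cells >= grid.n_coastal).any() or (schedule.cells < 0).any():
        raise LPSError("schedule contains non-coastal release cells")
    t_lo = field.time[0].astype("datetime64[h]")
    t_hi = field.time[-1].astype("datetime64[h]") + 24
    in_span = (schedule.times >= t_lo) & (schedule.times < t_hi)
    if not in_span.any():
        raise LPSError("no overlap between release schedule and velocity field")
    times = np.sort(schedule.times[in_span])
    centres = grid.coastal_centres()
    trajs: list[Trajectory] = []
    pid = 0
    # one independent stream per release time, keyed by its offset from the
    # earliest release so that runs split by year compose deterministically
    for t0 in times:
        key = int((t0 - t_lo).astype(int))
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1B5, key]))
        ppr = schedule.particles_per_release
        origins = np.repeat(schedule.cells, ppr)
        base = centres[origins]
        off = (rng.random((origins.size, 2)) - 0.5) * grid.cell_size
        x = base[:, 0] + off[:, 0]
        y = base[:, 1] + off[:, 1]
        trajs.extend(_advect_batch(field, grid, params, x, y, t0,
                                   origins, pid))
        pid += origins.size
    table = pd.DataFrame(
        [{k: getattr(t, k) for k in
          ("particle_id", "origin_cell", "fate", "dest_cell",
           "transport_days", "drift_km", "year")} for t in trajs]
    )
    paths = [t.positions for t in trajs] if params.store_paths else None
    meta = {"seed": seed, "n_release_times": int(times.size),
            "particles_per_release": schedule.particles_per_release,
            "dt_hours": params.dt_hours, "max_days": params.max_days,
            "grace_hours": params.grace_hours,
            "integrator": params.integrator}
    ts = TrajectorySet(table=table, meta=meta, paths=paths)
    ts.meta.update(ts.summary())
    return ts
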