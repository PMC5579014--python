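"""Cell-to-cell connectivity matrices from beached trajectories.

``T[i, j]`` is the mean transport time in days of particles released at
coastal cell ``i`` that beached at cell ``j``; ``N[i, j]`` is the particle
count behind the mean.  Entries with no particles are explicit missing
(NaN), never 0 or infinity, so "no connection" stays distinct from
"instantaneous".  The matrix is generally asymmetric and the diagonal
(self-recruitment) is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lps import TrajectorySet
from .seascape import SeascapeGrid

__all__ = ["ConnectivityMatrix", "build_connectivity", "average_years"]


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    T: np.ndarray                    # (n, n) mean transport days, NaN where N=0
    N: np.ndarray                    # (n, n) particle counts
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.N = np.asarray(self.N, dtype=int)
        if self.T.shape != self.N.shape or self.T.ndim != 2 \
                or self.T.shape[0] != self.T.shape[1]:
            raise ConnectivityError("T and N must be matching square matrices")
        defined = self.N > 0
        if np.isnan(self.T[defined]).any():
            raise ConnectivityError("T undefined where N > 0")
        if not np.isnan(self.T[~defined]).all():
            raise ConnectivityError("T defined where N = 0")

    @property
    def n(self) -> int:
        return self.T.shape[0]

    # -- serialization ------------------------------------------------------

    def to_long_csv(self, path) -> None:
        i, j = np.nonzero(self.N)
        pd.DataFrame({"i": i, "j": j, "T_days": self.T[i, j],
                      "N": self.N[i, j]}).to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path, n: int, meta: dict | None = None
                      ) -> "ConnectivityMatrix":
        df = pd.read_csv(path)
        T = np.full((n, n), np.nan)
        N = np.zeros((n, n), dtype=int)
        T[df.i, df.j] = df.T_days
        N[df.i, df.j] = df.N
        return cls(T=T, N=N, meta=meta or {})

    def to_dense_csv(self, path) -> None:
        pd.DataFrame(self.T).to_csv(path, index=False)

    @classmethod
    def from_dense(cls, T: np.ndarray, N: np.ndarray | None = None,
                   meta: dict | None = None) -> "ConnectivityMatrix":
        T = np.asarray(T, dtype=float)
        if N is None:
            N = (~np.isnan(T)).astype(int)
        return cls(T=T, N=N, meta=meta or {})


def build_connectivity(trajset: TrajectorySet, grid: SeascapeGrid
                       ) -> ConnectivityMatrix:
    """Mean transport times over beached particles, per origin/destination.

    Lost and expired particles contribute nothing; the result is invariant
    to trajectory order.
    """
    n = grid.n_coastal
    t = trajset.table
    beached = t[t.fate == "beached"]
    for col in ("origin_cell", "dest_cell"):
        vals = beached[col].to_numpy()
        if len(vals) and ((vals < 0).any() or (vals >= n).any()):
            raise ConnectivityError(f"trajectory references unknown cell in {col}")
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    if len(beached):
        i = beached.origin_cell.to_numpy(int)
        j = beached.dest_cell.to_numpy(int)
        np.add.at(sums, (i, j), beached.transport_days.to_numpy(float))
        np.add.at(counts, (i, j), 1)
    with np.errstate(invalid="ignore"):
        T = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    meta = {"years": sorted(t.year.unique().tolist()) if len(t) else [],
            "n_particles": int(len(t)), "n_beached": int(len(beached))}
    return ConnectivityMatrix(T=T, N=counts, meta=meta)


def average_years(matrices: list[ConnectivityMatrix],
                  weighted: bool = True) -> ConnectivityMatrix:
    """Combine per-year matrices.

    ``weighted=True`` (default) takes the particle-count-weighted mean,
    equivalent to pooling all particles; ``weighted=False`` is the
    unweighted mean over the years in which each edge is defined (the
    literal reading of per-year averaging).  Either way an edge defined in
    any year is defined in the result and counts are summed.
    """
    if not matrices:
        raise ConnectivityError("no matrices to average")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise ConnectivityError("mismatched matrix dimensions")
    Ns = np.stack([m.N for m in matrices])
    Ts = np.stack([m.T for m in matrices])
    N_total = Ns.sum(axis=0)
    if weighted:
        sums = np.where(Ns > 0, Ts * Ns, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            T = np.where(N_total > 0, sums / np.maximum(N_total, 1), np.nan)
    else:
        defined = (Ns > 0).sum(axis=0)
        sums = np.where(Ns > 0, Ts, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            T = np.where(defined > 0, sums / np.maximum(defined, 1), np.nan)
    meta = {"averaging": "count-weighted" if weighted else "unweighted",
            "n_years": len(matrices)}
    return ConnectivityMatrix(T=T, N=N_total, meta=meta)
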