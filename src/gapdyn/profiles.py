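"""Spatio-temporal maternal gradient profiles.

Maternal coordinate proteins (Bcd, Cad) form gradients along the A-P axis
that act as external, time-varying inputs to the gap gene circuit.  They
are represented as tables of concentration over a (position, time) grid
and evaluated at arbitrary coordinates by bilinear interpolation, exactly
reproducing the table at its knots.  Queries outside the table's bounding
box raise (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = ["MaternalProfiles", "interpolate_maternal"]


@dataclass
class MaternalProfiles:
    """Maternal regulator concentrations on a (position, time) grid.

    ``values[k, i, j]`` is the concentration of maternal gene ``names[k]``
    at ``positions[i]`` (% A-P) and ``times[j]`` (minutes).
    """

    names: tuple
    positions: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names), self.positions.size,
                                 self.times.size):
            raise ValueError("values must have shape (n_genes, n_pos, n_times)")
        if np.any(np.diff(self.positions) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("position and time grids must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("maternal concentrations must be >= 0")
        self._interps = [
            RegularGridInterpolator((self.positions, self.times), v,
                                    method="linear", bounds_error=True)
            for v in self.values
        ]

    def position_range(self):
        return float(self.positions[0]), float(self.positions[-1])

    def time_range(self):
        return float(self.times[0]), float(self.times[-1])

    def evaluate(self, position: float, time: float) -> np.ndarray:
        """Concentration vector (one entry per maternal gene) at
        (position, time).  Raises ``ValueError`` outside the grid."""
        pt = np.array([[position, time]], dtype=float)
        try:
            return np.array([float(itp(pt)[0]) for itp in self._interps])
        except ValueError as exc:
            raise ValueError(
                f"maternal profile query ({position}%, {time} min) outside "
                f"table support positions {self.position_range()}, "
                f"times {self.time_range()}"
            ) from exc

    def evaluate_gene(self, gene: str, position, time):
        """Interpolated concentration of one maternal gene; accepts scalar
        or array position/time (broadcast)."""
        k = self.names.index(gene)
        p = np.asarray(position, dtype=float)
        t = np.asarray(time, dtype=float)
        p, t = np.broadcast_arrays(p, t)
        pts = np.stack([p.ravel(), t.ravel()], axis=-1)
        try:
            out = self._interps[k](pts).reshape(p.shape)
        except ValueError as exc:
            raise ValueError(
                f"maternal profile query outside table support "
                f"(positions {self.position_range()}, times {self.time_range()})"
            ) from exc
        return out if out.ndim else float(out)

    def frozen_at(self, position: float, time: float) -> np.ndarray:
        """Alias of :meth:`evaluate`, named for phase-space freezing."""
        return self.evaluate(position, time)

    def subset(self, names) -> "MaternalProfiles":
        idx = [self.names.index(n) for n in names]
        return MaternalProfiles(tuple(names), self.positions.copy(),
                                self.times.copy(), self.values[idx].copy())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position, time_min, gene, concentration."""
        recs = []
        for k, name in enumerate(self.names):
            for i, p in enumerate(self.positions):
                for j, t in enumerate(self.times):
                    recs.append((p, t, name, self.values[k, i, j]))
        return pd.DataFrame(recs, columns=["position", "time_min", "gene",
                                           "concentration"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MaternalProfiles":
        required = {"position", "time_min", "gene", "concentration"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"maternal table missing columns: {sorted(missing)}")
        names = tuple(dict.fromkeys(df["gene"]))
        positions = np.unique(df["position"].to_numpy(dtype=float))
        times = np.unique(df["time_min"].to_numpy(dtype=float))
        values = np.full((len(names), positions.size, times.size), np.nan)
        pidx = {p: i for i, p in enumerate(positions)}
        tidx = {t: j for j, t in enumerate(times)}
        gidx = {g: k for k, g in enumerate(names)}
        for row in df.itertuples(index=False):
            values[gidx[row.gene], pidx[float(row.position)],
                   tidx[float(row.time_min)]] = row.concentration
        if np.any(np.isnan(values)):
            raise ValueError("maternal table is not a complete (position, time) grid")
        return cls(names, positions, times, values)


def interpolate_maternal(table: MaternalProfiles, position: float,
                         time: float) -> np.ndarray:
    """Bilinear interpolation of maternal concentrations at (position, time)."""
    return table.evaluate(position, time)
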