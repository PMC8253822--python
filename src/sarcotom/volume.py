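"""Cubic-voxel 3D density maps and MRC I/O.

A :class:`DensityMap` carries a (z, y, x)-indexed scalar grid, a cubic voxel
size in nm, and the world coordinate of the corner voxel center.  Maps are
written as 32-bit real MRC (mode 2) with the voxel size in the header; I/O
goes through gemmi's CCP4/MRC support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["DensityMap", "read_mrc", "write_mrc", "rotate180_x", "correlation"]


@dataclass
class DensityMap:
    """3D scalar grid with physical voxel size.

    values : (nz, ny, nx) ndarray
    voxel_size : nm, cubic
    origin : (x, y, z) nm coordinate of the voxel-(0,0,0) center
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D grid with positive extents")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def center_world(self) -> np.ndarray:
        """World xyz of the geometric grid center ((n-1)/2 voxel coordinate)."""
        nz, ny, nx = self.values.shape
        return self.origin + self.voxel_size * (np.array([nx, ny, nz]) - 1) / 2.0

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (z, y, x) voxel coordinate of a world xyz point."""
        xyz = np.asarray(xyz, dtype=float)
        rel = (xyz - self.origin) / self.voxel_size
        return rel[..., ::-1]

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size, self.origin.copy())


def write_mrc(dmap: DensityMap, path: str | Path) -> None:
    """Write as MRC mode 2 (32-bit real), voxel size in the header (Angstrom)."""
    vals = np.ascontiguousarray(dmap.values.T, dtype=np.float32)  # x fastest
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(vals)
    nx, ny, nz = vals.shape
    a = dmap.voxel_size * 10.0  # nm -> A
    m.grid.unit_cell = gemmi.UnitCell(nx * a, ny * a, nz * a, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for i, w in enumerate((50, 51, 52)):  # ORIGIN record, Angstrom
        m.set_header_float(w, float(dmap.origin[i]) * 10.0)
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)  # (x, y, z), x fastest
    vx = m.grid.unit_cell.a / arr.shape[0] / 10.0  # A -> nm
    origin = np.array([m.header_float(w) for w in (50, 51, 52)]) / 10.0
    return DensityMap(arr.T.astype(np.float32), vx, origin)


def rotate180_x(dmap: DensityMap) -> DensityMap:
    """Rotate a map by exactly 180 degrees about the x axis through its center.

    (x, y, z) -> (x, -y, -z) about the array center is an index flip on the z
    and y axes, exact for any grid parity.
    """
    return DensityMap(dmap.values[::-1, ::-1, :].copy(), dmap.voxel_size, dmap.origin.copy())


def correlation(a: np.ndarray | DensityMap, b: np.ndarray | DensityMap) -> float:
    """Pearson correlation of two equally-shaped grids."""
    va = a.values if isinstance(a, DensityMap) else np.asarray(a)
    vb = b.values if isinstance(b, DensityMap) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError("shape mismatch")
    va = va.ravel().astype(float) - va.mean()
    vb = vb.ravel().astype(float) - vb.mean()
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.dot(va, vb) / denom)
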