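"""Filament centerline geometry: resampling, tangents, orientation bookkeeping, poses.

Traced filament centerlines are the raw input of every analysis stage.  This
module holds the common containers (:class:`Filament`, :class:`FilamentNetwork`,
:class:`Pose`) and the operations that prepare centerlines for packing analysis
and subtomogram averaging: equal-arc-length resampling, local tangent
estimation, direction unification across a network, and construction of initial
subvolume poses in the zxz Euler convention.

Conventions
-----------
* Lengths are in nanometres; coordinates are right-handed (x, y, z).
* Euler angles (phi, theta, psi) are in degrees, zxz convention, with the
  rotation matrix ``R = Rz(psi) @ Rx(theta) @ Rz(phi)`` acting on column
  vectors.  ``R @ ez`` is independent of phi, so with (theta, psi) chosen from
  the local tangent the filament axis maps onto z and phi is the free in-plane
  rotation about the filament axis.
* ``Filament.polarity`` is +1 when the pointed (minus) end of the filament is
  the *last* point of the stored point order, -1 when it is the first point,
  and ``None`` when unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Filament",
    "FilamentNetwork",
    "Pose",
    "zxz_matrix",
    "angles_from_tangent",
    "matrix_to_zxz",
    "resample_centerline",
    "local_tangents",
    "unify_directions",
    "init_poses",
    "read_network_csv",
    "write_network_csv",
    "read_pose_csv",
    "write_pose_csv",
]

THIN = "thin"
THICK = "thick"


# ---------------------------------------------------------------------------
# containers


@dataclass
class Filament:
    """An ordered 3D centerline with a type tag and optional polarity.

    Parameters
    ----------
    id : int
        Unique identifier within a network.
    type : str
        ``"thin"`` (actin) or ``"thick"`` (myosin).
    points : (n, 3) ndarray
        Ordered centerline coordinates in nm; at least two points, consecutive
        points distinct.
    polarity : int or None
        +1 if the pointed end is the last stored point, -1 if it is the first,
        None if unknown.  Only meaningful for thin filaments.
    """

    id: int
    type: str
    points: np.ndarray
    polarity: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a filament needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.polarity not in (None, 1, -1):
            raise ValueError("polarity must be +1, -1 or None")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def direction(self) -> np.ndarray:
        """Unit end-to-end direction (first point to last point)."""
        d = self.points[-1] - self.points[0]
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("degenerate filament: coincident endpoints")
        return d / n

    def pointed_direction(self) -> np.ndarray:
        """Unit vector from the barbed end toward the pointed end."""
        if self.polarity is None:
            raise ValueError(f"filament {self.id} has no polarity label")
        return self.polarity * self.direction

    def barbed_end(self) -> np.ndarray:
        if self.polarity is None:
            raise ValueError(f"filament {self.id} has no polarity label")
        return self.points[0] if self.polarity == 1 else self.points[-1]

    def pointed_end(self) -> np.ndarray:
        if self.polarity is None:
            raise ValueError(f"filament {self.id} has no polarity label")
        return self.points[-1] if self.polarity == 1 else self.points[0]

    def reversed(self) -> "Filament":
        pol = None if self.polarity is None else -self.polarity
        return Filament(self.id, self.type, self.points[::-1].copy(), pol)


@dataclass
class FilamentNetwork:
    """A collection of filaments with unique ids."""

    filaments: list[Filament] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.filaments]
        if len(set(ids)) != len(ids):
            raise ValueError("filament ids must be unique")

    def __iter__(self) -> Iterator[Filament]:
        return iter(self.filaments)

    def __len__(self) -> int:
        return len(self.filaments)

    def __getitem__(self, fid: int) -> Filament:
        for f in self.filaments:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def of_type(self, ftype: str) -> list[Filament]:
        return [f for f in self.filaments if f.type == ftype]

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.filaments:
            counts[f.type] = counts.get(f.type, 0) + 1
        return counts

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([f.points for f in self.filaments])
        return pts.min(axis=0), pts.max(axis=0)

    def map(self, fn) -> "FilamentNetwork":
        return FilamentNetwork([fn(f) for f in self.filaments])


@dataclass
class Pose:
    """A subvolume anchor: position plus zxz Euler orientation.

    The rotation ``R = Rz(psi) @ Rx(theta) @ Rz(phi)`` maps the reference-frame
    z axis onto the local filament tangent; ``phi`` is the in-plane rotation
    about the filament axis.
    """

    position: np.ndarray
    phi: float
    theta: float
    psi: float
    filament_id: int = -1
    subunit_index: int = -1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.phi = float(self.phi) % 360.0

    def matrix(self) -> np.ndarray:
        return zxz_matrix(self.phi, self.theta, self.psi)

    def tangent(self) -> np.ndarray:
        return self.matrix() @ np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# rotations


def zxz_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix ``Rz(psi) @ Rx(theta) @ Rz(phi)`` (degrees)."""
    return Rotation.from_euler("zxz", [phi, theta, psi], degrees=True).as_matrix()


def matrix_to_zxz(R: np.ndarray) -> tuple[float, float, float]:
    """Factor a rotation matrix into zxz angles (phi, theta, psi), degrees.

    phi is wrapped to [0, 360); in the gimbal case (axis parallel to z)
    psi is set to 0 and the full z-rotation is carried by phi.
    """
    import warnings

    rot = Rotation.from_matrix(R)
    with warnings.catch_warnings():
        # the gimbal-degenerate factorization is resolved explicitly below
        warnings.simplefilter("ignore", UserWarning)
        phi, theta, psi = rot.as_euler("zxz", degrees=True)
    if abs(theta) < 1e-9:  # gimbal: only phi+psi determined
        phi, psi = (phi + psi) % 360.0, 0.0
    return phi % 360.0, float(theta), float(psi)


def angles_from_tangent(tangent: np.ndarray) -> tuple[float, float]:
    """(theta, psi) such that ``Rz(psi) @ Rx(theta)`` maps +z onto `tangent`.

    theta is the polar angle of the tangent from +z; psi its azimuth.  For a
    tangent parallel to z (gimbal case) psi = 0.
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    theta = float(np.degrees(np.arccos(np.clip(t[2], -1.0, 1.0))))
    if abs(np.sin(np.radians(theta))) < 1e-12:
        return theta, 0.0
    psi = float(np.degrees(np.arctan2(t[0], -t[1])))
    return theta, psi


# ---------------------------------------------------------------------------
# centerline operations


def resample_centerline(filament: Filament, step: float) -> Filament:
    """Resample a polyline to points equally spaced by `step` along its arc.

    The first point is preserved; subsequent points sit at arc lengths
    ``step, 2*step, ...`` up to the total arc length (the original far endpoint
    is reproduced exactly when the arc length is a multiple of `step`).
    Point order, and hence any polarity label, is preserved.
    """
    L = filament.arc_length
    if step <= 0:
        raise ValueError("step must be positive")
    if L == 0:
        raise ValueError("degenerate filament: zero arc length")
    if step > L * (1 + 1e-9):
        raise ValueError(f"step {step} exceeds arc length {L}")
    seg = np.linalg.norm(np.diff(filament.points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_steps = int(np.floor(L / step + 1e-9))
    targets = np.arange(n_steps + 1) * step
    pts = np.column_stack(
        [np.interp(targets, s, filament.points[:, k]) for k in range(3)]
    )
    return replace(filament, points=pts)


def local_tangents(filament: Filament) -> np.ndarray:
    """Unit tangent per point: central differences inside, one-sided at ends."""
    pts = filament.points
    t = np.empty_like(pts)
    t[0] = pts[1] - pts[0]
    t[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        t[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    return t / norms


def unify_directions(network: FilamentNetwork) -> FilamentNetwork:
    """Flip filament point orders onto a common direction.

    The common direction is the first principal axis of all local tangent
    orientations (second-moment eigenvector, insensitive to tangent sign).
    Each filament whose end-to-end direction has a negative dot product with
    that axis is reversed; an exactly-zero dot product is broken by
    lexicographic comparison of the two endpoints.  Applying the operation
    twice equals applying it once.
    """
    if len(network) == 0:
        raise ValueError("empty network")
    tangents = np.vstack([local_tangents(f) for f in network])
    M = tangents.T @ tangents
    w, v = np.linalg.eigh(M)
    pc1 = v[:, np.argmax(w)]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(pc1)))
    if pc1[k] < 0:
        pc1 = -pc1

    out = []
    for f in network:
        d = np.dot(f.direction, pc1)
        if d < 0:
            out.append(f.reversed())
        elif d == 0:
            a, b = f.points[0], f.points[-1]
            out.append(f.reversed() if tuple(b) < tuple(a) else f)
        else:
            out.append(f)
    return FilamentNetwork(out)


def init_poses(
    filament: Filament,
    phi_step: float = 30.0,
    seed: Optional[int | np.random.Generator] = None,
) -> list[Pose]:
    """One pose per centerline point, with randomized in-plane angle.

    (theta, psi) are set from the local tangent so the rotation carries the
    unit z axis onto it; the in-plane angle phi, unconstrained by the tomogram,
    is drawn i.i.d. uniformly from the grid {0, phi_step, 2*phi_step, ...}.
    Positions are the centerline points, untouched.
    """
    if phi_step <= 0 or abs(360.0 / phi_step - round(360.0 / phi_step)) > 1e-9:
        raise ValueError("phi_step must divide 360")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_phi = int(round(360.0 / phi_step))
    tangents = local_tangents(filament)
    poses = []
    for i, (p, t) in enumerate(zip(filament.points, tangents)):
        theta, psi = angles_from_tangent(t)
        phi = phi_step * rng.integers(n_phi)
        poses.append(Pose(p.copy(), phi, theta, psi, filament.id, i))
    return poses


# ---------------------------------------------------------------------------
# CSV I/O (shared dialect: filament_id, type, polarity, point_index, x/y/z_nm)


def write_network_csv(network: FilamentNetwork, path: str | Path) -> None:
    rows = []
    for f in network:
        pol = "" if f.polarity is None else f.polarity
        for i, p in enumerate(f.points):
            rows.append((f.id, f.type, pol, i, p[0], p[1], p[2]))
    df = pd.DataFrame(
        rows,
        columns=["filament_id", "type", "polarity", "point_index", "x_nm", "y_nm", "z_nm"],
    )
    df.to_csv(path, index=False)


def read_network_csv(path: str | Path) -> FilamentNetwork:
    df = pd.read_csv(path)
    fils = []
    for fid, grp in df.groupby("filament_id", sort=True):
        grp = grp.sort_values("point_index")
        pol = grp["polarity"].iloc[0]
        pol = None if pd.isna(pol) or pol == "" else int(pol)
        fils.append(
            Filament(
                int(fid),
                str(grp["type"].iloc[0]),
                grp[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                pol,
            )
        )
    return FilamentNetwork(fils)


def write_pose_csv(poses: Sequence[Pose], path: str | Path, scores: Optional[Sequence[float]] = None) -> None:
    rows = []
    for i, p in enumerate(poses):
        row = {
            "filament_id": p.filament_id,
            "subunit_index": p.subunit_index,
            "x_nm": p.position[0],
            "y_nm": p.position[1],
            "z_nm": p.position[2],
            "phi_deg": p.phi,
            "theta_deg": p.theta,
            "psi_deg": p.psi,
        }
        if scores is not None:
            row["score"] = scores[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pose_csv(path: str | Path) -> list[Pose]:
    df = pd.read_csv(path)
    return [
        Pose(
            np.array([r.x_nm, r.y_nm, r.z_nm]),
            r.phi_deg,
            r.theta_deg,
            r.psi_deg,
            int(r.filament_id),
            int(r.subunit_index),
        )
        for r in df.itertuples()
    ]
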