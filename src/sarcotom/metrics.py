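"""Polarity-derived sarcomere metrics.

Once thin filaments carry polarity labels, the sarcomere architecture can be
read directly from the geometry: gaps where filaments face each other with
their barbed ends locate Z-disks; encounters of pointed ends locate M-lines;
the axial interpenetration of opposite-polarity arrays at an M-line is the
thin-filament overlap, the structural signature of contraction.  Refined
subunit poses additionally yield the helical rise and twist of the filament,
and two subtomogram averages can be compared for an azimuthal shift of the
tropomyosin strands on the actin surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import THIN, Filament, FilamentNetwork, Pose, local_tangents
from .subtomo import PolarityCall
from .volume import DensityMap

__all__ = [
    "SarcomereAnnotation",
    "HelicalEstimate",
    "principal_axis",
    "apply_polarity_calls",
    "annotate_sarcomeres",
    "measure_overlap",
    "estimate_helix",
    "tpm_azimuth_shift",
    "export_polarity_arrows",
]

logger = logging.getLogger(__name__)


@dataclass
class SarcomereAnnotation:
    """Axial sarcomere architecture (all positions along the myofibril axis).

    Z-disks and M-lines alternate; overlap_fractions are percentages of the
    flanking sarcomere length (NaN where an M-line lacks a flanking Z-disk
    on either side).
    """

    z_disk_positions: np.ndarray
    m_line_positions: np.ndarray
    sarcomere_lengths: np.ndarray
    overlap_lengths: np.ndarray
    overlap_fractions: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def to_json_dict(self) -> dict:
        return {
            "z_disk_positions_nm": self.z_disk_positions.tolist(),
            "m_line_positions_nm": self.m_line_positions.tolist(),
            "sarcomere_lengths_nm": self.sarcomere_lengths.tolist(),
            "overlap_lengths_nm": self.overlap_lengths.tolist(),
            "overlap_fractions_percent": self.overlap_fractions.tolist(),
            "axis": self.axis.tolist(),
        }


@dataclass
class HelicalEstimate:
    """Helical parameters estimated from refined subunit poses."""

    rise: float
    twist: float
    repeat: float
    subunits_per_repeat: int
    n_pairs: int


def principal_axis(network: FilamentNetwork) -> np.ndarray:
    """First principal axis of all local tangents (sign-fixed, unit length)."""
    tangents = np.vstack([local_tangents(f) for f in network])
    M = tangents.T @ tangents
    w, v = np.linalg.eigh(M)
    ax = v[:, np.argmax(w)]
    k = int(np.argmax(np.abs(ax)))
    return ax if ax[k] > 0 else -ax


def apply_polarity_calls(
    network: FilamentNetwork, calls: dict[int, PolarityCall]
) -> FilamentNetwork:
    """Transfer polarity calls onto filaments.

    Assumes the network's point orders were unified before pose generation:
    a filament called "A" matched the forward reference along its point
    order (pointed end last, polarity +1); "B" is the 180-degree flip
    (polarity -1).  Unassigned filaments keep polarity None.
    """
    out = []
    for f in network:
        c = calls.get(f.id)
        pol = None
        if c is not None and c.call == "A":
            pol = 1
        elif c is not None and c.call == "B":
            pol = -1
        out.append(Filament(f.id, f.type, f.points.copy(), pol))
    return FilamentNetwork(out)


# ---------------------------------------------------------------------------
# Z-disk / M-line annotation


def _cluster_1d(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split sorted value indices into clusters separated by > gap."""
    order = np.argsort(values)
    clusters: list[list[int]] = [[order[0]]]
    for i in order[1:]:
        if values[i] - values[clusters[-1][-1]] > gap:
            clusters.append([i])
        else:
            clusters[-1].append(i)
    return [np.array(c) for c in clusters]


def annotate_sarcomeres(
    network: FilamentNetwork,
    axis: Optional[np.ndarray] = None,
    cluster_gap: float = 300.0,
    min_confident_fraction: float = 0.6,
) -> SarcomereAnnotation:
    """Locate Z-disks and M-lines from polarity-labeled thin filaments.

    Thin filaments are grouped into half-sarcomere arrays by polarity and
    barbed-end position (1D clustering with cluster_gap).  A left-pointing
    array followed by a right-pointing one is a Z-disk (position: midpoint of
    the facing barbed-end gap); the reverse succession is an M-line
    (position: midpoint of the pointed-end overlap interval, which is also
    the midpoint of the gap when the overlap is zero).  Sarcomere lengths
    are distances between consecutive Z-disks; each M-line's overlap is the
    maximal pointed-end interpenetration of the flanking arrays.
    """
    thins = network.of_type(THIN)
    if not thins:
        raise ValueError("no thin filaments")
    labeled = [f for f in thins if f.polarity is not None]
    if len(labeled) < min_confident_fraction * len(thins):
        raise ValueError(
            f"only {len(labeled)}/{len(thins)} thin filaments carry polarity "
            f"calls (< {min_confident_fraction:.0%})"
        )
    if axis is None:
        axis = principal_axis(network)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    barbed = np.array([float(np.dot(f.barbed_end(), axis)) for f in labeled])
    pointed = np.array([float(np.dot(f.pointed_end(), axis)) for f in labeled])
    sign = np.sign(pointed - barbed).astype(int)
    if len(set(sign)) < 2:
        logger.warning("uniform polarity: no Z-disk or M-line found")
        empty = np.array([])
        return SarcomereAnnotation(empty, empty, empty, empty, empty, axis)

    # half-sarcomere groups: cluster barbed positions within each polarity
    groups = []
    for s in (-1, 1):
        idx = np.nonzero(sign == s)[0]
        if not len(idx):
            continue
        for cl in _cluster_1d(barbed[idx], cluster_gap):
            members = idx[cl]
            groups.append(
                {
                    "sign": s,
                    "barbed_mean": float(barbed[members].mean()),
                    "pointed_far": float(
                        pointed[members].max() if s == 1 else pointed[members].min()
                    ),
                    "members": members,
                }
            )
    groups.sort(key=lambda g: g["barbed_mean"])

    z_positions, m_positions, overlaps = [], [], []
    # boundary arrays have no partner across the outermost Z-disks: estimate
    # those Z positions one-sidedly from the barbed-end cluster (the estimate
    # is off by half the Z-disk gap, i.e. within half a Z-disk width)
    if groups[0]["sign"] == 1:
        z_positions.append(groups[0]["barbed_mean"])
    for g1, g2 in zip(groups[:-1], groups[1:]):
        if g1["sign"] == -1 and g2["sign"] == 1:
            z_positions.append(0.5 * (g1["barbed_mean"] + g2["barbed_mean"]))
        elif g1["sign"] == 1 and g2["sign"] == -1:
            p_plus, p_minus = g1["pointed_far"], g2["pointed_far"]
            m_positions.append(0.5 * (p_plus + p_minus))
            overlaps.append(max(0.0, p_plus - p_minus))
    if groups[-1]["sign"] == -1:
        z_positions.append(groups[-1]["barbed_mean"])

    z_positions = np.array(z_positions)
    m_positions = np.array(m_positions)
    overlaps = np.array(overlaps)
    lengths = np.diff(z_positions) if len(z_positions) > 1 else np.array([])

    fractions = np.full(len(m_positions), np.nan)
    for i, m in enumerate(m_positions):
        left = z_positions[z_positions < m]
        right = z_positions[z_positions > m]
        if len(left) and len(right):
            fractions[i] = 100.0 * overlaps[i] / (right.min() - left.max())
    return SarcomereAnnotation(z_positions, m_positions, lengths, overlaps, fractions, axis)


def measure_overlap(
    network: FilamentNetwork,
    m_line_position: float,
    axis: Optional[np.ndarray] = None,
    annotation: Optional[SarcomereAnnotation] = None,
    window: Optional[float] = None,
) -> tuple[float, Optional[float], int]:
    """Thin-filament overlap at one M-line.

    The overlap is the maximum, over opposite-polarity thin-filament pairs
    bridging the M-line, of the axial interpenetration of their pointed-end
    extents, clipped at zero.  The fraction is relative to the flanking
    sarcomere length (None when a flanking Z-disk is missing on either
    side).  Returns (overlap nm, fraction percent or None, bridging pairs).
    """
    if annotation is None:
        annotation = annotate_sarcomeres(network, axis=axis)
    axis = annotation.axis
    if window is None:
        window = (
            0.45 * float(np.mean(annotation.sarcomere_lengths))
            if len(annotation.sarcomere_lengths)
            else 450.0
        )
    labeled = [f for f in network.of_type(THIN) if f.polarity is not None]
    p_plus = [
        float(np.dot(f.pointed_end(), axis))
        for f in labeled
        if np.dot(f.pointed_direction(), axis) > 0
        and abs(np.dot(f.pointed_end(), axis) - m_line_position) <= window
    ]
    p_minus = [
        float(np.dot(f.pointed_end(), axis))
        for f in labeled
        if np.dot(f.pointed_direction(), axis) < 0
        and abs(np.dot(f.pointed_end(), axis) - m_line_position) <= window
    ]
    if not p_plus or not p_minus:
        return 0.0, None, 0
    overlap = max(0.0, max(p_plus) - min(p_minus))
    n_pairs = sum(pp > pm for pp in p_plus for pm in p_minus)

    fraction: Optional[float] = None
    z = annotation.z_disk_positions
    left = z[z < m_line_position]
    right = z[z > m_line_position]
    if len(left) and len(right):
        fraction = 100.0 * overlap / (right.min() - left.max())
    return overlap, fraction, n_pairs


# ---------------------------------------------------------------------------
# helical parameters


def _wrap180(a: float) -> float:
    return -((-a + 180.0) % 360.0 - 180.0)


def estimate_helix(
    poses: Sequence[Pose],
    max_subunits_per_repeat: int = 28,
    repeat_tolerance_deg: float = 15.0,
) -> HelicalEstimate:
    """Helical rise and twist from deduplicated refined subunit poses.

    rise: mean axial spacing between consecutive-subunit poses, projected on
    the filament direction.  twist: signed circular mean of consecutive
    in-plane rotation (phi) differences.  The repeat is
    subunits_per_repeat x rise, with subunits_per_repeat the smallest n (up
    to max_subunits_per_repeat) for which n twists return the azimuth to
    within repeat_tolerance_deg of a full turn — the crossover pseudo-repeat
    of the actin helix (13 subunits for the canonical geometry).
    """
    by_fil: dict[int, list[Pose]] = {}
    for p in poses:
        by_fil.setdefault(p.filament_id, []).append(p)

    d_axial: list[float] = []
    d_phi: list[float] = []
    for fid, fposes in by_fil.items():
        if len(fposes) < 3:
            continue
        fposes = sorted(fposes, key=lambda p: p.subunit_index)
        tangents = np.array([p.tangent() for p in fposes])
        axis = tangents.mean(axis=0)
        axis /= np.linalg.norm(axis)
        for a, b in zip(fposes[:-1], fposes[1:]):
            if b.subunit_index - a.subunit_index != 1:
                continue
            d_axial.append(abs(float(np.dot(b.position - a.position, axis))))
            d_phi.append(_wrap180(b.phi - a.phi))
    if not d_axial:
        raise ValueError("need at least one filament with >= 3 subunit poses")

    rise = float(np.mean(d_axial))
    ang = np.radians(d_phi)
    twist = float(_wrap180(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()))))

    residues = [abs(_wrap180(n * twist)) for n in range(1, max_subunits_per_repeat + 1)]
    ok = [n for n, r in zip(range(1, max_subunits_per_repeat + 1), residues) if r <= repeat_tolerance_deg]
    n_rep = ok[0] if ok else int(np.argmin(residues)) + 1
    return HelicalEstimate(rise, twist, n_rep * rise, n_rep, len(d_axial))


# ---------------------------------------------------------------------------
# tropomyosin azimuth


def _azimuthal_profile(
    dmap: DensityMap, radius: float, dr: float, n_az: int, z_frac: float
) -> np.ndarray:
    """Mean intensity per azimuth bin on a cylindrical shell about z."""
    nz, ny, nx = dmap.values.shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az = np.radians(np.arange(n_az) * (360.0 / n_az))
    rr = np.linspace(radius - dr, radius + dr, 5) / dmap.voxel_size
    half = z_frac * nz / 2.0
    zz = np.linspace(cz - half, cz + half, max(int(2 * half), 2))
    A, R, Z = np.meshgrid(az, rr, zz, indexing="ij")
    X = cx + R * np.cos(A)
    Y = cy + R * np.sin(A)
    coords = np.stack([Z.ravel(), Y.ravel(), X.ravel()])
    vals = ndimage.map_coordinates(
        dmap.values.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    ).reshape(A.shape)
    # keep z resolved: averaging over z would wash out the helically
    # twisting tropomyosin strands
    return vals.mean(axis=1)  # (azimuth, z)


def tpm_azimuth_shift(
    map_a: DensityMap,
    map_b: DensityMap,
    radius: float = 4.8,
    dr: float = 0.8,
    az_bin_deg: float = 2.0,
    z_frac: float = 0.6,
) -> float:
    """Azimuthal shift (degrees) of the tropomyosin density between two maps.

    Both maps must share geometry and be aligned to a common filament axis
    (z).  Azimuthal intensity profiles on a cylindrical shell at the
    tropomyosin radius are circularly cross-correlated; the returned shift
    maximizes the correlation and is folded to (-90, 90] — the two-strand
    180-degree ambiguity is resolved to the smaller absolute shift.
    Positive values mean map_b is rotated by +shift relative to map_a.
    """
    if map_a.values.shape != map_b.values.shape or abs(map_a.voxel_size - map_b.voxel_size) > 1e-9:
        raise ValueError("maps must share box and voxel size (register mismatch)")
    n_az = int(round(360.0 / az_bin_deg))
    pa = _azimuthal_profile(map_a, radius, dr, n_az, z_frac)
    pb = _azimuthal_profile(map_b, radius, dr, n_az, z_frac)
    pa = pa - pa.mean(axis=0, keepdims=True)
    pb = pb - pb.mean(axis=0, keepdims=True)
    corr = np.fft.irfft(
        np.conj(np.fft.rfft(pa, axis=0)) * np.fft.rfft(pb, axis=0), n=n_az, axis=0
    ).sum(axis=1)
    k = int(np.argmax(corr))
    # parabolic sub-bin refinement
    c0, c1, c2 = corr[(k - 1) % n_az], corr[k], corr[(k + 1) % n_az]
    denom = c0 - 2 * c1 + c2
    frac = 0.5 * (c0 - c2) / denom if denom < -1e-12 else 0.0
    shift = (k + frac) * az_bin_deg
    shift = _wrap180(shift)
    if shift > 90.0:
        shift -= 180.0
    elif shift <= -90.0:
        shift += 180.0
    return float(shift)


# ---------------------------------------------------------------------------
# visualization export


def export_polarity_arrows(
    network: FilamentNetwork, path: str | Path
) -> tuple[int, int]:
    """Write one arrow per polarity-assigned filament (barbed to pointed end).

    The output is a plain-text segment table loadable by common 3D viewers:
    columns start_x/y/z_nm, end_x/y/z_nm, color (by polarity sign).
    Unassigned filaments are written to a companion file with suffix
    ``.unassigned.csv`` as bare segments.  Returns (arrows, unassigned).
    """
    path = Path(path)
    rows, rows_un = [], []
    for f in network.of_type(THIN):
        if f.polarity is None:
            a, b = f.points[0], f.points[-1]
            rows_un.append([f.id, *a, *b])
        else:
            a, b = f.barbed_end(), f.pointed_end()
            color = "red" if np.dot(f.pointed_direction(), [1, 0, 0]) >= 0 else "blue"
            rows.append([f.id, *a, *b, color])
    cols = ["filament_id", "start_x_nm", "start_y_nm", "start_z_nm",
            "end_x_nm", "end_y_nm", "end_z_nm"]
    pd.DataFrame(rows, columns=cols + ["color"]).to_csv(path, index=False)
    pd.DataFrame(rows_un, columns=cols).to_csv(
        path.with_suffix(".unassigned.csv"), index=False
    )
    return len(rows), len(rows_un)
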