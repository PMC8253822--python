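"""Subtomogram extraction, constrained alignment, averaging, and polarity.

The polarity of a thin filament is not visible in a raw tomogram slice; it is
recovered statistically.  Subvolumes sampled densely along each filament are
aligned against two references related by a 180-degree rotation about x (the
two possible polarities).  Per filament, the two score samples are compared
with an unpaired Student's t-test: a significant difference assigns the
filament the higher-scoring polarity, otherwise it stays unassigned.

Alignment maximizes a masked normalized cross-correlation over a rotation
grid and a constrained translation window: shifts along the filament axis
(the reference z axis) are limited to half an actin subunit rise by default,
so alignment cannot slide a subvolume onto the neighboring subunit.

Averaging resamples every subvolume into the reference frame through the
inverse of its (refined) pose and takes a uniform voxel-wise mean; map
quality is monitored with Fourier shell correlation between independent
half-set averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy import ndimage, stats

from .geometry import Pose, matrix_to_zxz, zxz_matrix
from .volume import DensityMap

__all__ = [
    "Subvolume",
    "AlignmentResult",
    "PolarityCall",
    "FSCCurve",
    "AngularSearch",
    "soft_cylinder_mask",
    "rotate_density",
    "extract_subvolumes",
    "align_subvolume",
    "score_subvolumes",
    "average_subvolumes",
    "iterate_alignment",
    "dedupe_positions",
    "fsc",
    "assign_polarity",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class Subvolume:
    """A cubic crop of a tomogram together with the pose it was taken at."""

    values: np.ndarray
    voxel_size: float
    source_pose: Pose
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        s = self.values.shape
        if len(s) != 3 or s[0] != s[1] or s[1] != s[2]:
            raise ValueError("subvolumes must be cubic")

    @property
    def box(self) -> int:
        return self.values.shape[0]

    def center_world(self) -> np.ndarray:
        n = self.box
        return self.origin + self.voxel_size * (n - 1) / 2.0


@dataclass
class AlignmentResult:
    pose: Pose
    score: float


@dataclass
class PolarityCall:
    """Per-filament polarity decision from two-reference alignment scores."""

    filament_id: int
    n_subvolumes: int
    mean_score_a: float
    mean_score_b: float
    p_value: float
    call: str  # "A", "B", or "unassigned"


@dataclass
class FSCCurve:
    frequencies: np.ndarray  # 1/nm, increasing
    correlations: np.ndarray
    resolution: float  # nm at the 0.143 crossing (Nyquist-limited)

    @property
    def resolution_angstrom(self) -> float:
        return 10.0 * self.resolution


@dataclass
class AngularSearch:
    """Rotation grid for alignment.

    mode "inplane": global search of the in-plane angle phi on a step-degree
    grid (the full circle).  mode "local": refinement of all three zxz angles
    on a +/-range_deg grid at step_deg spacing around the current pose.
    """

    mode: str
    step_deg: float
    range_deg: float = 0.0

    @classmethod
    def inplane(cls, step_deg: float = 10.0) -> "AngularSearch":
        return cls("inplane", step_deg)

    @classmethod
    def local(cls, range_deg: float = 10.0, step_deg: float = 2.0) -> "AngularSearch":
        return cls("local", step_deg, range_deg)

    def rotations(self) -> list[np.ndarray]:
        """Delta rotations applied on top of the current pose."""
        if self.mode == "inplane":
            if self.step_deg <= 0:
                raise ValueError("empty search grid")
            phis = np.arange(0.0, 360.0, self.step_deg)
            return [zxz_matrix(p, 0.0, 0.0) for p in phis]
        if self.mode == "local":
            if self.step_deg <= 0 or self.range_deg < 0:
                raise ValueError("empty search grid")
            grid = np.arange(-self.range_deg, self.range_deg + 1e-9, self.step_deg)
            return [
                zxz_matrix(dphi, dtheta, dpsi)
                for dphi in grid
                for dtheta in grid
                for dpsi in grid
            ]
        raise ValueError(f"unknown search mode {self.mode!r}")


# ---------------------------------------------------------------------------
# geometry helpers


def rotate_density(values: np.ndarray, R: np.ndarray, order: int = 1) -> np.ndarray:
    """Rotate a (z, y, x) density about its array center: out(x) = in(R x).

    R is a world (x, y, z) rotation matrix; in index space the matrix becomes
    R with both axis orders reversed.
    """
    A = R[::-1, ::-1]
    c = (np.array(values.shape) - 1) / 2.0
    return ndimage.affine_transform(
        values, A, offset=c - A @ c, order=order, mode="constant", cval=0.0
    )


def resample_to_reference(sub: Subvolume, pose: Pose, box: int, voxel_size: float,
                          order: int = 1) -> np.ndarray:
    """Resample a subvolume into the reference frame of `pose`.

    The output grid is a centered cubic box in the reference frame; output
    voxel u maps to world position pose.position + R @ x(u), which is looked
    up in the subvolume.  Rotation and (sub-voxel) translation are applied in
    a single trilinear resampling.
    """
    R = pose.matrix()
    A = R[::-1, ::-1]  # index-space rotation (zyx)
    c_out = (box - 1) / 2.0 * np.ones(3)
    shift = (pose.position - sub.origin)[::-1] / sub.voxel_size  # zyx voxels
    scale = voxel_size / sub.voxel_size
    return ndimage.affine_transform(
        sub.values,
        A * scale,
        offset=shift - (A * scale) @ c_out,
        output_shape=(box, box, box),
        order=order,
        mode="constant",
        cval=0.0,
    )


def soft_cylinder_mask(
    box: int, radius_frac: float = 0.4, soft_vox: float = 2.0
) -> np.ndarray:
    """Soft cylindrical mask about the z axis of a cubic box (values in [0,1])."""
    c = (box - 1) / 2.0
    y = np.arange(box) - c
    r = np.hypot(y[:, None], y[None, :])  # transverse radius in voxels
    radius = radius_frac * box
    m2d = np.clip((radius - r) / soft_vox + 0.5, 0.0, 1.0)
    zprof = np.clip((0.45 * box - np.abs(np.arange(box) - c)) / soft_vox + 0.5, 0.0, 1.0)
    return (zprof[:, None, None] * m2d[None, :, :]).astype(np.float64)


# ---------------------------------------------------------------------------
# extraction


def extract_subvolumes(
    dmap: DensityMap, poses: Sequence[Pose], box: int
) -> tuple[list[Subvolume], int]:
    """Axis-aligned cubic crops centered at the pose positions.

    Crops are centered on the nearest voxel.  Poses whose box does not fit
    inside the map are skipped (their count is returned and logged), not an
    error.
    """
    subs = []
    skipped = 0
    nz, ny, nx = dmap.values.shape
    half = box // 2
    for pose in poses:
        czyx = np.round(dmap.world_to_voxel(pose.position)).astype(int)
        lo = czyx - half
        hi = lo + box
        if np.any(lo < 0) or np.any(hi > np.array([nz, ny, nx])):
            skipped += 1
            continue
        vals = dmap.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        origin = dmap.origin + dmap.voxel_size * lo[::-1]
        subs.append(Subvolume(vals.copy(), dmap.voxel_size, pose, origin))
    if skipped:
        logger.warning("extract_subvolumes: skipped %d out-of-bounds poses", skipped)
    return subs, skipped


# ---------------------------------------------------------------------------
# masked NCC scoring


class _ReferenceBank:
    """Rotated-and-masked reference FFTs, shared across subvolumes."""

    def __init__(self, ref: np.ndarray, mask: np.ndarray, rotations: Sequence[np.ndarray]):
        self.rotations = list(rotations)
        self.mask = mask
        self.wsum = float(mask.sum())
        self.f_mask = np.conj(spfft.rfftn(mask))
        self.entries = []
        for Q in self.rotations:
            refq = rotate_density(ref, Q)
            wr = mask * refq
            swr = float(wr.sum())
            var = float((mask * refq**2).sum()) - swr**2 / self.wsum
            sigma = np.sqrt(max(var, 1e-30))
            self.entries.append((np.conj(spfft.rfftn(wr)), swr, sigma))


def _shift_window(box: int, n_ax: int, n_tr: int):
    """Index/offset arrays for the allowed shifts, in monotone offset order."""
    oz = np.arange(-n_ax, n_ax + 1)
    ot = np.arange(-n_tr, n_tr + 1)
    return (oz % box, ot % box, ot % box), (oz, ot, ot)


def score_subvolumes(
    subs: Sequence[Subvolume],
    ref: DensityMap,
    search: AngularSearch,
    shift_limit: float = 1.38,
    transverse_limit: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
    base_poses: Optional[Sequence[Pose]] = None,
    batch: int = 64,
) -> list[AlignmentResult]:
    """Align each subvolume against a reference over a rotation grid.

    Each subvolume is resampled into the reference frame through the inverse
    of its base pose; candidate delta rotations (shared across subvolumes,
    so rotated references are computed once) and a constrained translation
    window are searched for the maximum masked normalized cross-correlation.
    The translation is limited to shift_limit nm along the filament axis
    (reference z) and transverse_limit nm (default two voxels) sideways.

    Returns one :class:`AlignmentResult` per subvolume with the composed
    refined pose and its score.
    """
    subs = list(subs)
    if not subs:
        return []
    box = ref.values.shape[0]
    vox = ref.voxel_size
    if mask is None:
        mask = soft_cylinder_mask(box)
    rotations = search.rotations()
    if not rotations:
        raise ValueError("empty search grid")
    if base_poses is None:
        base_poses = [s.source_pose for s in subs]

    bank = _ReferenceBank(ref.values.astype(np.float64), mask, rotations)
    n_ax = int(np.floor(shift_limit / vox + 1e-9))
    if transverse_limit is None:
        transverse_limit = 2.0 * vox
    n_tr = int(np.floor(transverse_limit / vox + 1e-9))
    (iz, iy, ix), (oz, oy, ox) = _shift_window(box, n_ax, n_tr)

    results: list[AlignmentResult] = [None] * len(subs)  # type: ignore[list-item]
    for start in range(0, len(subs), batch):
        chunk = list(range(start, min(start + batch, len(subs))))
        vols = np.stack(
            [
                resample_to_reference(subs[i], base_poses[i], box, vox)
                for i in chunk
            ]
        ).astype(np.float64)
        f_sub = spfft.rfftn(vols, axes=(1, 2, 3))
        f_sub2 = spfft.rfftn(vols**2, axes=(1, 2, 3))
        s_w = spfft.irfftn(bank.f_mask[None] * f_sub, s=(box,) * 3, axes=(1, 2, 3))
        s_w2 = spfft.irfftn(bank.f_mask[None] * f_sub2, s=(box,) * 3, axes=(1, 2, 3))
        var_sub = s_w2 - s_w**2 / bank.wsum
        denom_sub = np.sqrt(np.clip(var_sub, 1e-30, None))
        # restrict to the allowed shift window
        s_w_win = s_w[np.ix_(range(len(chunk)), iz, iy, ix)]
        den_win = denom_sub[np.ix_(range(len(chunk)), iz, iy, ix)]

        best_score = np.full(len(chunk), -np.inf)
        best_rot = np.zeros(len(chunk), dtype=int)
        best_idx = np.zeros((len(chunk), 3), dtype=int)
        best_win = np.zeros((len(chunk),) + tuple(len(a) for a in (oz, oy, ox)))
        for qi, (g_q, swr, sigma_ref) in enumerate(bank.entries):
            num = spfft.irfftn(g_q[None] * f_sub, s=(box,) * 3, axes=(1, 2, 3))
            num_win = num[np.ix_(range(len(chunk)), iz, iy, ix)]
            ncc = (num_win - swr * s_w_win / bank.wsum) / (sigma_ref * den_win)
            flat = ncc.reshape(len(chunk), -1)
            idx = np.argmax(flat, axis=1)
            sc = flat[np.arange(len(chunk)), idx]
            better = sc > best_score
            if np.any(better):
                ii, jj, kk = np.unravel_index(idx[better], ncc.shape[1:])
                best_score[better] = sc[better]
                best_rot[better] = qi
                best_idx[better] = np.column_stack([ii, jj, kk])
                best_win[better] = ncc[better]

        # sub-voxel shift refinement: parabolic interpolation of the NCC
        # peak along each axis (skipped at window edges)
        best_shift = np.column_stack(
            [oz[best_idx[:, 0]], oy[best_idx[:, 1]], ox[best_idx[:, 2]]]
        ).astype(float)
        for ci in range(len(chunk)):
            for ax, offs in enumerate((oz, oy, ox)):
                j = best_idx[ci, ax]
                if 0 < j < len(offs) - 1:
                    sel = list(best_idx[ci])
                    sel[ax] = slice(j - 1, j + 2)
                    c0, c1, c2 = best_win[ci][tuple(sel)]
                    denom = c0 - 2 * c1 + c2
                    if denom < -1e-12:
                        best_shift[ci, ax] += float(
                            np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5)
                        )
        for ci, i in enumerate(chunk):
            base = base_poses[i]
            # the bank rotates the reference grid by Q (refq(x) = ref(Q x)),
            # so a match means the particle rotation is base composed with
            # the inverse delta
            Q = rotations[best_rot[ci]]
            phi, theta, psi = matrix_to_zxz(base.matrix() @ Q.T)
            shift_xyz = best_shift[ci][::-1] * vox
            pos = base.position + base.matrix() @ shift_xyz
            results[i] = AlignmentResult(
                Pose(pos, phi, theta, psi, base.filament_id, base.subunit_index),
                float(best_score[ci]),
            )
    return results


def align_subvolume(
    sub: Subvolume,
    ref: DensityMap,
    search: AngularSearch,
    shift_limit: float = 1.38,
    transverse_limit: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
) -> AlignmentResult:
    """Align a single subvolume (see :func:`score_subvolumes`)."""
    if sub.box != ref.values.shape[0] or abs(sub.voxel_size - ref.voxel_size) > 1e-9:
        raise ValueError("subvolume and reference must share box and voxel size")
    return score_subvolumes(
        [sub], ref, search, shift_limit, transverse_limit, mask
    )[0]


# ---------------------------------------------------------------------------
# averaging


def average_subvolumes(
    subs: Sequence[Subvolume],
    poses: Optional[Sequence[Pose]] = None,
    box: Optional[int] = None,
) -> DensityMap:
    """Uniform voxel-wise average in the reference frame.

    Each subvolume is inverse-transformed through its pose (rotation plus
    constrained shift, in one resampling) and averaged with uniform weights.
    """
    subs = list(subs)
    if not subs:
        raise ValueError("no subvolumes to average")
    if poses is None:
        poses = [s.source_pose for s in subs]
    if box is None:
        box = subs[0].box
    vox = subs[0].voxel_size
    acc = np.zeros((box, box, box), dtype=np.float64)
    for s, p in zip(subs, poses):
        acc += resample_to_reference(s, p, box, vox)
    acc /= len(subs)
    c = vox * (box - 1) / 2.0
    return DensityMap(acc.astype(np.float32), vox, origin=np.array([-c, -c, -c]))


def iterate_alignment(
    subs: Sequence[Subvolume],
    ref0: DensityMap,
    schedule: Sequence[AngularSearch],
    shift_limit: float = 1.38,
    transverse_limit: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
) -> tuple[DensityMap, list[Pose], list[float]]:
    """Alternate constrained alignment and averaging over a search schedule.

    Each round aligns all subvolumes against the current reference (global
    in-plane search or local all-angle refinement, as the schedule entry
    specifies), then averages them into the next reference.  The mean
    alignment score per round is returned; an error is raised if it decreases
    for three consecutive rounds (divergence guard).
    """
    subs = list(subs)
    ref = ref0
    poses = [s.source_pose for s in subs]
    history: list[float] = []
    worse = 0
    for search in schedule:
        results = score_subvolumes(
            subs, ref, search, shift_limit, transverse_limit, mask, base_poses=poses
        )
        poses = [r.pose for r in results]
        mean_score = float(np.mean([r.score for r in results]))
        if history and mean_score < history[-1]:
            worse += 1
            if worse >= 3:
                raise RuntimeError(
                    f"alignment diverging: mean score decreased for {worse} "
                    f"consecutive rounds (last {mean_score:.4f})"
                )
        else:
            worse = 0
        history.append(mean_score)
        ref = average_subvolumes(subs, poses, box=ref.values.shape[0])
    return ref, poses, history


# ---------------------------------------------------------------------------
# deduplication


def dedupe_positions(
    poses: Sequence[Pose],
    scores: Optional[Sequence[float]] = None,
    min_distance: float = 2.76,
) -> list[int]:
    """Keep one pose per subunit: greedy selection by descending score.

    Within each filament, poses are visited in descending score order (ties
    in input order); a pose closer than min_distance to an already-kept pose
    of the same filament is dropped.  Returns the kept indices, in input
    order.  The kept set is maximal: every dropped pose is within
    min_distance of a kept one.
    """
    poses = list(poses)
    if scores is None:
        scores = np.zeros(len(poses))
    scores = np.asarray(scores, dtype=float)
    kept: list[int] = []
    by_fil: dict[int, list[int]] = {}
    for i, p in enumerate(poses):
        by_fil.setdefault(p.filament_id, []).append(i)
    for fid, idxs in by_fil.items():
        order = sorted(idxs, key=lambda i: -scores[i])
        kept_fil: list[int] = []
        for i in order:
            pos = poses[i].position
            if all(
                np.linalg.norm(pos - poses[j].position) >= min_distance
                for j in kept_fil
            ):
                kept_fil.append(i)
        kept.extend(kept_fil)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Fourier shell correlation


def fsc(map_a: DensityMap, map_b: DensityMap, threshold: float = 0.143) -> FSCCurve:
    """Fourier shell correlation between two maps of identical geometry.

    The resolution is 1/frequency at the first downward crossing of the
    threshold (linear interpolation between shells); if the curve never
    drops below the threshold the Nyquist resolution (two voxels) is
    reported.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("box mismatch")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-9:
        raise ValueError("voxel size mismatch")
    n = map_a.values.shape[0]
    vox = map_a.voxel_size
    fa = np.fft.fftn(map_a.values.astype(np.float64))
    fb = np.fft.fftn(map_b.values.astype(np.float64))
    freq = np.fft.fftfreq(n)  # cycles per voxel
    kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
    shell = np.round(np.sqrt(kz**2 + ky**2 + kx**2) * n).astype(int)
    nshell = n // 2
    num = np.zeros(nshell + 1, dtype=complex)
    pa = np.zeros(nshell + 1)
    pb = np.zeros(nshell + 1)
    flat = shell.ravel()
    valid = flat <= nshell
    np.add.at(num, flat[valid], (fa * np.conj(fb)).ravel()[valid])
    np.add.at(pa, flat[valid], (np.abs(fa) ** 2).ravel()[valid])
    np.add.at(pb, flat[valid], (np.abs(fb) ** 2).ravel()[valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.real(num) / np.sqrt(pa * pb)
    corr = np.nan_to_num(corr[1:], nan=0.0)
    freqs = np.arange(1, nshell + 1) / (n * vox)  # 1/nm

    res = 2.0 * vox
    below = np.nonzero(corr < threshold)[0]
    if len(below):
        j = below[0]
        if j == 0:
            res = 1.0 / freqs[0]
        else:
            f0, f1 = freqs[j - 1], freqs[j]
            c0, c1 = corr[j - 1], corr[j]
            fcross = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
            res = 1.0 / fcross
    return FSCCurve(freqs, corr, float(res))


# ---------------------------------------------------------------------------
# polarity assignment


def assign_polarity(
    subs: Sequence[Subvolume],
    ref_a: DensityMap,
    ref_b: DensityMap,
    search: Optional[AngularSearch] = None,
    alpha: float = 0.05,
    shift_limit: float = 1.38,
    transverse_limit: Optional[float] = None,
    welch: bool = False,
    mask: Optional[np.ndarray] = None,
    design: str = "split",
) -> dict[int, PolarityCall]:
    """Two-reference statistical polarity assignment, one call per filament.

    Subvolumes are aligned against the two references with identical search
    settings.  Per filament, the two score samples are compared with a
    two-sided unpaired Student's t-test (pooled variance; Welch's variant
    behind the flag): p < alpha assigns the polarity of the higher-scoring
    reference, otherwise the filament stays unassigned.  Filaments with
    fewer than two subvolumes are unassigned with p = 1.

    design controls how the two samples are formed.  "split" (default)
    scores the even-indexed subvolumes of each filament against reference A
    and the odd-indexed ones against B, so the compared samples are
    statistically independent and the unpaired t-test is calibrated (its
    false-assignment rate on polarity-free input is alpha).  "both" scores
    every subvolume against both references; the samples then share the
    subvolume noise, which makes the unpaired test conservative.
    """
    if search is None:
        search = AngularSearch.inplane(10.0)
    if design not in ("split", "both"):
        raise ValueError("design must be 'split' or 'both'")
    by_fil: dict[int, list[int]] = {}
    for i, s in enumerate(subs):
        by_fil.setdefault(s.source_pose.filament_id, []).append(i)

    if design == "both":
        idx_a = {fid: idxs for fid, idxs in by_fil.items()}
        idx_b = idx_a
    else:
        idx_a = {fid: idxs[0::2] for fid, idxs in by_fil.items()}
        idx_b = {fid: idxs[1::2] for fid, idxs in by_fil.items()}
    sub_list = list(subs)
    need_a = sorted(i for idxs in idx_a.values() for i in idxs)
    need_b = sorted(i for idxs in idx_b.values() for i in idxs)
    res_a = dict(
        zip(need_a, score_subvolumes([sub_list[i] for i in need_a], ref_a, search,
                                     shift_limit, transverse_limit, mask))
    )
    res_b = dict(
        zip(need_b, score_subvolumes([sub_list[i] for i in need_b], ref_b, search,
                                     shift_limit, transverse_limit, mask))
    )

    calls: dict[int, PolarityCall] = {}
    for fid, idxs in sorted(by_fil.items()):
        sa = np.array([res_a[i].score for i in idx_a[fid]])
        sb = np.array([res_b[i].score for i in idx_b[fid]])
        if len(sa) < 2 or len(sb) < 2:
            logger.warning("filament %d has too few subvolumes; unassigned", fid)
            ma = float(sa.mean()) if len(sa) else float("nan")
            mb = float(sb.mean()) if len(sb) else float("nan")
            calls[fid] = PolarityCall(fid, len(idxs), ma, mb, 1.0, "unassigned")
            continue
        import warnings

        with warnings.catch_warnings():
            # identical samples trigger a precision warning; the NaN result
            # is guarded to p = 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            t = stats.ttest_ind(sa, sb, equal_var=not welch)
        p = float(t.pvalue)
        if not np.isfinite(p):  # identical samples
            p = 1.0
        if p < alpha:
            call = "A" if sa.mean() > sb.mean() else "B"
        else:
            call = "unassigned"
        calls[fid] = PolarityCall(fid, len(idxs), float(sa.mean()), float(sb.mean()), p, call)
    return calls


def polarity_calls_to_csv(calls: dict[int, PolarityCall], path) -> None:
    pd.DataFrame(
        [
            {
                "filament_id": c.filament_id,
                "n": c.n_subvolumes,
                "mean_A": c.mean_score_a,
                "mean_B": c.mean_score_b,
                "p": c.p_value,
                "call": c.call,
            }
            for c in calls.values()
        ]
    ).to_csv(path, index=False)
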