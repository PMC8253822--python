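"""Synthetic sarcomere geometry and density volumes.

Generates filament networks and 3D density maps with the geometric and
statistical structure that the packing, polarity, and metrics stages assume,
so the whole pipeline is testable without a real tomogram:

* double hexagonal myofilament lattices (thick filaments at hexagonal nodes,
  thin filaments at trigonal sites plus interstitial extras) with per-filament
  positional jitter;
* polarity-segmented sarcomeres with Z-disk gaps, I-bands, and a plantable
  thin-filament overlap at the M-line;
* helical thin-filament densities (single-start actin helix decorated with two
  tropomyosin strands) with additive Gaussian noise and an optional missing
  wedge;
* polarity reference pairs related by a 180-degree rotation about x.

All generation is reproducible given the spec seeds.  Generated sarcomeres run
along +x; maps are indexed (z, y, x) with the voxel center at its coordinate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    THICK,
    THIN,
    Filament,
    FilamentNetwork,
    Pose,
    angles_from_tangent,
    resample_centerline,
    zxz_matrix,
)
from .volume import DensityMap, rotate180_x

__all__ = [
    "LatticeSpec",
    "SarcomereSpec",
    "HelicalParams",
    "ImagingSpec",
    "build_lattice",
    "build_calibrated_lattice",
    "build_sarcomere",
    "helical_poses",
    "render_filament_density",
    "make_reference_pair",
    "apply_missing_wedge",
    "spec_to_json",
    "spec_from_json",
]


def _wrap180(angle: float | np.ndarray):
    """Wrap an angle in degrees to (-180, 180]."""
    a = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return float(a) if np.isscalar(angle) else a


# ---------------------------------------------------------------------------
# specs


@dataclass
class LatticeSpec:
    """Transverse myofilament lattice geometry.

    spacing_a is the thick-thick hexagonal lattice constant (nm).  jitter_sd
    parameterizes the per-filament rigid lateral jitter; it is calibrated so
    that the standard deviation it induces on nearest-neighbor *spacings*
    equals jitter_sd (each filament's in-plane offset therefore has
    per-component sd jitter_sd/sqrt(2)), matching how interfilament spacing
    spreads are reported from tomograms.  trigonal_occupancy is the fraction
    of trigonal sites holding a thin filament; interstitial_density the
    expected number of extra thin filaments per unit cell, placed uniformly
    with a steric minimum-distance constraint.
    """

    spacing_a: float = 45.1
    jitter_sd: float = 0.0
    n_a: int = 8
    n_b: int = 8
    trigonal_occupancy: float = 1.0
    interstitial_density: float = 0.0
    filament_length: float = 300.0
    min_interstitial_distance: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.spacing_a <= 0:
            raise ValueError("spacing_a must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.trigonal_occupancy <= 1.0:
            raise ValueError("trigonal_occupancy must be in [0, 1]")
        if self.interstitial_density < 0:
            raise ValueError("interstitial_density must be >= 0")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("lattice extents must be >= 1")
        if self.filament_length <= 0:
            raise ValueError("filament_length must be positive")


@dataclass
class SarcomereSpec:
    """Longitudinal sarcomere layout (all lengths nm).

    The sarcomere spans one Z-disk to the next.  Thin filaments are anchored
    with their barbed ends at the Z-disk faces (half the z_disk_width away
    from the Z-disk center) and extend toward the M-line; filaments from the
    two half-sarcomeres interpenetrate the M-region by exactly overlap_length.
    Thick filaments span the A-band and are absent from the I-band.
    """

    sarcomere_length: float = 1800.0
    z_disk_width: float = 120.0
    i_band_width: float = 270.0
    bare_zone_length: float = 140.0
    overlap_length: float = 0.0
    thin_length_mean: float = 800.0
    thin_length_sd: float = 50.0
    thick_length: Optional[float] = None
    n_sarcomeres: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.thick_length is None:
            self.thick_length = self.sarcomere_length - self.i_band_width
        for name in (
            "sarcomere_length",
            "z_disk_width",
            "i_band_width",
            "bare_zone_length",
            "thin_length_mean",
            "thin_length_sd",
            "thick_length",
            "overlap_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sarcomeres < 1:
            raise ValueError("n_sarcomeres must be >= 1")
        L, zw, ov = self.sarcomere_length, self.z_disk_width, self.overlap_length
        # maximum thin extent measured from the Z-disk face
        cap = L / 2.0 + ov / 2.0 - zw / 2.0
        if cap <= 0:
            raise ValueError("sarcomere too short for the requested Z-disk width")
        if cap > self.thin_length_mean + 3.0 * self.thin_length_sd:
            raise ValueError(
                "planted overlap is not reachable: thin filaments are too short "
                f"(need extent {cap:.1f} nm from the Z-disk face)"
            )
        if self.thick_length > L - zw:
            raise ValueError("thick filaments do not fit between Z-disks")


@dataclass
class HelicalParams:
    """Thin-filament helical geometry.

    F-actin is a left-handed single-start helix: rise per subunit 2.76 nm and
    signed twist per subunit -167.0 degrees, giving the canonical 13-subunit
    repeat of 35.9 nm.  Two tropomyosin strands run along the long-pitch
    helix at tpm_radius; tpm_azimuth rotates both strands on the filament
    surface (azimuth 0 points through the center of subunit 0).
    """

    rise: float = 2.76
    twist: float = -167.0
    subunits_per_repeat: int = 13
    actin_radius: float = 2.2
    tpm_radius: float = 4.8
    tpm_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < abs(self.twist) < 360:
            raise ValueError("twist magnitude must be in (0, 360)")
        if self.subunits_per_repeat < 1:
            raise ValueError("subunits_per_repeat must be >= 1")

    @property
    def repeat_length(self) -> float:
        return self.subunits_per_repeat * self.rise


@dataclass
class ImagingSpec:
    """Imaging conditions for synthetic volumes.

    snr = signal variance / noise variance (np.inf means noise-free).
    wedge_half_angle, when set, is the half-angle (degrees) of the missing
    wedge about the beam-direction frequency axis (tilt axis along y).
    """

    snr: float = np.inf
    wedge_half_angle: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noise-free)")
        if self.wedge_half_angle is not None and not 0 < self.wedge_half_angle < 90:
            raise ValueError("wedge_half_angle must be in (0, 90)")


def spec_to_json(spec, path: str | Path) -> None:
    d = asdict(spec)
    d = {k: (None if isinstance(v, float) and np.isinf(v) else v) for k, v in d.items()}
    Path(path).write_text(json.dumps({"class": type(spec).__name__, **d}, indent=1))


def spec_from_json(cls, path: str | Path):
    d = json.loads(Path(path).read_text())
    d.pop("class", None)
    if cls is ImagingSpec and d.get("snr") is None:
        d["snr"] = np.inf
    return cls(**d)


# ---------------------------------------------------------------------------
# lattice generation


def _hex_axes(a: float) -> tuple[np.ndarray, np.ndarray]:
    return np.array([a, 0.0]), np.array([a / 2.0, a * np.sqrt(3.0) / 2.0])


def _lattice_sites(spec: LatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """(thick, trigonal-thin) transverse (y, z) site arrays, jitter-free."""
    a1, a2 = _hex_axes(spec.spacing_a)
    thick = np.array(
        [i * a1 + j * a2 for i in range(spec.n_a) for j in range(spec.n_b)]
    )
    trig = []
    for i in range(spec.n_a - 1):
        for j in range(spec.n_b - 1):
            base = i * a1 + j * a2
            trig.append(base + (a1 + a2) / 3.0)
            trig.append(base + 2.0 * (a1 + a2) / 3.0)
    return thick, np.asarray(trig).reshape(-1, 2)


def _straight(fid: int, ftype: str, yz: np.ndarray, length: float) -> Filament:
    y, z = yz
    return Filament(
        fid,
        ftype,
        np.array([[-length / 2.0, y, z], [length / 2.0, y, z]]),
    )


def build_lattice(spec: LatticeSpec, seed: Optional[int] = None) -> FilamentNetwork:
    """Build a double hexagonal lattice of parallel straight filaments.

    Thick filaments sit at hexagonal nodes; thin filaments occupy trigonal
    sites (at spacing_a/sqrt(3) from three thick neighbors) with probability
    trigonal_occupancy, plus Poisson-distributed interstitials placed
    uniformly with a steric minimum-distance constraint.  Jitter is applied
    per filament as a rigid lateral offset.  Filaments run along x.

    Raises
    ------
    RuntimeError
        If an interstitial cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    thick_sites, trig_sites = _lattice_sites(spec)

    if spec.trigonal_occupancy >= 1.0:
        occupied = trig_sites
    elif len(trig_sites):
        keep = rng.random(len(trig_sites)) < spec.trigonal_occupancy
        occupied = trig_sites[keep]
    else:
        occupied = trig_sites

    n_cells = max((spec.n_a - 1) * (spec.n_b - 1), 0)
    n_inter = rng.poisson(spec.interstitial_density * n_cells) if n_cells else 0
    axes = [s for s in thick_sites] + [s for s in occupied]
    lo = thick_sites.min(axis=0)
    hi = thick_sites.max(axis=0)
    inter_sites = []
    for _ in range(n_inter):
        for _attempt in range(200):
            cand = lo + rng.random(2) * (hi - lo)
            dmin = min(np.linalg.norm(cand - s) for s in axes)
            if dmin >= spec.min_interstitial_distance:
                inter_sites.append(cand)
                axes.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place an interstitial thin filament within the "
                "minimum-distance constraint (retry budget exhausted)"
            )

    # per-component jitter sd = jitter_sd / sqrt(2): nearest-neighbor spacing
    # spreads then have sd jitter_sd (see LatticeSpec)
    sig = spec.jitter_sd / np.sqrt(2.0)
    fils = []
    fid = 0
    for sites, ftype in ((thick_sites, THICK), (occupied, THIN), (np.asarray(inter_sites).reshape(-1, 2), THIN)):
        for s in sites:
            offset = rng.normal(0.0, sig, 2) if sig > 0 else np.zeros(2)
            fils.append(_straight(fid, ftype, s + offset, spec.filament_length))
            fid += 1
    return FilamentNetwork(fils)


def build_calibrated_lattice(
    spec: LatticeSpec,
    pair_distance_mean: float = 15.5,
    pair_distance_sd: float = 1.4,
    safety_distance: float = 22.0,
    seed: Optional[int] = None,
) -> FilamentNetwork:
    """Hexagonal lattice whose nearest thin-thin distances are planted.

    Thick filaments occupy the full hexagonal lattice.  Thin filaments come
    in isolated clusters of four: the two trigonal sites of every other unit
    cell (one trigonal spacing_a/sqrt(3) apart, so the trigonal shell is
    present in the thin-thin histogram), each with a companion thin filament
    at a planted distance ~ N(pair_distance_mean, pair_distance_sd).

    The companion *direction* is resampled until the companion clears
    safety_distance from every thin filament other than its own base; because
    only the direction is resampled — never the drawn distance — the planted
    nearest-neighbor distance distribution is preserved exactly: every thin
    filament's nearest thin is its pair partner at the drawn distance.
    Companion placement skips the steric thick-filament exclusion for the
    same reason.  Distance draws are clipped at 4.3 sd so a companion can
    never undercut the safety margin.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if pair_distance_mean + 4.3 * pair_distance_sd >= safety_distance:
        raise ValueError("pair distance distribution overlaps the safety margin")
    a1, a2 = _hex_axes(spec.spacing_a)
    thick_sites, _ = _lattice_sites(spec)
    sig = spec.jitter_sd / np.sqrt(2.0)

    def jit() -> np.ndarray:
        return rng.normal(0.0, sig, 2) if sig > 0 else np.zeros(2)

    fils: list[Filament] = []
    fid = 0
    for s in thick_sites:
        fils.append(_straight(fid, THICK, s + jit(), spec.filament_length))
        fid += 1

    thin_axes: list[np.ndarray] = []
    bases: list[np.ndarray] = []
    for i in range(0, spec.n_a - 1, 2):
        for j in range(0, spec.n_b - 1, 2):
            base = i * a1 + j * a2
            for frac in (1.0 / 3.0, 2.0 / 3.0):
                bases.append(base + frac * (a1 + a2) + jit())
    thin_axes.extend(bases)
    companions: list[np.ndarray] = []
    lim = 4.3 * pair_distance_sd
    for b in bases:
        d = float(np.clip(rng.normal(pair_distance_mean, pair_distance_sd),
                          pair_distance_mean - lim, pair_distance_mean + lim))
        for _attempt in range(500):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = b + d * np.array([np.cos(ang), np.sin(ang)])
            others = [t for t in thin_axes if t is not b] + companions
            if all(np.linalg.norm(cand - t) >= safety_distance for t in others):
                companions.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place a companion thin filament clear of the "
                "safety distance (retry budget exhausted)"
            )
    for yz in list(bases) + companions:
        fils.append(_straight(fid, THIN, yz, spec.filament_length))
        fid += 1
    return FilamentNetwork(fils)


# ---------------------------------------------------------------------------
# sarcomere generation


def build_sarcomere(
    sspec: SarcomereSpec, lspec: LatticeSpec, seed: Optional[int] = None
) -> FilamentNetwork:
    """Build polarity-labeled sarcomeres on a hexagonal transverse lattice.

    Z-disks sit at x = 0, L, 2L, ...; no filament density lies inside the
    Z-disk gap (z_disk_width).  Thin filaments emanate from both Z-disk faces
    (barbed ends at the face) with opposite polarity labels; their lengths are
    Gaussian, truncated at the planted maximum extent, and the two
    half-sarcomere arrays interpenetrate the M-region by exactly
    overlap_length.  Thick filaments are centered on the M-line and absent
    from the I-band.  Points are stored in ascending x, so polarity is +1 for
    right-pointing (pointed end last) and -1 for left-pointing filaments.
    """
    rng = np.random.default_rng(sspec.seed if seed is None else seed)
    thick_sites, trig_sites = _lattice_sites(lspec)
    if lspec.trigonal_occupancy >= 1.0:
        thin_sites = trig_sites
    else:
        keep = rng.random(len(trig_sites)) < lspec.trigonal_occupancy
        thin_sites = trig_sites[keep]
    sig = lspec.jitter_sd / np.sqrt(2.0)

    L = sspec.sarcomere_length
    zw = sspec.z_disk_width
    fils: list[Filament] = []
    fid = 0

    def jittered(yz: np.ndarray) -> np.ndarray:
        return yz + (rng.normal(0.0, sig, 2) if sig > 0 else 0.0)

    for s in range(sspec.n_sarcomeres):
        x0 = s * L
        m = x0 + L / 2.0
        cap = m + sspec.overlap_length / 2.0  # max pointed extent, right-pointing
        # right-pointing thins (barbed at left Z-disk face), polarity +1
        for side in (+1, -1):
            barbed = (x0 + zw / 2.0) if side == 1 else (x0 + L - zw / 2.0)
            cap_x = cap if side == 1 else 2.0 * m - cap
            lengths = rng.normal(sspec.thin_length_mean, sspec.thin_length_sd, len(thin_sites))
            lengths = np.clip(lengths, zw, None)
            tips = barbed + side * lengths
            tips = np.minimum(tips, cap_x) if side == 1 else np.maximum(tips, cap_x)
            # guarantee the planted extent is realized exactly
            if len(tips):
                idx = int(np.argmax(side * tips))
                tips[idx] = cap_x
            for yz, tip in zip(thin_sites, tips):
                y, z = jittered(yz)
                xa, xb = (barbed, tip) if side == 1 else (tip, barbed)
                fils.append(
                    Filament(fid, THIN, np.array([[xa, y, z], [xb, y, z]]), polarity=side)
                )
                fid += 1
        # thick filaments span the A-band, centered on the M-line
        half = sspec.thick_length / 2.0
        for yz in thick_sites:
            y, z = jittered(yz)
            fils.append(
                Filament(fid, THICK, np.array([[m - half, y, z], [m + half, y, z]]))
            )
            fid += 1
    return FilamentNetwork(fils)


# ---------------------------------------------------------------------------
# helical poses and density rendering


def helical_poses(
    filament: Filament, helix: HelicalParams, phi0: float = 0.0
) -> list[Pose]:
    """Subunit poses along a centerline with coherent helical phase.

    Subunit k sits at arc length k*rise with in-plane angle
    phi0 + k*twist; (theta, psi) carry the local tangent.  These poses are the
    ground truth consumed by the density renderer and recovered by the
    helical-parameter estimator.
    """
    res = resample_centerline(filament, helix.rise)
    from .geometry import local_tangents

    tangents = local_tangents(res)
    poses = []
    for k, (p, t) in enumerate(zip(res.points, tangents)):
        theta, psi = angles_from_tangent(t)
        poses.append(
            Pose(p.copy(), (phi0 + k * helix.twist) % 360.0, theta, psi, filament.id, k)
        )
    return poses


# soft-sphere subunit model: (radial offset rel. actin_radius, azimuth deg,
# axial offset nm, sigma nm, weight).  The off-axis secondary lobe breaks the
# perpendicular two-fold symmetry of a plain helix of spheres, so filament
# polarity is encoded in the density (as it is by the actin subunit shape).
_SUBUNIT_LOBES = (
    (1.0, 0.0, 0.0, 1.2, 1.0),
    (1.3, 45.0, 0.69, 0.8, 1.0),
)
_TPM_SIGMA = 1.0
_TPM_WEIGHT = 0.35
_TPM_STEP = 0.25  # subunit units


def _splat(values: np.ndarray, centers: np.ndarray, sigmas: np.ndarray, weights: np.ndarray) -> None:
    """Accumulate Gaussian blobs; centers in continuous (z, y, x) voxel coords."""
    nz, ny, nx = values.shape
    for (cz, cy, cx), sig, w in zip(centers, sigmas, weights):
        r = 3.5 * sig
        z0, z1 = max(0, int(np.floor(cz - r))), min(nz, int(np.ceil(cz + r)) + 1)
        y0, y1 = max(0, int(np.floor(cy - r))), min(ny, int(np.ceil(cy + r)) + 1)
        x0, x1 = max(0, int(np.floor(cx - r))), min(nx, int(np.ceil(cx + r)) + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz = (np.arange(z0, z1) - cz)[:, None, None]
        yy = (np.arange(y0, y1) - cy)[None, :, None]
        xx = (np.arange(x0, x1) - cx)[None, None, :]
        values[z0:z1, y0:y1, x0:x1] += w * np.exp(
            -(zz**2 + yy**2 + xx**2) / (2.0 * sig**2)
        )


def apply_missing_wedge(values: np.ndarray, half_angle: float) -> np.ndarray:
    """Zero the frequency wedge within half_angle of the beam (z) axis.

    Single-axis tilt geometry with the tilt axis along y: frequencies whose
    (kx, kz) direction lies within half_angle of the kz axis are unmeasured.
    """
    f = np.fft.fftn(values)
    nz, ny, nx = values.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kx), np.abs(kz)))
    mask = (ang >= half_angle) | ((kz == 0) & (kx == 0))
    return np.real(np.fft.ifftn(f * mask)).astype(np.float32)


def render_filament_density(
    poses: Sequence[Pose],
    helix: HelicalParams,
    voxel_size: float,
    box: int | tuple[int, int, int],
    imaging: Optional[ImagingSpec] = None,
    origin: Optional[np.ndarray] = None,
) -> DensityMap:
    """Render thin-filament density from subunit poses.

    Each pose contributes soft-sphere actin-subunit lobes placed in its local
    frame; per filament, two continuous tropomyosin tubes at tpm_radius follow
    the long-pitch twist at azimuth helix.tpm_azimuth (and +180 for the second
    strand).  Additive Gaussian noise is scaled to imaging.snr and an optional
    missing-wedge filter is applied in the frequency domain.  Deterministic
    given imaging.seed.
    """
    if isinstance(box, int):
        box = (box, box, box)
    nz, ny, nx = box
    poses = list(poses)
    if not poses:
        raise ValueError("no poses to render")
    positions = np.array([p.position for p in poses])
    if origin is None:
        center = positions.mean(axis=0)
        origin = center - voxel_size * (np.array([nx, ny, nz]) - 1) / 2.0
    origin = np.asarray(origin, dtype=float)
    span = voxel_size * (np.array([nx, ny, nz]) - 1)
    if np.any(positions < origin - 1e-9) or np.any(positions > origin + span + 1e-9):
        raise ValueError("box too small: a pose lies outside the volume")

    centers, sigmas, weights = [], [], []

    def add_blob(world: np.ndarray, sigma: float, weight: float) -> None:
        centers.append(((world - origin) / voxel_size)[::-1])  # xyz -> zyx
        sigmas.append(sigma / voxel_size)
        weights.append(weight)

    by_fil: dict[int, list[Pose]] = {}
    for p in poses:
        by_fil.setdefault(p.filament_id, []).append(p)

    lam = _wrap180(2.0 * helix.twist) / 2.0  # long-pitch twist rate, deg/subunit
    for fid, fposes in by_fil.items():
        fposes = sorted(fposes, key=lambda p: p.subunit_index)
        for p in fposes:
            R = p.matrix()
            for rfrac, az, dz, sig, w in _SUBUNIT_LOBES:
                local = zxz_matrix(az, 0.0, 0.0) @ np.array(
                    [rfrac * helix.actin_radius, 0.0, 0.0]
                ) + np.array([0.0, 0.0, dz])
                add_blob(p.position + R @ local, sig, w)
        # tropomyosin tubes: continuous strands along the long-pitch helix
        if len(fposes) >= 2:
            idx = np.array([p.subunit_index for p in fposes], dtype=float)
            pos = np.array([p.position for p in fposes])
            phi0 = fposes[0].phi - idx[0] * helix.twist
            ts = np.arange(idx[0] - 0.5, idx[-1] + 0.5 + 1e-9, _TPM_STEP)
            for t in ts:
                tc = np.clip(t, idx[0], idx[-1])
                # interpolate position (extrapolate linearly at the ends)
                k = int(np.clip(np.searchsorted(idx, tc) - 1, 0, len(idx) - 2))
                frac = (t - idx[k]) / (idx[k + 1] - idx[k])
                world = pos[k] + frac * (pos[k + 1] - pos[k])
                near = fposes[k if frac < 0.5 else k + 1]
                for strand in (0.0, 180.0):
                    az = phi0 + helix.tpm_azimuth + strand + t * lam
                    off = zxz_matrix(az, near.theta, near.psi) @ np.array(
                        [helix.tpm_radius, 0.0, 0.0]
                    )
                    add_blob(world + off, _TPM_SIGMA, _TPM_WEIGHT)

    values = np.zeros((nz, ny, nx), dtype=np.float64)
    _splat(values, np.array(centers), np.array(sigmas), np.array(weights))

    if imaging is not None and np.isfinite(imaging.snr):
        rng = np.random.default_rng(imaging.seed)
        sigma_noise = float(np.sqrt(values.var() / imaging.snr)) if values.var() > 0 else 1.0
        values = values + rng.normal(0.0, sigma_noise, values.shape)
    if imaging is not None and imaging.wedge_half_angle is not None:
        values = apply_missing_wedge(values, imaging.wedge_half_angle)
    return DensityMap(values.astype(np.float32), voxel_size, origin)


def make_reference_pair(
    helix: HelicalParams,
    voxel_size: float,
    box: int,
    fill: float = 0.8,
) -> tuple[DensityMap, DensityMap]:
    """Noise-free polarity reference pair.

    Renders a straight thin filament along +z centered in a cubic box (axial
    extent `fill` of the box) and returns it together with its 180-degree
    rotation about the x axis — the opposite-polarity reference.
    """
    length = fill * box * voxel_size
    n_sub = max(int(np.floor(length / helix.rise)), 2)
    half = n_sub * helix.rise / 2.0
    fil = Filament(0, THIN, np.array([[0.0, 0.0, -half], [0.0, 0.0, half]]))
    poses = helical_poses(fil, helix, phi0=0.0)
    center = voxel_size * (box - 1) / 2.0
    origin = -np.array([center, center, center])
    ref_a = render_filament_density(poses, helix, voxel_size, box, origin=origin)
    return ref_a, rotate180_x(ref_a)
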