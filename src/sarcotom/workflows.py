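"""End-to-end reproduction workflows at desk scale.

Each function regenerates its study conditions from a seed, runs the
corresponding analysis pipeline, and returns the recovered quantities.  They
are the programmatic equivalents of the CLI pipelines and are what the
reproduction script and the acceptance tests call.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .geometry import THICK, THIN, Filament, FilamentNetwork, resample_centerline
from .metrics import HelicalEstimate, annotate_sarcomeres, estimate_helix, measure_overlap
from .packing import NeighborHistogram, SpacingEstimate, estimate_spacing, near_neighbor_histogram
from .synthetic import (
    HelicalParams,
    LatticeSpec,
    SarcomereSpec,
    build_calibrated_lattice,
    build_lattice,
    build_sarcomere,
    helical_poses,
)

__all__ = [
    "recover_thick_spacing",
    "recover_trigonal_spacing",
    "recover_thin_thin_spacing",
    "recover_helical_parameters",
    "recover_overlap_metrics",
]

RESAMPLE_STEP = 3.0  # nm, equal weight per point along a filament


def _resampled(net: FilamentNetwork) -> FilamentNetwork:
    return net.map(lambda f: resample_centerline(f, RESAMPLE_STEP))


def recover_thick_spacing(
    seed: int = 0, spacing: float = 45.1, jitter_sd: float = 3.8, n_a: int = 14, n_b: int = 14
) -> SpacingEstimate:
    """Thick-thick lattice spacing from the near-neighbor analysis.

    Generates a jittered hexagonal thick-filament lattice (~200 filaments by
    default), resamples at 3 nm, and reads the first-shell mean spacing from
    the (d, theta) histogram.
    """
    net = build_lattice(
        LatticeSpec(
            spacing_a=spacing, jitter_sd=jitter_sd, n_a=n_a, n_b=n_b,
            trigonal_occupancy=0.0,
        ),
        seed=seed,
    )
    hist = near_neighbor_histogram(_resampled(net), THICK, THICK, d_max=60.0)
    return estimate_spacing(hist)


def recover_trigonal_spacing(spacing: float = 45.1, n: int = 8) -> SpacingEstimate:
    """Thin-to-thick spacing on the jitter-free double hexagonal lattice.

    With no jitter the estimator returns the trigonal distance
    spacing/sqrt(3) exactly, with zero spread.
    """
    net = build_lattice(LatticeSpec(spacing_a=spacing, n_a=n, n_b=n), seed=0)
    hist = near_neighbor_histogram(_resampled(net), THIN, THICK, d_max=40.0)
    return estimate_spacing(hist)


def recover_thin_thin_spacing(
    seed: int = 0,
    planted_mean: float = 15.5,
    planted_sd: float = 1.4,
    n: int = 25,
) -> tuple[SpacingEstimate, NeighborHistogram]:
    """Nearest parallel thin-thin spacing on the calibrated lattice.

    The generator plants a nearest-thin-neighbor law N(planted_mean,
    planted_sd) while keeping the trigonal (26 nm) shell present; the
    first-shell estimator must recover the planted mean, not the trigonal
    shell.  Returns the estimate together with the histogram so callers can
    verify the trigonal shell was present and not selected.
    """
    net = build_calibrated_lattice(
        LatticeSpec(spacing_a=45.1, jitter_sd=2.0, n_a=n, n_b=n),
        pair_distance_mean=planted_mean,
        pair_distance_sd=planted_sd,
        seed=seed,
    )
    hist = near_neighbor_histogram(_resampled(net), THIN, THIN, d_max=35.0)
    return estimate_spacing(hist), hist


def recover_helical_parameters(
    helix: Optional[HelicalParams] = None,
    n_filaments: int = 3,
    length: float = 110.0,
) -> HelicalEstimate:
    """Helical rise and twist from noise-free synthetic subunit poses.

    Builds straight filaments, generates one pose per actin subunit with the
    canonical geometry, and estimates rise/twist from consecutive-pose axial
    spacings and in-plane rotation differences.
    """
    helix = helix or HelicalParams()
    poses = []
    for fid in range(n_filaments):
        fil = Filament(
            fid, THIN, np.array([[0.0, 30.0 * fid, 0.0], [length, 30.0 * fid, 0.0]])
        )
        poses += helical_poses(fil, helix, phi0=fid * 71.0)
    return estimate_helix(poses)


def recover_overlap_metrics(
    sarcomere_length: float,
    overlap_length: float,
    thin_length_mean: float,
    seed: int = 0,
) -> tuple[float, float]:
    """Planted overlap and overlap fraction recovered through annotation.

    Builds a three-sarcomere polarity-labeled network, annotates Z-disks and
    M-lines, and measures the overlap at the middle M-line (flanked by
    interior Z-disks on both sides).  Returns (overlap nm, fraction %).
    """
    sspec = SarcomereSpec(
        sarcomere_length=sarcomere_length,
        overlap_length=overlap_length,
        thin_length_mean=thin_length_mean,
        thin_length_sd=50.0,
        n_sarcomeres=3,
    )
    net = build_sarcomere(sspec, LatticeSpec(n_a=4, n_b=4, jitter_sd=2.0), seed=seed)
    ann = annotate_sarcomeres(net)
    mid = ann.m_line_positions[len(ann.m_line_positions) // 2]
    overlap, fraction, _ = measure_overlap(net, mid, annotation=ann)
    return overlap, fraction
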