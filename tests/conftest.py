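"""Shared fixtures and small numerical helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sarcotom import (
    Filament,
    FilamentNetwork,
    HelicalParams,
    make_reference_pair,
    resample_centerline,
)
from sarcotom.geometry import zxz_matrix
from sarcotom.subtomo import rotate_density, soft_cylinder_mask


@pytest.fixture(scope="session")
def helix() -> HelicalParams:
    return HelicalParams()


@pytest.fixture(scope="session")
def refpair(helix):
    """Noise-free polarity reference pair at desk scale (voxel 1 nm, box 24)."""
    return make_reference_pair(helix, 1.0, 24)


def resampled(net: FilamentNetwork, step: float = 3.0) -> FilamentNetwork:
    return net.map(lambda f: resample_centerline(f, step))


def straight(fid: int, ftype: str, p0, p1, polarity=None) -> Filament:
    return Filament(fid, ftype, np.array([p0, p1], dtype=float), polarity)


def masked_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wa = a - (w * a).sum() / w.sum()
    wb = b - (w * b).sum() / w.sum()
    return float(
        (w * wa * wb).sum() / np.sqrt((w * wa * wa).sum() * (w * wb * wb).sum())
    )


def best_registration_corr(ref: np.ndarray, vol: np.ndarray,
                           phi_step: float = 5.0, dz_max: float = 1.5) -> float:
    """Max masked correlation over in-plane rotation and axial shift of ref."""
    from scipy.ndimage import shift as ndshift

    w = soft_cylinder_mask(ref.shape[0])
    best = -1.0
    for phi in np.arange(0.0, 360.0, phi_step):
        r = rotate_density(ref, zxz_matrix(phi, 0.0, 0.0))
        for dz in np.arange(-dz_max, dz_max + 1e-9, 0.5):
            best = max(best, masked_corr(ndshift(r, (dz, 0, 0), order=1), vol, w))
    return best
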