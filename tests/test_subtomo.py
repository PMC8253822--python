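"""Subtomogram extraction, alignment, averaging, FSC, polarity assignment."""

import numpy as np
import pytest

import sarcotom.subtomo as subtomo_mod
from sarcotom.geometry import (
    Filament,
    FilamentNetwork,
    Pose,
    init_poses,
    resample_centerline,
    unify_directions,
    zxz_matrix,
)
from sarcotom.subtomo import (
    AngularSearch,
    Subvolume,
    align_subvolume,
    assign_polarity,
    average_subvolumes,
    dedupe_positions,
    extract_subvolumes,
    fsc,
    iterate_alignment,
    rotate_density,
    soft_cylinder_mask,
)
from sarcotom.synthetic import (
    HelicalParams,
    helical_poses,
    make_reference_pair,
    render_filament_density,
)
from sarcotom.volume import DensityMap, correlation

from conftest import best_registration_corr

VOX = 1.0
BOX = 24


def centered_sub(values, pose=None):
    c = VOX * (values.shape[0] - 1) / 2.0
    pose = pose or Pose(np.zeros(3), 0, 0, 0, 0, 0)
    return Subvolume(values, VOX, pose, origin=np.array([-c, -c, -c]))


@pytest.fixture(scope="module")
def refs(helix):
    return make_reference_pair(helix, VOX, BOX)


@pytest.fixture(scope="module")
def tomo_scene(helix):
    """Eight straight rendered filaments, alternating polarity."""
    fils, truth = [], {}
    for k in range(8):
        y = 25.0 + 30.0 * (k % 3)
        z = 25.0 + 30.0 * (k // 3)
        pts = np.array([[10.0, y, z], [110.0, y, z]])
        fils.append(Filament(k, "thin", pts if k % 2 == 0 else pts[::-1].copy()))
        truth[k] = "A" if k % 2 == 0 else "B"
    poses = []
    for f in fils:
        poses += helical_poses(f, helix, phi0=f.id * 37.0)
    tomo = render_filament_density(
        poses, helix, VOX, (120, 120, 120), origin=np.array([0.0, 0.0, 0.0])
    )
    net = unify_directions(FilamentNetwork(fils))
    sample = []
    rng = np.random.default_rng(1)
    for f in net:
        rf = resample_centerline(f, 1.38)
        sample += [p for p in init_poses(rf, 30.0, seed=rng) if 25 < p.position[0] < 95][::3]
    subs, _ = extract_subvolumes(tomo, sample, BOX)
    return tomo, subs, truth


class TestExtract:
    def test_center_pose_full_box_is_whole_map(self):
        rng = np.random.default_rng(0)
        dmap = DensityMap(rng.normal(size=(16, 16, 16)), VOX)
        center = dmap.center_world()
        subs, skipped = extract_subvolumes(dmap, [Pose(center, 0, 0, 0)], 16)
        assert skipped == 0
        assert np.array_equal(subs[0].values, dmap.values)

    def test_crop_equals_source_region(self):
        rng = np.random.default_rng(1)
        dmap = DensityMap(rng.normal(size=(32, 32, 32)), VOX)
        pose = Pose(np.array([10.0, 12.0, 14.0]), 0, 0, 0)
        subs, _ = extract_subvolumes(dmap, [pose], 8)
        assert np.array_equal(subs[0].values, dmap.values[10:18, 8:16, 6:14])

    def test_boundary_poses_skipped_with_count(self):
        dmap = DensityMap(np.zeros((20, 20, 20)), VOX)
        box = 8
        poses = [Pose(np.array([x, 10.0, 10.0]), 0, 0, 0) for x in np.arange(0.0, 20.0)]
        subs, skipped = extract_subvolumes(dmap, poses, box)
        # positions within half a box of either face cannot be cropped
        expected_ok = sum(1 for x in np.arange(20.0) if 0 <= round(x) - 4 and round(x) + 4 <= 20)
        assert len(subs) == expected_ok
        assert skipped == 20 - expected_ok


class TestAlign:
    def test_identity_scores_one(self, refs):
        a, _ = refs
        r = align_subvolume(centered_sub(a.values.copy()), a, AngularSearch.inplane(30.0))
        assert r.score == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(r.pose.position, 0.0, atol=0.01)

    def test_constructed_axial_shift_recovered(self, refs):
        a, _ = refs
        shifted = np.roll(a.values, 1, axis=0)  # density moved +1 voxel in z
        r = align_subvolume(centered_sub(shifted), a, AngularSearch.inplane(30.0),
                            shift_limit=1.38)
        assert abs(r.pose.position[2] - 1.0) <= 0.5  # particle center at +1 nm

    def test_constructed_inplane_rotation_recovered(self, refs):
        a, _ = refs
        vrot = rotate_density(a.values, zxz_matrix(40.0, 0, 0))
        r = align_subvolume(centered_sub(vrot), a, AngularSearch.inplane(10.0))
        assert r.score > 0.98
        # recovered pose must reproduce the subvolume from the reference
        avg = average_subvolumes([centered_sub(vrot)], [r.pose])
        assert correlation(avg.values, a.values) > 0.99

    def test_matches_exhaustive_grid_search_oracle(self, refs):
        a, _ = refs
        rng = np.random.default_rng(5)
        vol = rotate_density(a.values, zxz_matrix(60.0, 0, 0)) + rng.normal(
            0, 0.05, a.values.shape
        )
        sub = centered_sub(vol.astype(np.float32))
        search = AngularSearch.inplane(45.0)
        res = align_subvolume(sub, a, search, shift_limit=1.0, transverse_limit=1.0)

        # independent oracle: direct masked NCC over the same grid
        w = soft_cylinder_mask(BOX)
        wsum = w.sum()
        best = -np.inf
        sub_in_ref = sub.values.astype(float)
        for phi in np.arange(0.0, 360.0, 45.0):
            refq = rotate_density(a.values.astype(float), zxz_matrix(phi, 0, 0))
            swr = (w * refq).sum()
            sref = np.sqrt((w * refq**2).sum() - swr**2 / wsum)
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        shifted = np.roll(sub_in_ref, (-dz, -dy, -dx), axis=(0, 1, 2))
                        sw = (w * shifted).sum()
                        ssub = np.sqrt((w * shifted**2).sum() - sw**2 / wsum)
                        num = (w * refq * shifted).sum() - swr * sw / wsum
                        best = max(best, num / (sref * ssub))
        assert res.score >= best - 1e-6

    def test_score_invariant_under_simultaneous_90deg_rotation(self, refs):
        a, _ = refs
        rng = np.random.default_rng(7)
        vol = (a.values + rng.normal(0, 0.1, a.values.shape)).astype(np.float32)
        r1 = align_subvolume(centered_sub(vol), a, AngularSearch.inplane(30.0))
        R = zxz_matrix(90.0, 0, 0)  # exact for the grid
        vol_r = rotate_density(vol, R)
        ref_r = DensityMap(rotate_density(a.values, R), VOX, a.origin)
        r2 = align_subvolume(centered_sub(vol_r), ref_r, AngularSearch.inplane(30.0))
        assert r1.score == pytest.approx(r2.score, abs=5e-3)

    def test_mismatched_geometry_raises(self, refs):
        a, _ = refs
        bad = centered_sub(np.zeros((16, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError):
            align_subvolume(bad, a, AngularSearch.inplane(30.0))


class TestAverage:
    def test_identical_aligned_subvolumes_average_to_themselves(self, refs):
        a, _ = refs
        subs = [centered_sub(a.values.copy()) for _ in range(5)]
        avg = average_subvolumes(subs)
        assert correlation(avg.values, a.values) > 0.9999

    def test_noise_reduction_follows_central_limit(self):
        rng = np.random.default_rng(0)
        sigma, n = 2.0, 100
        subs = [
            centered_sub(rng.normal(0, sigma, (12, 12, 12)).astype(np.float32))
            for _ in range(n)
        ]
        avg = average_subvolumes(subs)
        assert avg.values.std() == pytest.approx(sigma / np.sqrt(n), rel=0.1)

    def test_randomized_phi_average_is_nearly_cylindrical(self, helix):
        # with the in-plane angle randomized, the unaligned average loses
        # azimuthal contrast: a featureless cylinder
        fil = Filament(0, "thin", np.array([[30.0, 30.0, 30.0], [90.0, 30.0, 30.0]]))
        tomo = render_filament_density(
            helical_poses(fil, helix), helix, VOX, (60, 60, 120),
            origin=np.array([0.0, 0.0, 0.0]),
        )
        rf = resample_centerline(fil, 1.38)
        poses = [p for p in init_poses(rf, 30.0, seed=3) if 42 < p.position[0] < 78]
        subs, _ = extract_subvolumes(tomo, poses, BOX)
        avg = average_subvolumes(subs)

        def azimuthal_variation(slice2d):
            c = (slice2d.shape[0] - 1) / 2.0
            y, x = np.mgrid[0 : slice2d.shape[0], 0 : slice2d.shape[1]] - c
            r = np.hypot(y, x)
            ring = (r > 2.5) & (r < 7.5)
            ang = (np.degrees(np.arctan2(y, x)) % 360.0)[ring]
            vals = slice2d[ring]
            prof = np.array(
                [vals[(ang >= 30 * k) & (ang < 30 * (k + 1))].mean() for k in range(12)]
            )
            return prof.std() / max(abs(prof.mean()), 1e-9)

        mid_avg = avg.values[BOX // 2 - 4 : BOX // 2 + 4].mean(axis=0)
        mid_tomo = tomo.values[30, 18:42, 18:42]
        # azimuthal contrast collapses relative to a single tomogram slice
        assert azimuthal_variation(mid_avg) < 0.5 * azimuthal_variation(mid_tomo)


class TestIterate:
    def test_noise_free_recovery_and_monotone_scores(self, helix, refs):
        a, _ = refs
        fils = [
            Filament(0, "thin", np.array([[15.0, 30.0, 30.0], [105.0, 30.0, 30.0]])),
            Filament(1, "thin", np.array([[15.0, 56.0, 30.0], [105.0, 56.0, 30.0]])),
        ]
        gp = []
        for f in fils:
            gp += helical_poses(f, helix, phi0=10 + f.id * 50)
        tomo = render_filament_density(gp, helix, VOX, (60, 90, 120),
                                       origin=np.array([0.0, 0.0, 0.0]))
        ps = []
        rng = np.random.default_rng(5)
        for f in fils:
            rf = resample_centerline(f, 1.38)
            ps += [p for p in init_poses(rf, 30.0, seed=rng) if 28 < p.position[0] < 92]
        subs, _ = extract_subvolumes(tomo, ps, BOX)
        sched = [AngularSearch.inplane(10.0)] * 2 + [AngularSearch.local(6.0, 2.0)]
        ref, poses, hist = iterate_alignment(subs, a, sched)
        assert all(b >= a_ - 1e-3 for a_, b in zip(hist, hist[1:]))
        assert best_registration_corr(a.values.astype(float), ref.values.astype(float)) > 0.95

    def test_divergence_guard_raises_after_three_decreasing_rounds(self, refs, monkeypatch):
        a, _ = refs
        canned = iter([0.9, 0.8, 0.7, 0.6])

        class FakeResult:
            def __init__(self, score, pose):
                self.score = score
                self.pose = pose

        def fake_score(subs, ref, search, *args, **kwargs):
            s = next(canned)
            return [FakeResult(s, sub.source_pose) for sub in subs]

        monkeypatch.setattr(subtomo_mod, "score_subvolumes", fake_score)
        subs = [centered_sub(a.values.copy())]
        with pytest.raises(RuntimeError, match="diverging"):
            subtomo_mod.iterate_alignment(subs, a, [AngularSearch.inplane(90.0)] * 4)


class TestDedupe:
    def test_oversampled_half_rise_positions_keep_alternate(self):
        poses = [
            Pose(np.array([1.38 * k, 0.0, 0.0]), 0, 0, 0, 0, k) for k in range(11)
        ]
        kept = dedupe_positions(poses, min_distance=2.76)
        assert kept == list(range(0, 11, 2))
        assert len(kept) == int(np.ceil(11 / 2))

    def test_single_pose_kept(self):
        assert dedupe_positions([Pose(np.zeros(3), 0, 0, 0, 0, 0)]) == [0]

    def test_greedy_maximality_bruteforce(self):
        rng = np.random.default_rng(8)
        poses = [
            Pose(np.array([x, 0.0, 0.0]), 0, 0, 0, 0, i)
            for i, x in enumerate(np.sort(rng.uniform(0, 40, 30)))
        ]
        scores = rng.uniform(size=30)
        kept = dedupe_positions(poses, scores, min_distance=2.76)
        kept_set = set(kept)
        # kept pairwise distances respect the threshold
        for i in kept:
            for j in kept:
                if i != j:
                    assert np.linalg.norm(poses[i].position - poses[j].position) >= 2.76
        # maximal: every dropped pose conflicts with a kept one
        for i in range(30):
            if i not in kept_set:
                assert any(
                    np.linalg.norm(poses[i].position - poses[j].position) < 2.76
                    for j in kept_set
                )

    def test_never_increases_and_respects_filament_grouping(self):
        poses = [Pose(np.array([0.0, 0.0, 0.0]), 0, 0, 0, fid, 0) for fid in range(4)]
        kept = dedupe_positions(poses, min_distance=5.0)
        assert kept == [0, 1, 2, 3]  # same position but different filaments


class TestFSC:
    def test_map_vs_itself_is_unity_at_nyquist(self):
        rng = np.random.default_rng(0)
        m = DensityMap(rng.normal(size=(32, 32, 32)), 0.5)
        c = fsc(m, m)
        assert np.allclose(c.correlations, 1.0, atol=1e-9)
        assert c.resolution == pytest.approx(2 * 0.5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = DensityMap(rng.normal(size=(24, 24, 24)), 1.0)
        b = DensityMap(rng.normal(size=(24, 24, 24)) + 0.2 * a.values, 1.0)
        ca, cb = fsc(a, b), fsc(b, a)
        assert np.allclose(ca.correlations, cb.correlations, atol=1e-12)

    def test_independent_noise_correlates_near_zero(self):
        rng = np.random.default_rng(2)
        a = DensityMap(rng.normal(size=(64, 64, 64)), 1.0)
        b = DensityMap(rng.normal(size=(64, 64, 64)), 1.0)
        c = fsc(a, b)
        assert np.abs(c.correlations).mean() < 0.05

    def test_band_limited_signal_crosses_at_planted_cutoff(self):
        rng = np.random.default_rng(3)
        n, vox = 48, 1.0
        f_cut = 0.25  # 1/nm
        sig = rng.normal(size=(n, n, n))
        F = np.fft.fftn(sig)
        freq = np.fft.fftfreq(n, d=vox)
        kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
        F[np.sqrt(kz**2 + ky**2 + kx**2) > f_cut] = 0.0
        sig = np.real(np.fft.ifftn(F))
        sig *= 40.0 / sig.std()
        a = DensityMap(sig + rng.normal(size=(n, n, n)), vox)
        b = DensityMap(sig + rng.normal(size=(n, n, n)), vox)
        c = fsc(a, b)
        shell_width = 1.0 / (n * vox)
        assert 1.0 / c.resolution == pytest.approx(f_cut, abs=shell_width)

    def test_box_mismatch_raises(self):
        a = DensityMap(np.zeros((8, 8, 8)), 1.0)
        b = DensityMap(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError):
            fsc(a, b)


class TestAssignPolarity:
    def test_identical_score_samples_unassigned_with_p_one(self, refs):
        a, b = refs
        subs = [
            centered_sub(a.values.copy(), Pose(np.zeros(3), 0, 0, 0, 0, k))
            for k in range(4)
        ]
        calls = assign_polarity(subs, a, a, AngularSearch.inplane(90.0), design="both")
        assert calls[0].call == "unassigned" and calls[0].p_value == 1.0

    def test_too_few_subvolumes_unassigned(self, refs):
        a, b = refs
        subs = [centered_sub(a.values.copy(), Pose(np.zeros(3), 0, 0, 0, 0, 0))]
        calls = assign_polarity(subs, a, b, AngularSearch.inplane(90.0))
        assert calls[0].call == "unassigned" and calls[0].p_value == 1.0

    def test_noise_free_known_polarity_fully_correct(self, tomo_scene, refs):
        _, subs, truth = tomo_scene
        a, b = refs
        calls = assign_polarity(subs, a, b, AngularSearch.inplane(15.0))
        assert all(c.call == truth[fid] for fid, c in calls.items())
        assert all(c.p_value < 0.05 for c in calls.values())

    def test_swapping_references_swaps_calls(self, tomo_scene, refs):
        _, subs, _ = tomo_scene
        a, b = refs
        # the score-both design is exactly symmetric under reference swap
        # (the split design is symmetric only in distribution)
        subs2 = [s for s in subs if s.source_pose.filament_id < 2]
        c1 = assign_polarity(subs2, a, b, AngularSearch.inplane(30.0), design="both")
        c2 = assign_polarity(subs2, b, a, AngularSearch.inplane(30.0), design="both")
        swap = {"A": "B", "B": "A", "unassigned": "unassigned"}
        for fid in c1:
            assert c2[fid].call == swap[c1[fid].call]
            assert c2[fid].p_value == pytest.approx(c1[fid].p_value, abs=1e-12)
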