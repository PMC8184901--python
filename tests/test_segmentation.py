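"""2.5D stack assembly, consensus voting, failure repair, Dice, backends."""

import dataclasses

import numpy as np
import pytest

from voxdose.phantom import OrganSpec, PhantomSpec, make_ct, make_spect
from voxdose.segmentation import (
    ReferenceBackend,
    SliceResult,
    SliceStack,
    build_stacks,
    consensus,
    dice,
    interpolate_missing,
    reference_backend,
    segment_consensus,
    segment_plane,
    spect_threshold_segment,
)
from voxdose.volumes import BinaryMask, GeometryError, VoxelGrid


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(grid=VoxelGrid(np.asarray(data, dtype=np.uint8), spacing=spacing))


def _disc(radius, n=64, center=None):
    c = (n - 1) / 2 if center is None else center
    yy, xx = np.mgrid[:n, :n]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)


def _sphere_volume(radius=20, n=56):
    c = (n - 1) / 2
    ii, jj, kk = np.mgrid[:n, :n, :n]
    inside = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= radius**2
    return inside


class _AlwaysFail:
    name = "always-fail"

    def __call__(self, stack: SliceStack) -> SliceResult:
        return SliceResult(
            mask=np.zeros(stack.center_frame.shape, dtype=np.uint8), success=False
        )


class _TruthBackend:
    """Oracle backend that thresholds the raw frame at half maximum."""

    name = "truth-threshold"

    def __init__(self, level: float):
        self.level = level

    def __call__(self, stack: SliceStack) -> SliceResult:
        return SliceResult(mask=(stack.center_frame >= self.level).astype(np.uint8))


class TestBuildStacks:
    def test_one_stack_per_slice_with_three_frames(self, rng):
        v = VoxelGrid(rng.random((12, 13, 10)))
        stacks = build_stacks(v, "axial", k=1)
        assert len(stacks) == 10
        assert all(s.slices.shape == (3, 12, 13) for s in stacks)

    def test_edge_padding_repeats_boundary_slice(self, rng):
        v = VoxelGrid(rng.random((6, 6, 8)))
        first = build_stacks(v, "axial", k=2)[0]
        np.testing.assert_array_equal(first.slices[0], first.slices[2])
        np.testing.assert_array_equal(first.slices[1], first.slices[2])
        np.testing.assert_array_equal(first.slices[2], v.data[:, :, 0])

    def test_k_zero_gives_pure_2d_mode(self, rng):
        v = VoxelGrid(rng.random((6, 6, 8)))
        stacks = build_stacks(v, "sagittal", k=0)
        assert all(s.slices.shape[0] == 1 for s in stacks)

    def test_plane_selects_axis(self, rng):
        v = VoxelGrid(rng.random((5, 6, 7)))
        assert len(build_stacks(v, "sagittal")) == 5
        assert len(build_stacks(v, "coronal")) == 6
        assert len(build_stacks(v, "axial")) == 7

    def test_excessive_context_rejected(self, rng):
        v = VoxelGrid(rng.random((4, 4, 4)))
        with pytest.raises(ValueError, match="context"):
            build_stacks(v, "axial", k=4)


class TestSegmentPlane:
    def test_failing_backend_yields_empty_volume_and_flags(self, rng):
        v = VoxelGrid(rng.random((8, 8, 8)))
        mask, flags = segment_plane(v, "axial", _AlwaysFail())
        assert mask.voxel_count == 0
        assert not flags.any()

    def test_backend_error_carries_slice_context(self, rng):
        class Boom:
            name = "boom"

            def __call__(self, stack):
                raise RuntimeError("kaput")

        v = VoxelGrid(rng.random((4, 4, 4)))
        with pytest.raises(RuntimeError, match="slice 0"):
            segment_plane(v, "axial", Boom())

    def test_axial_and_sagittal_agree_on_sphere(self):
        sphere = _sphere_volume()
        v = VoxelGrid(sphere.astype(np.float64))
        backend = _TruthBackend(level=0.5)
        m_ax, _ = segment_plane(v, "axial", backend)
        m_sag, _ = segment_plane(v, "sagittal", backend)
        assert dice(m_ax, m_sag) >= 0.95


class TestInterpolateMissing:
    def test_failed_slice_between_identical_neighbours(self):
        frame = _disc(12, n=32)
        vol = np.stack([frame, np.zeros_like(frame), frame], axis=-1)
        repaired = interpolate_missing(
            _mask(vol), np.array([True, False, True]), "axial"
        )
        np.testing.assert_array_equal(repaired.data[..., 1], frame)

    def test_midway_between_discs_gives_mid_disc(self):
        vol = np.zeros((64, 64, 3), dtype=np.uint8)
        vol[..., 0] = _disc(10)
        vol[..., 2] = _disc(20)
        repaired = interpolate_missing(
            _mask(vol), np.array([True, False, True]), "axial"
        )
        mid, want = repaired.data[..., 1].astype(bool), _disc(15).astype(bool)
        d = 2 * np.logical_and(mid, want).sum() / (mid.sum() + want.sum())
        assert d >= 0.97

    def test_all_successful_is_identity(self, rng):
        vol = (rng.random((8, 8, 4)) > 0.5).astype(np.uint8)
        m = _mask(vol)
        repaired = interpolate_missing(m, np.ones(4, dtype=bool), "axial")
        np.testing.assert_array_equal(repaired.data, vol)

    def test_end_failures_copy_nearest_success(self):
        frame = _disc(8, n=16)
        vol = np.stack([np.zeros_like(frame), np.zeros_like(frame), frame], axis=-1)
        repaired = interpolate_missing(
            _mask(vol), np.array([False, False, True]), "axial"
        )
        np.testing.assert_array_equal(repaired.data[..., 0], frame)
        np.testing.assert_array_equal(repaired.data[..., 1], frame)

    def test_no_successful_slices_raises(self):
        m = _mask(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="no successful"):
            interpolate_missing(m, np.zeros(3, dtype=bool), "axial")


class TestConsensus:
    def test_three_identical_masks_return_that_mask(self, rng):
        m = _mask((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        out = consensus(m, m, m)
        np.testing.assert_array_equal(out.data, m.data)

    def test_two_of_three_votes_set_voxel(self):
        a = _mask(np.ones((2, 2, 2)))
        b = _mask(np.ones((2, 2, 2)))
        c = _mask(np.zeros((2, 2, 2)))
        assert consensus(a, b, c).data.all()
        assert not consensus(a, c, _mask(np.zeros((2, 2, 2)))).data.any()

    def test_matches_brute_force_vote_on_random_masks(self, rng):
        vols = [(rng.random((20, 20, 20)) > 0.5).astype(np.uint8) for _ in range(3)]
        out = consensus(*[_mask(v) for v in vols])
        # exhaustive per-voxel oracle
        expect = np.zeros((20, 20, 20), dtype=np.uint8)
        for idx in np.ndindex(20, 20, 20):
            votes = sum(v[idx] for v in vols)
            expect[idx] = 1 if votes >= 2 else 0
        np.testing.assert_array_equal(out.data, expect)

    def test_permutation_invariant(self, rng):
        vols = [(rng.random((9, 9, 9)) > 0.4).astype(np.uint8) for _ in range(3)]
        a, b, c = (_mask(v) for v in vols)
        np.testing.assert_array_equal(consensus(a, b, c).data, consensus(c, a, b).data)

    def test_geometry_mismatch_rejected(self):
        a = _mask(np.zeros((4, 4, 4)))
        b = _mask(np.zeros((4, 4, 4)), spacing=(2.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            consensus(a, a, b)


class TestDice:
    def test_identical_masks_score_one(self, rng):
        m = _mask((rng.random((5, 5, 5)) > 0.5).astype(np.uint8))
        assert dice(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_half_overlap_by_hand(self):
        a = np.zeros((10, 10, 2), dtype=np.uint8)
        b = np.zeros((10, 10, 2), dtype=np.uint8)
        a[:10, :10, 0] = 1  # |a| = 100
        b[:5, :10, 0] = 1  # overlap 50
        b[:5, :10, 1] = 1  # |b| = 100
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        m = _mask(np.zeros((3, 3, 3)))
        assert dice(m, m) == 1.0

    def test_symmetric(self, rng):
        a = _mask((rng.random((6, 6, 6)) > 0.3).astype(np.uint8))
        b = _mask((rng.random((6, 6, 6)) > 0.7).astype(np.uint8))
        assert dice(a, b) == dice(b, a)


class TestReferenceBackend:
    def test_phantom_kidneys_recovered_with_high_dice(self, default_spec, ct_and_masks):
        ct, masks = ct_and_masks
        union = BinaryMask(
            grid=ct.with_data(
                (masks["left_kidney"].data | masks["right_kidney"].data).astype(
                    np.uint8
                ),
                intensity_kind="unitless",
            )
        )
        m, flags = segment_plane(ct, "axial", reference_backend())
        assert dice(m, union) >= 0.95
        # slices without any organ are reported as failures, not as empty successes
        organ_slices = union.data.any(axis=(0, 1))
        np.testing.assert_array_equal(flags, organ_slices)

    def test_empty_slice_reports_failure(self):
        stack = SliceStack(
            slices=np.full((3, 16, 16), -1000.0), center_index=0, plane="axial"
        )
        assert not reference_backend()(stack).success

    def test_two_organs_two_components_bbox_covers_union(self):
        frame = np.full((40, 40), -1000.0)
        frame[5:12, 5:12] = 50.0
        frame[25:36, 25:36] = 50.0
        stack = SliceStack(slices=frame[None], center_index=0, plane="axial")
        res = reference_backend()(stack)
        from scipy import ndimage

        _, ncomp = ndimage.label(res.mask)
        assert ncomp == 2
        assert res.bbox == (5, 5, 36, 36)

    def test_min_area_filter_drops_specks(self):
        frame = np.full((30, 30), -1000.0)
        frame[4, 4] = 50.0  # single-pixel speck
        frame[10:20, 10:20] = 50.0
        res = reference_backend(min_area_px=10, closing_radius_px=0)(
            SliceStack(slices=frame[None], center_index=0, plane="axial")
        )
        assert res.mask[4, 4] == 0
        assert res.mask[10:20, 10:20].all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            reference_backend(window_lo=10, window_hi=-10)
        with pytest.raises(ValueError):
            reference_backend(threshold=1.5)


class TestRepairProperty:
    def test_ten_percent_failures_lose_little_dice(self, ct_and_masks):
        """Randomly failing 10% of kidney-bearing slices then repairing
        must stay within 0.03 Dice of the no-failure segmentation."""
        ct, masks = ct_and_masks
        union = BinaryMask(
            grid=ct.with_data(
                (masks["left_kidney"].data | masks["right_kidney"].data).astype(
                    np.uint8
                ),
                intensity_kind="unitless",
            )
        )
        backend = reference_backend()
        clean, flags = segment_plane(ct, "axial", backend)
        base = dice(clean, union)
        rng = np.random.default_rng(42)
        fail_flags = flags.copy()
        candidates = np.nonzero(flags)[0]
        fail_flags[rng.choice(candidates, size=max(1, len(candidates) // 10),
                              replace=False)] = False
        broken = clean.data.copy()
        broken[:, :, ~fail_flags] = 0
        repaired = interpolate_missing(
            BinaryMask(grid=clean.grid.with_data(broken)), fail_flags, "axial"
        )
        assert base - dice(repaired, union) <= 0.03


class TestConsensusPipeline:
    def test_consensus_on_phantom_beats_threshold(self, ct_and_masks):
        ct, masks = ct_and_masks
        union = BinaryMask(
            grid=ct.with_data(
                (masks["left_kidney"].data | masks["right_kidney"].data).astype(
                    np.uint8
                ),
                intensity_kind="unitless",
            )
        )
        m = segment_consensus(ct, reference_backend())
        assert dice(m, union) >= 0.95


class TestSpectThreshold:
    def test_uniform_organ_recovers_exact_support(self):
        spec = PhantomSpec(
            shape=(40, 40, 40),
            spacing_mm=(2.0, 2.0, 2.0),
            organs=[
                OrganSpec(
                    name="k",
                    center_mm=(40.0, 40.0, 40.0),
                    semi_axes_mm=(20.0, 15.0, 25.0),
                    hu_value=40.0,
                    kinetics=(5e7, 0.3, 1e7, 0.01),
                )
            ],
        )
        spect = make_spect(spec, 6.0)
        _, masks = make_ct(spec)
        voi = spect_threshold_segment(spect, frac=0.5)
        np.testing.assert_array_equal(voi.data, masks["k"].data)

    def test_threshold_volume_on_blurred_phantom(self, blurred_spec):
        """42%-of-max thresholding of the σ=3 mm blurred kidney recovers
        the physical organ volume within 10%."""
        spect = make_spect(blurred_spec, 24.0)
        _, masks = make_ct(blurred_spec)
        from voxdose.kinetics import expand_mask

        for name in ("left_kidney", "right_kidney"):
            seed = expand_mask(masks[name], margin_mm=12.0).extended
            voi = spect_threshold_segment(spect, frac=0.42, seed_region=seed)
            assert voi.volume_ml == pytest.approx(masks[name].volume_ml, rel=0.10)

    def test_higher_fraction_nested_in_lower(self, blurred_spec):
        spect = make_spect(blurred_spec, 24.0)
        lo = spect_threshold_segment(spect, frac=0.5)
        hi = spect_threshold_segment(spect, frac=0.99)
        assert np.all(lo.as_bool() | ~hi.as_bool())
        assert hi.voxel_count < lo.voxel_count

    def test_all_zero_spect_rejected(self):
        v = VoxelGrid(np.zeros((8, 8, 8)), intensity_kind="activity_conc_Bq_per_ml")
        with pytest.raises(ValueError, match="all-zero"):
            spect_threshold_segment(v)
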