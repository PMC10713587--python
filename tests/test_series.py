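"""Tests for the dynamic-series container and preprocessing operations."""

import numpy as np
import pytest
from scipy import signal

from sparsectp.kinetics import GammaVariate, TimeDensityCurve
from sparsectp.series import (
    HEMI_LEFT,
    HEMI_RIGHT,
    AcquisitionProtocol,
    DynamicSeries,
    NoVesselError,
    apply_inplane_transform,
    assemble_mcta_p,
    correct_mcta_bias,
    detect_aif_vof,
    downsample_ctp,
    interpolate_to_1s,
    motion_correct_inplane,
    slab_average,
    smooth_spatial,
)


def make_series(frames, times, spacing=(2.0, 2.0, 5.0), mask=None, hemi=None):
    return DynamicSeries(
        frames=frames, times=times, spacing=spacing,
        brain_mask=mask, hemisphere_labels=hemi,
    )


class TestProtocolConstants:
    def test_ctp_timing(self):
        t = np.asarray(AcquisitionProtocol.ctp().frame_times)
        assert len(t) == 28
        np.testing.assert_allclose(t[:22], 5.0 + 2.8 * np.arange(22))
        np.testing.assert_allclose(np.diff(t[21:]), 15.0)

    def test_mcta_timing_and_bias(self):
        p = AcquisitionProtocol.mcta_p()
        assert p.frame_times == (0.0, 16.0, 24.0, 32.0)
        assert p.bias_hu == 4.0


class TestInterpolateTo1s:
    def test_linear_values(self):
        frames = np.zeros((1, 1, 1, 2))
        frames[..., 1] = 2.8
        out = interpolate_to_1s(make_series(frames, [0.0, 2.8]))
        np.testing.assert_allclose(out.times, [0, 1, 2])
        np.testing.assert_allclose(out.frames[0, 0, 0], [0.0, 1.0, 2.0])

    def test_constant_series_unchanged(self):
        frames = np.full((2, 2, 1, 4), 7.0)
        out = interpolate_to_1s(make_series(frames, [0, 16, 24, 32]))
        assert out.frames.shape[-1] == 33
        np.testing.assert_allclose(out.frames, 7.0)

    def test_matches_scalar_interpolation_oracle(self, rng):
        times = np.sort(rng.uniform(0, 50, 12))
        times[0], times[-1] = 0.0, 50.0
        frames = rng.normal(size=(3, 2, 2, 12))
        out = interpolate_to_1s(make_series(frames, times))
        for idx in np.ndindex(3, 2, 2):
            expected = np.interp(out.times, times, frames[idx])
            np.testing.assert_allclose(out.frames[idx], expected, atol=1e-12)

    def test_idempotent_on_1s_grid(self, rng):
        frames = rng.normal(size=(2, 2, 1, 20))
        s = make_series(frames, np.arange(20.0))
        out = interpolate_to_1s(s)
        np.testing.assert_array_equal(out.frames, frames)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            interpolate_to_1s(make_series(np.zeros((1, 1, 1, 1)), [0.0]))


class TestSmoothSpatial:
    def test_uniform_frame_unchanged(self):
        frames = np.full((16, 16, 2, 3), 50.0)
        out = smooth_spatial(make_series(frames, [0, 1, 2]), fwhm_mm=4.8)
        np.testing.assert_allclose(out.frames, 50.0, atol=1e-9)

    def test_point_source_matches_kernel_oracle(self):
        spacing = (2.0, 2.0, 5.0)
        frames = np.zeros((33, 33, 1, 1))
        frames[16, 16, 0, 0] = 1.0
        s = DynamicSeries(np.repeat(frames, 2, axis=3), [0.0, 1.0], spacing)
        out = smooth_spatial(s, fwhm_mm=4.8)
        sigma_vox = 4.8 / np.sqrt(8 * np.log(2)) / 2.0
        radius = int(4.0 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = signal.convolve2d(frames[:, :, 0, 0], kernel, mode="same")
        np.testing.assert_allclose(out.frames[:, :, 0, 0], expected, atol=1e-6)

    def test_mean_preserved_away_from_boundary(self, rng):
        frames = np.zeros((40, 40, 1, 1))
        frames[15:25, 15:25, 0, 0] = rng.uniform(10, 60, (10, 10))
        s = DynamicSeries(np.repeat(frames, 2, axis=3), [0.0, 1.0], (2, 2, 5))
        out = smooth_spatial(s, fwhm_mm=4.8)
        assert out.frames[..., 0].mean() == pytest.approx(
            frames[..., 0].mean(), rel=1e-3
        )

    def test_invalid_fwhm_rejected(self):
        s = DynamicSeries(np.zeros((4, 4, 1, 2)), [0, 1], (2, 2, 5))
        with pytest.raises(ValueError):
            smooth_spatial(s, fwhm_mm=0.0)


def _smooth_blobs(rng, shape=(48, 48, 2)):
    img = np.zeros(shape)
    for _ in range(6):
        cx, cy = rng.uniform(12, 36, 2)
        amp = rng.uniform(20, 60)
        x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        blob = amp * np.exp(-(((x - cx) / 5.0) ** 2 + ((y - cy) / 5.0) ** 2))
        img += blob[:, :, None]
    return img


class TestMotionCorrect:
    def test_identity_for_static_series(self, rng):
        base = _smooth_blobs(rng)
        frames = np.stack([base, base, base], axis=3)
        mask = base > 5
        s = DynamicSeries(frames, [0, 1, 2], (2, 2, 5), brain_mask=mask)
        corrected, log = motion_correct_inplane(s)
        for entry in log:
            assert abs(entry["dx_vox"]) < 0.1
            assert abs(entry["dy_vox"]) < 0.1
            assert abs(entry["theta_deg"]) < 0.1

    def test_recovers_known_translation(self, rng):
        base = _smooth_blobs(rng)
        moved = apply_inplane_transform(base, 3.0, -2.0, 0.0)
        mask = base > 5
        s = DynamicSeries(
            np.stack([base, moved], axis=3), [0, 1], (2, 2, 5), brain_mask=mask
        )
        _, log = motion_correct_inplane(s)
        # registering the moved frame needs the inverse translation
        assert abs(log[1]["dx_vox"] + 3.0) < 0.5
        assert abs(log[1]["dy_vox"] - 2.0) < 0.5

    def test_recovers_known_rotation(self, rng):
        base = _smooth_blobs(rng)
        moved = apply_inplane_transform(base, 0.0, 0.0, 3.0)
        mask = base > 5
        s = DynamicSeries(
            np.stack([base, moved], axis=3), [0, 1], (2, 2, 5), brain_mask=mask
        )
        _, log = motion_correct_inplane(s)
        assert abs(log[1]["theta_deg"] + 3.0) < 0.5

    def test_empty_mask_rejected(self):
        s = DynamicSeries(
            np.zeros((8, 8, 1, 2)), [0, 1], (2, 2, 5),
            brain_mask=np.zeros((8, 8, 1), bool),
        )
        with pytest.raises(ValueError):
            motion_correct_inplane(s)


def _vessel_phantom():
    """One artery-like voxel cluster (tall, early, narrow) and one vein-like
    cluster (larger integral, later) in a low-enhancement background."""
    times = np.arange(0.0, 40.0)
    artery = GammaVariate(peak_hu=200, onset_s=5, alpha=3, scale_s=2)
    vein = GammaVariate(peak_hu=220, onset_s=8, alpha=3, scale_s=5)
    frames = np.zeros((16, 16, 1, len(times)))
    frames[...] = 1.0 + 0.02 * times  # faint drift background
    frames[4:7, 4:7, 0, :] = artery.value(times)
    frames[10:13, 10:13, 0, :] = vein.value(times)
    mask = np.zeros((16, 16, 1), bool)
    mask[1:15, 1:15] = True
    return DynamicSeries(frames, times, (2, 2, 5), brain_mask=mask)


class TestDetectAifVof:
    def test_assigns_correct_voxels(self):
        s = _vessel_phantom()
        vessels = detect_aif_vof(s)
        ax, ay, _ = vessels.aif_location
        vx, vy, _ = vessels.vof_location
        assert (4 <= ax < 7) and (4 <= ay < 7)
        assert (10 <= vx < 13) and (10 <= vy < 13)

    def test_peak_time_ordering(self):
        vessels = detect_aif_vof(_vessel_phantom())
        assert vessels.aif.peak_time <= vessels.vof.peak_time

    def test_zero_enhancement_rejected(self):
        frames = np.zeros((8, 8, 1, 5))
        s = DynamicSeries(frames, np.arange(5.0), (2, 2, 5),
                          brain_mask=np.ones((8, 8, 1), bool))
        with pytest.raises(NoVesselError):
            detect_aif_vof(s)


class TestDownsampleCtp:
    def _ctp_series(self, peak_index):
        proto = AcquisitionProtocol.ctp()
        times = np.asarray(proto.frame_times)
        values = np.exp(-0.5 * ((np.arange(len(times)) - peak_index) / 2.0) ** 2)
        frames = np.broadcast_to(values, (2, 2, 1, len(times))).copy()
        return (
            DynamicSeries(frames, times, (2, 2, 5)),
            TimeDensityCurve(times, values),
        )

    def test_default_protocol_frame_selection(self):
        # AIF peaking at frame 6 (t = 21.8 s); nearest frames to 29.8 and
        # 37.8 on the 2.8 s grid are 30.2 and 38.6
        s, aif = self._ctp_series(peak_index=6)
        out = downsample_ctp(s, aif)
        np.testing.assert_allclose(out.times, [5.0, 21.8, 30.2, 38.6])

    def test_frames_copied_bitwise(self):
        s, aif = self._ctp_series(peak_index=6)
        out = downsample_ctp(s, aif)
        src_idx = [0, 6, 9, 12]
        np.testing.assert_array_equal(out.frames, s.frames[..., src_idx])

    def test_output_shape_and_monotonic_times(self):
        s, aif = self._ctp_series(peak_index=8)
        out = downsample_ctp(s, aif)
        assert out.n_frames == 4
        assert np.all(np.diff(out.times) > 0)

    def test_monotonic_aif_rejected(self):
        proto = AcquisitionProtocol.ctp()
        times = np.asarray(proto.frame_times)
        values = np.linspace(0, 1, len(times))
        frames = np.zeros((1, 1, 1, len(times)))
        s = DynamicSeries(frames, times, (2, 2, 5))
        with pytest.raises(ValueError):
            downsample_ctp(s, TimeDensityCurve(times, values))

    def test_peak_at_first_frame_rejected(self):
        s, aif = self._ctp_series(peak_index=0)
        with pytest.raises(ValueError, match="baseline"):
            downsample_ctp(s, aif)


class TestAssembleMctaP:
    def _inputs(self):
        shape = (6, 6, 2)
        ncct = np.full(shape, 30.0)
        phases = [np.full(shape, 40.0 + i) for i in range(3)]
        mask = np.zeros(shape, bool)
        mask[1:5, 1:5, :] = True
        return ncct, phases, mask

    def test_bias_subtracted_in_brain_only(self):
        ncct, phases, mask = self._inputs()
        s = assemble_mcta_p(ncct, phases, mask, (2, 2, 5), bias_hu=4.0)
        np.testing.assert_allclose(s.times, [0, 16, 24, 32])
        assert s.frames[2, 2, 0, 1] == 36.0  # brain voxel, 40 - 4
        assert s.frames[0, 0, 0, 1] == 40.0  # non-brain untouched
        assert s.frames[2, 2, 0, 0] == 30.0  # NCCT untouched

    def test_adding_bias_back_restores_inputs(self):
        ncct, phases, mask = self._inputs()
        s = assemble_mcta_p(ncct, phases, mask, (2, 2, 5), bias_hu=4.0)
        restored = correct_mcta_bias(s, -4.0)
        for j, phase in enumerate(phases):
            np.testing.assert_array_equal(restored.frames[..., j + 1], phase)

    def test_zero_bias_passthrough(self):
        ncct, phases, mask = self._inputs()
        s = assemble_mcta_p(ncct, phases, mask, (2, 2, 5), bias_hu=0.0)
        for j, phase in enumerate(phases):
            np.testing.assert_array_equal(s.frames[..., j + 1], phase)

    def test_shape_mismatch_rejected(self):
        ncct, phases, mask = self._inputs()
        phases[1] = phases[1][:-1]
        with pytest.raises(ValueError):
            assemble_mcta_p(ncct, phases, mask, (2, 2, 5))


class TestSlabAverage:
    def test_window_means_match_oracle(self):
        nz = 32
        dz = 0.625
        frames = np.zeros((2, 2, nz, 1))
        for k in range(nz):
            frames[:, :, k, 0] = k
        s = DynamicSeries(np.repeat(frames, 2, axis=3), [0, 1], (1, 1, dz))
        out = slab_average(s, slab_mm=10.0, step_mm=5.0)
        # each slab holds 16 slices; slab k starts at slice 8k
        n_out = out.frames.shape[2]
        assert n_out == 3
        for k in range(n_out):
            members = np.arange(8 * k, 8 * k + 16)
            assert out.frames[0, 0, k, 0] == pytest.approx(members.mean())
        assert out.spacing[2] == 5.0

    def test_uniform_volume_unchanged(self):
        frames = np.full((2, 2, 32, 2), 12.5)
        s = DynamicSeries(frames, [0, 1], (1, 1, 0.625))
        out = slab_average(s)
        np.testing.assert_allclose(out.frames, 12.5)

    def test_adjacent_slabs_share_half_their_slices(self):
        dz, slab, step = 0.625, 10.0, 5.0
        z = np.arange(32) * dz
        w0 = set(np.flatnonzero((z >= 0) & (z < slab)))
        w1 = set(np.flatnonzero((z >= step) & (z < step + slab)))
        assert len(w0 & w1) == len(w0) // 2

    def test_extent_too_small_rejected(self):
        s = DynamicSeries(np.zeros((2, 2, 4, 2)), [0, 1], (1, 1, 0.625))
        with pytest.raises(ValueError):
            slab_average(s, slab_mm=10.0)


class TestHemisphereLabels:
    def test_labels_partition_brain(self, ctp_phantom):
        series, _, _ = ctp_phantom
        labels = series.hemisphere_labels
        brain = series.brain_mask
        assert set(np.unique(labels[brain])) <= {HEMI_LEFT, HEMI_RIGHT}
        assert np.all(labels[~brain] == 0)
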