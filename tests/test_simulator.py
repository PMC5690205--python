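"""Renderer and cine-study simulator: sub-pixel fidelity, timing, I/O."""

import numpy as np
import pytest

from resp4d import (
    AcquisitionConfig,
    MotionWaveform,
    WaveformKind,
    read_study,
    render_frame,
    simulate_cine_study,
    write_study,
)
from resp4d.geometry import DEFAULT_GEOMETRY
from resp4d.simulator import DEFAULT_SCENE, HU_BACKGROUND, HU_WIRE

from conftest import make_study

CFG0 = AcquisitionConfig(n_slabs=1, slices_per_slab=1, noise_sd_hu=0.0)
SPACING = CFG0.pixel_spacing_mm


def brute_force_centroid(img, x_px, y_px, halfwidth=6):
    """Independent oracle: intensity-above-background centroid over a
    window around the nominal disc position."""
    r0, c0 = int(round(y_px)) - halfwidth, int(round(x_px)) - halfwidth
    patch = img[r0 : r0 + 2 * halfwidth + 1, c0 : c0 + 2 * halfwidth + 1].astype(float)
    w = patch - HU_BACKGROUND
    rows, cols = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    return (
        float((cols * w).sum() / w.sum()) + c0,
        float((rows * w).sum() / w.sum()) + r0,
    )


class TestRenderFrame:
    def test_config_derived_quantities(self):
        assert CFG0.pixel_spacing_mm == pytest.approx(500.0 / 768)
        assert CFG0.frames_per_slice == 20

    def test_peak_at_pixel_aligned_center(self):
        # put the left wire exactly on a pixel centre
        x_mm = (107 + 0.5) * SPACING
        y_mm = (583 + 0.5) * SPACING
        img = render_frame(y_mm, y_mm, (x_mm, 430.0), CFG0)
        assert img[583, 107] == img.max()
        assert img[583, 107] >= HU_WIRE - 1

    def test_noiseless_centroid_tracks_subpixel_offset(self):
        y_px = 583.0
        for dy in (0.25, 0.5, 0.75):
            y_mm = (y_px + dy + 0.5) * SPACING
            img = render_frame(y_mm, y_mm, DEFAULT_SCENE.wire_x_mm, CFG0)
            x_true = DEFAULT_SCENE.wire_x_mm[0] / SPACING - 0.5
            _, cy = brute_force_centroid(img, x_true, y_px + dy)
            assert cy == pytest.approx(y_px + dy, abs=0.1)

    def test_centroid_fidelity_over_random_positions(self):
        """Noiseless rendered-disc centroid within 0.1 px of request,
        checked against the brute-force oracle at 100 random sub-pixel
        positions."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            x_px = rng.uniform(100.0, 120.0)
            y_px = rng.uniform(570.0, 590.0)
            x_mm, y_mm = (x_px + 0.5) * SPACING, (y_px + 0.5) * SPACING
            img = render_frame(y_mm, y_mm, (x_mm, 430.0), CFG0)
            cx, cy = brute_force_centroid(img, x_px, y_px)
            worst = max(worst, np.hypot(cx - x_px, cy - y_px))
        assert worst < 0.1

    def test_mirrored_wires_give_mirror_symmetric_image(self):
        x1, x2 = 100.0, CFG0.fov_mm - 100.0
        img = render_frame(380.0, 380.0, (x1, x2), CFG0)
        np.testing.assert_array_equal(img, np.fliplr(img))

    def test_disc_on_border_rejected(self):
        with pytest.raises(ValueError, match="border"):
            render_frame(0.5, 380.0, DEFAULT_SCENE.wire_x_mm, CFG0)


class TestSimulateStudy:
    def test_default_protocol_frame_count(self):
        study = make_study(
            amplitude_mm=2.0, noise_sd_hu=0.0, n_slabs=4, slices_per_slab=8, seed=0
        )
        assert len(study.frames) == 4 * 8 * 20
        assert len(study.slice_keys()) == 32

    def test_timing_grid_and_slab_sequencing(self):
        study = make_study(amplitude_mm=2.0, noise_sd_hu=0.0, n_slabs=2, slices_per_slab=2, seed=0)
        t_first = [f.time_s for f in study.frames_for_slice((0, 0))]
        np.testing.assert_allclose(t_first, np.arange(20) * 0.8)
        t_second_slab = [f.time_s for f in study.frames_for_slice((1, 0))]
        np.testing.assert_allclose(t_second_slab, 16.0 + np.arange(20) * 0.8)

    def test_constant_waveform_frames_identical_without_noise(self):
        study = make_study(kind=WaveformKind.CONSTANT, amplitude_mm=0.0, noise_sd_hu=0.0, seed=0)
        frames = study.frames_for_slice((0, 0))
        for f in frames[1:]:
            np.testing.assert_array_equal(f.pixels, frames[0].pixels)

    def test_wire_travel_follows_lever_ratio(self):
        # slice exactly at mid-span: ratio 0.5, so a +/-10 mm waveform
        # moves the wires by ~10 mm peak-to-peak in the image
        g = DEFAULT_GEOMETRY
        z_mid = (g.z0_mm + g.zp_mm) / 2.0
        study = make_study(amplitude_mm=10.0, noise_sd_hu=0.0, slice_zs=[z_mid], seed=0)
        ys = np.array([f.true_centers_px[0][1] for f in study.frames]) * SPACING
        assert 9.8 <= ys.max() - ys.min() <= 10.0

    def test_identical_seed_reproduces_study_bitwise(self):
        s1 = make_study(amplitude_mm=5.0, seed=123)
        s2 = make_study(amplitude_mm=5.0, seed=123)
        for f1, f2 in zip(s1.frames, s2.frames):
            np.testing.assert_array_equal(f1.pixels, f2.pixels)
            assert f1.time_s == f2.time_s

    def test_empty_slice_list_rejected(self):
        w = MotionWaveform(WaveformKind.SINE, amplitude_mm=1.0, period_s=6.0)
        with pytest.raises(ValueError):
            simulate_cine_study(w, DEFAULT_GEOMETRY, CFG0, slice_zs=[])


@pytest.fixture(scope="module")
def tiny_study():
    return make_study(amplitude_mm=3.0, seed=5, cine_duration_s=1.6)  # 2 frames


class TestStudyIO:
    @pytest.mark.parametrize("fmt", ["tiff", "dicom"])
    def test_round_trip_pixels_and_metadata(self, tiny_study, fmt, tmp_path):
        write_study(tiny_study, tmp_path / fmt, format=fmt)
        back = read_study(tmp_path / fmt)
        assert len(back.frames) == len(tiny_study.frames)
        for f0, f1 in zip(tiny_study.frames, back.frames):
            np.testing.assert_array_equal(f0.pixels, f1.pixels)
            assert f1.time_s == pytest.approx(f0.time_s, abs=1e-6)
            assert f1.slice_z_mm == f0.slice_z_mm
            assert f1.pixel_spacing_mm == pytest.approx(f0.pixel_spacing_mm)

    def test_dicom_times_parse_back_in_order(self, tiny_study, tmp_path):
        write_study(tiny_study, tmp_path / "d", format="dicom")
        back = read_study(tmp_path / "d")
        times = [f.time_s for f in back.frames_for_slice((0, 0))]
        assert times == sorted(times)

    def test_ground_truth_sidecar_iff_present(self, tiny_study, tmp_path):
        write_study(tiny_study, tmp_path / "gt", format="tiff")
        assert read_study(tmp_path / "gt").ground_truth is not None
        stripped = type(tiny_study)(
            frames=tiny_study.frames,
            geometry=tiny_study.geometry,
            acquisition=tiny_study.acquisition,
            scene=tiny_study.scene,
            ground_truth=None,
        )
        write_study(stripped, tmp_path / "nogt", format="tiff")
        assert read_study(tmp_path / "nogt").ground_truth is None
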