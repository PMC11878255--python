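import numpy as np
import pytest

import bblattice as bl
from conftest import hankel_field, profile_fwhm

WL = 0.488


@pytest.fixture(scope="module")
def gaussian_field(grid_512):
    return bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="gaussian", w0=50.0), WL)


class TestApplyTransmission:
    def test_identity_transmission(self, gaussian_field):
        out = bl.apply_transmission(gaussian_field, np.ones(gaussian_field.grid.shape))
        np.testing.assert_array_equal(out.data, gaussian_field.data)

    def test_annulus_passes_area_fraction_of_power(self, grid_512, default_beamlet):
        beam = bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="uniform"), WL)
        m = bl.annulus_mask(grid_512, default_beamlet)
        out = bl.apply_transmission(beam, m)
        assert bl.field_power(out) / bl.field_power(beam) == pytest.approx(m.mean())

    def test_pure_phase_conserves_power(self, gaussian_field):
        phase = np.random.default_rng(0).uniform(-np.pi, np.pi, gaussian_field.grid.shape)
        out = bl.apply_transmission(gaussian_field, np.exp(1j * phase))
        assert bl.field_power(out) == pytest.approx(bl.field_power(gaussian_field), rel=1e-12)

    def test_grid_mismatch_rejected(self, gaussian_field):
        with pytest.raises(ValueError, match="shape"):
            bl.apply_transmission(gaussian_field, np.ones((16, 16)))


class TestPropagator:
    def test_zero_distance_is_identity(self, gaussian_field):
        out = bl.propagate(gaussian_field, 0.0)
        np.testing.assert_allclose(out.data, gaussian_field.data, rtol=1e-12)

    def test_energy_conservation(self, gaussian_field):
        out = bl.propagate(gaussian_field, 1000.0)
        assert bl.field_power(out) == pytest.approx(
            bl.field_power(gaussian_field), rel=1e-9
        )

    def test_semigroup_two_half_steps(self, gaussian_field):
        one = bl.propagate(gaussian_field, 800.0)
        two = bl.propagate(bl.propagate(gaussian_field, 400.0), 400.0)
        err = np.linalg.norm(two.data - one.data) / np.linalg.norm(one.data)
        assert err < 1e-10
        assert two.z == one.z

    def test_unitarity_forward_backward(self, gaussian_field):
        back = bl.propagate(bl.propagate(gaussian_field, 600.0), -600.0)
        err = np.linalg.norm(back.data - gaussian_field.data) / np.linalg.norm(
            gaussian_field.data
        )
        assert err < 1e-10

    def test_gaussian_waist_law_at_rayleigh_range(self, gaussian_field):
        # intensity FWHM grows by sqrt(2) at z_R = pi w0^2 / lambda
        w0 = 50.0
        z_r = np.pi * w0**2 / WL
        g = gaussian_field.grid
        row = g.ny // 2
        fw0 = profile_fwhm(g.x, np.abs(gaussian_field.data[row]) ** 2)
        assert fw0 == pytest.approx(w0 * np.sqrt(2 * np.log(2)), rel=1e-3)
        out = bl.propagate(gaussian_field, z_r)
        fw1 = profile_fwhm(g.x, np.abs(out.data[row]) ** 2)
        assert fw1 == pytest.approx(np.sqrt(2) * fw0, rel=0.01)

    def test_airy_pattern_of_full_disk_lens(self, grid_1024):
        # near-full disk + lens phase: focus at z≈f with first dark ring at
        # 1.22 λ f / (2R)
        from conftest import hankel_onaxis_intensity

        disk = bl.BeamletSpec(R=100.0, delta=99.9, f=2000.0)
        beam = bl.make_input_beam(grid_1024, bl.InputBeamSpec(kind="uniform"), WL)
        f0 = bl.apply_transmission(beam, bl.beamlet_transmission(grid_1024, disk, WL))
        z = np.arange(1900.0, 2041.0, 10.0)
        stack = bl.propagate_stack(f0, z)
        iz = int(np.argmax([fr.max() for fr in stack.frames]))
        # the apertured lens peaks slightly before f (low Fresnel number); the
        # on-axis quadrature oracle predicts where
        z_pred = z[int(np.argmax(hankel_onaxis_intensity(z, R=100.0, delta=99.9, f=2000.0)))]
        assert abs(stack.z_list[iz] - z_pred) <= 10.0
        # the textbook dark-ring radius holds at the Fourier plane z = f
        frame = stack.frame_at(2000.0).astype(float)
        row = grid_1024.ny // 2
        prof = frame[row, grid_1024.nx // 2 :]
        first_min = next(
            i for i in range(1, 30) if prof[i] < prof[i - 1] and prof[i] <= prof[i + 1]
        )
        r_dark = grid_1024.x[grid_1024.nx // 2 + first_min]
        assert r_dark == pytest.approx(1.22 * WL * 2000.0 / 200.0, abs=2 * grid_1024.dx)

    def test_padding_agrees_with_unpadded_for_contained_field(self, gaussian_field):
        plain = bl.propagate(gaussian_field, 1000.0)
        padded = bl.propagate(
            gaussian_field, 1000.0, bl.PropagatorConfig(pad_factor=2)
        )
        err = np.linalg.norm(padded.data - plain.data) / np.linalg.norm(plain.data)
        assert err < 1e-6

    def test_band_limit_leak_warning(self, grid_512, default_beamlet):
        beam = bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="uniform"), WL)
        field = bl.apply_transmission(
            beam, bl.beamlet_transmission(grid_512, default_beamlet, WL)
        )
        cfg = bl.PropagatorConfig(band_limit=True, leak_warn_fraction=1e-9)
        with pytest.warns(UserWarning, match="band limit"):
            bl.propagate(field, 3000.0, cfg)


class TestPropagateStack:
    def test_single_plane_at_source_equals_masked_input(self, grid_512, default_beamlet):
        beam = bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="uniform"), WL)
        t = bl.beamlet_transmission(grid_512, default_beamlet, WL)
        field = bl.apply_transmission(beam, t)
        stack = bl.propagate_stack(field, [0.0])
        np.testing.assert_allclose(
            stack.frames[0], np.abs(t * beam.data) ** 2, rtol=1e-5, atol=1e-10
        )

    def test_free_plane_wave_frames_identical(self, grid_512):
        beam = bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="uniform"), WL)
        stack = bl.propagate_stack(beam, [0.0, 100.0, 200.0])
        np.testing.assert_allclose(stack.frames[1], stack.frames[0], rtol=1e-6)
        np.testing.assert_allclose(stack.frames[2], stack.frames[0], rtol=1e-6)

    def test_characterization_schedule_expressible(self):
        z = bl.config.ZSchedule(500.0, 3500.0, 5.0).positions()
        assert len(z) == 601
        assert z[0] == 500.0 and z[-1] == 3500.0

    def test_empty_schedule_rejected(self, gaussian_field):
        with pytest.raises(ValueError, match="empty"):
            bl.propagate_stack(gaussian_field, [])


class TestAgainstHankelOracle:
    """The FFT propagation path checked against 1D radial quadrature."""

    def test_focal_profile_matches_radial_quadrature(self, grid_1024, default_beamlet):
        beam = bl.make_input_beam(grid_1024, bl.InputBeamSpec(kind="uniform"), WL)
        field = bl.apply_transmission(
            beam, bl.beamlet_transmission(grid_1024, default_beamlet, WL)
        )
        z = 1810.0
        out = bl.propagate(field, z)
        row = grid_1024.ny // 2
        half = grid_1024.nx // 2
        rho = grid_1024.x[half : half + 13]  # central lobe and first side lobe
        sim = np.abs(out.data[row, half : half + 13]) ** 2
        oracle = np.abs(hankel_field(rho, z)) ** 2
        sim = sim / sim[0]
        oracle = oracle / oracle[0]
        rms = np.sqrt(np.mean((sim - oracle) ** 2))
        assert rms < 0.02

    def test_central_lobe_fwhm_near_delta_ring_value(self, grid_1024, default_beamlet):
        # 2·1.127/k_r with k_r = (2π/λ)(R/f) gives 3.50 µm; the finite-thickness
        # annulus measured at its axial peak agrees within 5%
        beam = bl.make_input_beam(grid_1024, bl.InputBeamSpec(kind="uniform"), WL)
        field = bl.apply_transmission(
            beam, bl.beamlet_transmission(grid_1024, default_beamlet, WL)
        )
        out = bl.propagate(field, 1810.0)
        row = grid_1024.ny // 2
        fw = profile_fwhm(grid_1024.x, np.abs(out.data[row]) ** 2)
        k_r = (2 * np.pi / WL) * (100.0 / 2000.0)
        assert fw == pytest.approx(2 * 1.12764 / k_r, rel=0.05)


class TestShiftEquivariance:
    def test_focal_pattern_translates_with_beamlet_center(self, grid_1024):
        base = bl.BeamletSpec(R=100.0, delta=17.0, f=2000.0)
        shifted = bl.BeamletSpec(R=100.0, delta=17.0, f=2000.0, center=(40.0, 0.0))
        beam = bl.make_input_beam(grid_1024, bl.InputBeamSpec(kind="uniform"), WL)
        frames = []
        for spec in (base, shifted):
            f0 = bl.apply_transmission(beam, bl.beamlet_transmission(grid_1024, spec, WL))
            frames.append(np.abs(bl.propagate(f0, 1810.0).data) ** 2)
        shift_cells = int(round(40.0 / grid_1024.dx))
        rolled = np.roll(frames[0], shift_cells, axis=1)
        core = np.s_[:, 200:-200]
        denom = frames[1][core].max()
        assert np.max(np.abs(frames[1][core] - rolled[core])) / denom < 0.02
        i1 = np.unravel_index(np.argmax(frames[1]), frames[1].shape)
        i0 = np.unravel_index(np.argmax(frames[0]), frames[0].shape)
        assert abs((i1[1] - i0[1]) * grid_1024.dx - 40.0) <= grid_1024.dx


class TestTiltShift:
    def test_tilt_displaces_focus_geometrically(self, grid_1024, default_beamlet):
        theta = 0.005
        beam = bl.make_input_beam(grid_1024, bl.InputBeamSpec(kind="uniform"), WL)
        t = bl.beamlet_transmission(grid_1024, default_beamlet, WL)
        tilted = bl.apply_transmission(
            bl.apply_transmission(beam, np.exp(1j * bl.tilt_phase(grid_1024, theta, 0.0, WL))),
            t,
        )
        out = bl.propagate(tilted, 2000.0)
        frame = np.abs(out.data) ** 2
        i = np.unravel_index(np.argmax(frame), frame.shape)
        x_peak = grid_1024.x[i[1]]
        assert x_peak == pytest.approx(2000.0 * np.tan(theta), abs=2 * grid_1024.dx)


class TestDither:
    def test_dithered_stack_is_weighted_average(self, grid_512, default_beamlet):
        beam = bl.make_input_beam(grid_512, bl.InputBeamSpec(kind="uniform"), WL)
        field = bl.apply_transmission(
            beam, bl.beamlet_transmission(grid_512, default_beamlet, WL)
        )
        spec = bl.DitherSpec(tilts=((0.003, 0.0), (-0.003, 0.0)), weights=(1.0, 3.0))
        z = [1800.0, 1900.0]
        avg = bl.dithered_stack(field, z, spec)
        parts = []
        for tx, _ in spec.tilts:
            tilted = bl.apply_transmission(
                field, np.exp(1j * bl.tilt_phase(grid_512, tx, 0.0, WL))
            )
            parts.append(bl.propagate_stack(tilted, z).frames)
        expected = 0.25 * parts[0] + 0.75 * parts[1]
        np.testing.assert_allclose(avg.frames, expected, rtol=1e-5)
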