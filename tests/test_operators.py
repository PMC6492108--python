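"""Encoding operator: sample times, adjointness, oracles, shift behavior."""

import numpy as np
import pytest
from scipy.ndimage import center_of_mass

import epiunwarp as eu
from epiunwarp.fourier import cfft2, cifft2

from conftest import random_field, random_image


class TestSampleTimes:
    def test_linear_ramp_blip_up(self):
        g = eu.GridGeometry(4, 4, echo_spacing_s=1e-3)
        t = eu.build_sample_times(g, eu.Polarity.BLIP_UP)
        assert np.allclose(t.line_times_s, [-2e-3, -1e-3, 0.0, 1e-3])

    def test_blip_down_is_sign_flip(self):
        g = eu.GridGeometry(4, 4, echo_spacing_s=1e-3)
        up = eu.build_sample_times(g, eu.Polarity.BLIP_UP)
        down = eu.build_sample_times(g, eu.Polarity.BLIP_DOWN)
        assert np.allclose(down.times_s, -up.times_s)

    def test_total_readout_duration_matches_bandwidth(self):
        g = eu.GridGeometry.from_bandwidth(96, 96, bw_per_pixel_hz=10.4)
        assert g.n_pe * g.echo_spacing_s == pytest.approx(1.0 / 10.4, rel=1e-12)
        assert g.bw_per_pixel_hz * g.n_pe * g.echo_spacing_s == pytest.approx(1.0, rel=1e-9)

    def test_constant_along_readout(self, small_geometry):
        t = eu.build_sample_times(small_geometry, eu.Polarity.BLIP_UP)
        assert np.all(t.times_s == t.times_s[:, :1])

    def test_invalid_echo_spacing_rejected(self):
        with pytest.raises(eu.InvalidGeometryError):
            eu.GridGeometry(8, 8, echo_spacing_s=0.0)


class TestAdjointIdentity:
    @pytest.mark.parametrize("polarity", list(eu.Polarity))
    def test_inner_product_identity_random_draws(self, polarity, rng):
        """<Ex, y> == <x, E^H y> for random images, data, fields and coils."""
        for _ in range(25):
            n_pe, n_ro = rng.choice([8, 16, 24, 48], size=2)
            g = eu.GridGeometry(int(n_pe), int(n_ro))
            j = int(rng.integers(1, 4))
            coils = eu.CoilMaps(
                maps=rng.normal(size=(j, *g.shape)) + 1j * rng.normal(size=(j, *g.shape))
            )
            b0 = eu.B0Map(
                delta_b0_hz=rng.normal(0, 60, g.shape),
                f0_offset_hz=float(rng.normal(0, 20)),
            )
            mask = g.sample_mask(polarity) if rng.random() < 0.5 else None
            op = eu.EncodingOperator(g, coils, b0, polarity, mask)
            x = random_image(g, rng)
            y = rng.normal(size=(j, *g.shape)) + 1j * rng.normal(size=(j, *g.shape))
            lhs = np.vdot(y, op.forward_array(x))
            rhs = np.vdot(op.adjoint_array(y), x)
            assert abs(lhs - rhs) / (abs(lhs) + 1e-300) < 1e-10

    def test_zero_field_single_coil_is_unitary_dft(self, rng):
        g = eu.GridGeometry(16, 16)
        coils = eu.CoilMaps(maps=np.ones((1, 16, 16), complex))
        b0 = eu.B0Map(delta_b0_hz=np.zeros((16, 16)))
        op = eu.EncodingOperator(g, coils, b0, eu.Polarity.BLIP_UP)
        x = random_image(g, rng)
        assert np.allclose(op.forward_array(x)[0], cfft2(x), atol=1e-12)
        assert np.allclose(op.adjoint_array(op.forward_array(x)), x, atol=1e-12)

    def test_impulse_has_flat_spectrum(self):
        g = eu.GridGeometry(16, 16)
        coils = eu.CoilMaps(maps=np.ones((1, 16, 16), complex))
        b0 = eu.B0Map(delta_b0_hz=np.zeros((16, 16)))
        x = np.zeros((16, 16), complex)
        x[8, 8] = 1.0
        y = eu.EncodingOperator(g, coils, b0, eu.Polarity.BLIP_UP).forward_array(x)
        assert np.allclose(np.abs(y), np.abs(y).flat[0])


class TestDenseOracle:
    @pytest.mark.parametrize("polarity", list(eu.Polarity))
    def test_forward_matches_dense_matrix(self, polarity, rng):
        """FFT fast path equals the explicitly built encoding matrix."""
        g = eu.GridGeometry.from_bandwidth(16, 16, 10.4, partial_fourier=0.75)
        coils = eu.CoilMaps(
            maps=rng.normal(size=(3, 16, 16)) + 1j * rng.normal(size=(3, 16, 16))
        )
        b0 = eu.B0Map(delta_b0_hz=rng.normal(0, 80, (16, 16)), f0_offset_hz=17.0)
        mask = g.sample_mask(polarity)
        times = eu.build_sample_times(g, polarity)
        dense = eu.dense_encoding_matrix(g, coils, b0, times, mask)
        x = random_image(g, rng)
        y_dense = (dense @ x.ravel()).reshape(3, 16, 16)
        op = eu.EncodingOperator(g, coils, b0, polarity, mask)
        y_fast = op.forward_array(x)
        assert np.linalg.norm(y_fast - y_dense) / np.linalg.norm(y_dense) < 1e-9

    def test_adjoint_matches_dense_conjugate_transpose(self, rng):
        g = eu.GridGeometry(12, 12)
        coils = eu.CoilMaps(
            maps=rng.normal(size=(2, 12, 12)) + 1j * rng.normal(size=(2, 12, 12))
        )
        b0 = eu.B0Map(delta_b0_hz=rng.normal(0, 50, (12, 12)))
        times = eu.build_sample_times(g, eu.Polarity.BLIP_DOWN)
        dense = eu.dense_encoding_matrix(g, coils, b0, times)
        y = rng.normal(size=(2, 12, 12)) + 1j * rng.normal(size=(2, 12, 12))
        x_dense = (dense.conj().T @ y.ravel()).reshape(12, 12)
        op = eu.EncodingOperator(g, coils, b0, eu.Polarity.BLIP_DOWN)
        assert np.allclose(op.adjoint_array(y), x_dense, atol=1e-10)


def _gaussian_blob(geometry, sigma_px=6.0):
    yy = np.arange(geometry.n_pe)[:, None] - geometry.n_pe // 2
    xx = np.arange(geometry.n_ro)[None, :] - geometry.n_ro // 2
    return np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2)).astype(complex)


class TestConstantFieldShift:
    @pytest.mark.parametrize("polarity,sign", [(eu.Polarity.BLIP_UP, 1), (eu.Polarity.BLIP_DOWN, -1)])
    def test_translation_magnitude_and_sign(self, polarity, sign):
        """Constant effective field translates by f/bw px, opposite per polarity."""
        g = eu.GridGeometry.from_bandwidth(96, 96, 15.80)
        blob = _gaussian_blob(g)
        coils = eu.CoilMaps(maps=np.ones((1, 96, 96), complex))
        b0 = eu.B0Map(delta_b0_hz=np.zeros((96, 96)), f0_offset_hz=47.15)
        op = eu.EncodingOperator(g, coils, b0, polarity)
        img = np.abs(cifft2(op.forward_array(blob)[0]))
        com_shift = center_of_mass(img)[0] - center_of_mass(np.abs(blob))[0]
        assert com_shift == pytest.approx(sign * 47.15 / 15.80, abs=0.1)

    def test_conjugate_phase_restores_blob_under_smooth_field(self):
        """Conjugate phase undoes a smooth 120 Hz field where gradients are mild."""
        g = eu.GridGeometry.from_bandwidth(32, 32, 10.4)
        blob = _gaussian_blob(g, sigma_px=4.0)
        coils = eu.CoilMaps(maps=np.ones((1, 32, 32), complex))
        yy = np.arange(32)[:, None] / 31.0
        b0 = eu.B0Map(delta_b0_hz=120.0 * np.broadcast_to(np.sin(np.pi * yy / 2), (32, 32)).copy())
        op = eu.EncodingOperator(g, coils, b0, eu.Polarity.BLIP_UP)
        y = op.forward_array(blob)
        # uncorrected image is visibly displaced; conjugate phase restores it
        com_true = center_of_mass(np.abs(blob))[0]
        com_unc = center_of_mass(np.abs(cifft2(y[0])))[0]
        com_cp = center_of_mass(np.abs(op.adjoint_array(y)))[0]
        assert abs(com_unc - com_true) > 1.0
        assert abs(com_cp - com_true) < 1.0


class TestPixelShiftMap:
    def test_headline_shift_arithmetic(self):
        """120 Hz at 15.80 Hz/px is a 7.59-pixel displacement."""
        g = eu.GridGeometry.from_bandwidth(64, 64, 15.80)
        b0 = eu.B0Map(delta_b0_hz=np.full((64, 64), 120.0))
        shift = eu.pixel_shift_map(b0, g)
        assert shift.max() == pytest.approx(120.0 / 15.80, rel=1e-12)
        assert 7.0 <= shift.max() <= 8.0

    def test_zero_field_zero_shift(self, small_geometry):
        b0 = eu.B0Map(delta_b0_hz=np.zeros(small_geometry.shape))
        assert np.all(eu.pixel_shift_map(b0, small_geometry) == 0)

    def test_offset_only_shift_equal_and_opposite(self):
        g = eu.GridGeometry.from_bandwidth(32, 32, 15.80)
        b0 = eu.B0Map(delta_b0_hz=np.zeros((32, 32)), f0_offset_hz=47.15)
        up = eu.pixel_shift_map(b0, g, eu.Polarity.BLIP_UP)
        down = eu.pixel_shift_map(b0, g, eu.Polarity.BLIP_DOWN)
        assert np.allclose(up, 47.15 / 15.80)
        assert np.allclose(up, -down)


class TestValidation:
    def test_shape_mismatch_raises(self, small_geometry, rng):
        coils = eu.CoilMaps(maps=np.ones((1, *small_geometry.shape), complex))
        b0 = eu.B0Map(delta_b0_hz=np.zeros(small_geometry.shape))
        op = eu.EncodingOperator(small_geometry, coils, b0, eu.Polarity.BLIP_UP)
        with pytest.raises(eu.DimensionError):
            op.forward_array(np.zeros((3, 3), complex))
        with pytest.raises(eu.DimensionError):
            op.adjoint_array(np.zeros((2, 3, 3), complex))

    def test_mismatched_b0_rejected(self, small_geometry):
        coils = eu.CoilMaps(maps=np.ones((1, *small_geometry.shape), complex))
        with pytest.raises(eu.DimensionError):
            eu.EncodingOperator(
                small_geometry,
                coils,
                eu.B0Map(delta_b0_hz=np.zeros((3, 3))),
                eu.Polarity.BLIP_UP,
            )
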