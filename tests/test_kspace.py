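"""k-space transforms, artifact operators and reconstruction manipulations."""

import numpy as np
import pytest
from scipy import stats

import mrisim as m
from mrisim import kspace as ksp
from mrisim.phantom import ValidationError


def point_image(n=128):
    img = np.zeros((n, n))
    img[n // 2, n // 2] = 1.0
    return img


class TestTransforms:
    def test_constant_image_concentrates_at_dc(self):
        n, c = 64, 0.7
        k = ksp.forward_kspace(np.full((n, n), c))
        dc = ksp.dc_index((n, n))
        assert abs(k.data[dc]) == pytest.approx(c * n, rel=1e-12)
        off_dc = np.abs(k.data.copy())
        off_dc[dc] = 0
        assert np.max(off_dc) < 1e-10

    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        img = rng.random((96, 96))
        rec = ksp.inverse_recon(ksp.forward_kspace(img))
        assert np.max(np.abs(rec - img)) < 1e-10

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((64, 80))
        k = ksp.forward_kspace(img)
        rel = abs(np.sum(np.abs(k.data) ** 2) - np.sum(img**2)) / np.sum(img**2)
        assert rel < 1e-9

    def test_hermitian_symmetry_for_real_input(self):
        rng = np.random.default_rng(2)
        k = ksp.forward_kspace(rng.random((32, 32))).data
        c0, c1 = ksp.dc_index(k.shape)
        i = np.arange(32)
        mirrored = k[(2 * c0 - i[:, None]) % 32, (2 * c1 - i[None, :]) % 32]
        assert np.max(np.abs(k - np.conj(mirrored))) < 1e-12

    def test_magnitude_invariant_to_global_phase(self):
        rng = np.random.default_rng(3)
        k = ksp.forward_kspace(rng.random((32, 32)))
        rotated = k.copy_with(k.data * np.exp(1j * 1.234))
        assert np.allclose(ksp.inverse_recon(k), ksp.inverse_recon(rotated), atol=1e-12)

    def test_zero_kspace_gives_zero_image(self):
        k = ksp.KSpaceSlice(np.zeros((16, 16), complex))
        assert np.all(ksp.inverse_recon(k) == 0)


class TestArtifactConfig:
    def test_defaults_are_artifact_free(self):
        cfg = m.ArtifactConfig()
        assert cfg.thermal_sigma == 0 and not cfg.spikes
        assert cfg.motion.kind == "none" and not cfg.half_fourier.enabled

    @pytest.mark.parametrize("bad", [
        dict(thermal_sigma=-0.1),
        dict(half_fourier=m.HalfFourierSpec(enabled=True, fraction=0.5)),
        dict(half_fourier=m.HalfFourierSpec(enabled=True, fraction=1.2)),
        dict(motion=m.MotionSpec(kind="periodic", amplitude_mm=1.0, period_lines=1.0)),
    ])
    def test_invalid_configurations_rejected(self, bad):
        with pytest.raises(ValidationError):
            m.ArtifactConfig(**bad)


class TestThermalNoise:
    def test_zero_sigma_is_identity(self):
        k = ksp.forward_kspace(point_image(32))
        assert np.array_equal(ksp.add_thermal_noise(k, 0.0, seed=1).data, k.data)

    def test_negative_sigma_rejected(self):
        k = ksp.forward_kspace(point_image(32))
        with pytest.raises(ValidationError):
            ksp.add_thermal_noise(k, -0.1, seed=1)

    def test_same_seed_same_noise(self):
        k = ksp.forward_kspace(point_image(32))
        a = ksp.add_thermal_noise(k, 0.5, seed=42)
        b = ksp.add_thermal_noise(k, 0.5, seed=42)
        assert np.array_equal(a.data, b.data)
        c = ksp.add_thermal_noise(k, 0.5, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_air_magnitude_is_rayleigh(self):
        """Background magnitude noise follows a Rayleigh law with scale sigma."""
        sigma = 0.3
        k = ksp.KSpaceSlice(np.zeros((128, 128), complex))  # pure air
        noisy = ksp.add_thermal_noise(k, sigma, seed=7)
        mag = ksp.inverse_recon(noisy).ravel()  # 16384 >= 1e4 pixels
        assert stats.kstest(mag, "rayleigh", args=(0, sigma)).pvalue > 0.01


class TestSpike:
    def test_dc_spike_gives_constant_image(self):
        n = 64
        k = ksp.KSpaceSlice(np.zeros((n, n), complex))
        spiked = ksp.add_spike(k, ksp.dc_index((n, n)), 2.0)
        img = ksp.inverse_complex(spiked)
        assert np.allclose(img, img[0, 0], atol=1e-12)

    def test_offset_spike_is_plane_wave_with_matching_cycles(self):
        """A spike 8 lines off DC reconstructs to a stripe with exactly 8 cycles."""
        n, offset = 128, 8
        k = ksp.KSpaceSlice(np.zeros((n, n), complex))
        dc = ksp.dc_index((n, n))
        spiked = ksp.add_spike(k, (dc[0], dc[1] + offset), 1.0)
        row = ksp.inverse_complex(spiked)[0]
        # cycle count from the unwrapped phase slope of the complex exponential
        cycles = (np.unwrap(np.angle(row))[-1] - np.unwrap(np.angle(row))[0]) / (2 * np.pi)
        assert cycles * n / (n - 1) == pytest.approx(offset, abs=1e-9)
        # real part crosses zero 2*offset times (samples landing exactly on a
        # zero are dropped before counting sign changes)
        r = np.real(row)
        s = np.sign(r)
        s = s[s != 0]
        crossings = np.sum(s[:-1] * s[1:] < 0)
        assert crossings == 2 * offset

    def test_add_then_subtract_restores_kspace(self):
        k = ksp.forward_kspace(point_image(32))
        loc = (3, 5)
        restored = ksp.add_spike(ksp.add_spike(k, loc, 1 + 2j), loc, -1 - 2j)
        assert np.max(np.abs(restored.data - k.data)) < 1e-12

    def test_out_of_bounds_location_rejected(self):
        k = ksp.forward_kspace(point_image(32))
        with pytest.raises(ValidationError):
            ksp.add_spike(k, (32, 0), 1.0)


class TestMotion:
    def test_zero_amplitude_is_identity(self, unit_geometry):
        k = ksp.forward_kspace(point_image(128), unit_geometry)
        assert np.array_equal(ksp.add_motion(k, 0.0, 8, unit_geometry).data, k.data)

    def test_period_below_two_rejected(self, unit_geometry):
        k = ksp.forward_kspace(point_image(128), unit_geometry)
        with pytest.raises(ValidationError):
            ksp.add_motion(k, 1.0, 1.5, unit_geometry)

    @pytest.mark.parametrize("period", [4, 8, 16])
    def test_ghosts_at_matrix_over_period_offsets(self, unit_geometry, period):
        """Discrete ghosts appear only at multiples of N_phase/period pixels.

        Peak location uses a per-column maximum over frequency rows: on the
        exact parent row the odd-order ghosts cancel by symmetry, so a
        single-row profile would miss the first-order ghost.
        """
        n = 128
        k = ksp.forward_kspace(point_image(n), unit_geometry)
        rec = ksp.inverse_recon(ksp.add_motion(k, 0.2, period, unit_geometry))
        profile = rec.max(axis=0)  # strongest magnitude in each phase column
        parent = n // 2
        profile[parent] = 0.0
        step = n // period
        # the two largest spurious peaks sit at +/- one ghost step
        top2 = np.argsort(profile)[-2:]
        assert sorted(abs(int(t) - parent) for t in top2) == [step, step]
        # spurious energy lives only on the ghost comb
        energy = np.sum(rec**2, axis=0)
        comb = np.zeros(n, bool)
        comb[parent % step :: step] = True
        assert energy[~comb].max() < 1e-20

    def test_oracle_direct_dft_of_modulated_lines(self, unit_geometry):
        """Ghost image equals a direct DFT evaluation of the line model."""
        n, period, amp = 128, 8, 0.3
        img = point_image(n)
        k = ksp.forward_kspace(img, unit_geometry)
        fast = ksp.inverse_recon(ksp.add_motion(k, amp, period, unit_geometry))
        # oracle: modulate each line explicitly with the shift theorem factors
        kf = (np.arange(n) - n // 2) / unit_geometry.fov_freq
        d = amp * np.sin(2 * np.pi * np.arange(n) / period)
        modulated = k.data * np.exp(-2j * np.pi * np.outer(kf, d))
        oracle = np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(modulated), norm="ortho")))
        assert np.max(np.abs(fast - oracle)) < 1e-12

    def test_ghost_offsets_independent_of_fov(self, unit_geometry):
        import dataclasses

        n = 128
        wide = dataclasses.replace(unit_geometry, fov_freq=512.0, fov_phase=512.0)
        for geom in (unit_geometry, wide):
            k = ksp.forward_kspace(point_image(n), geom)
            rec = ksp.inverse_recon(ksp.add_motion(k, 0.2, 8, geom))
            profile = rec.max(axis=0)
            profile[n // 2] = 0
            top2 = sorted(abs(int(t) - n // 2) for t in np.argsort(profile)[-2:])
            assert top2 == [16, 16]


class TestEtlAttenuation:
    def slice_maps(self, n=128, t2=80.0):
        return {"pd": np.ones((n, n)), "t2": np.full((n, n), t2)}

    def test_etl1_is_uniform_scale_exp_te_over_t2eff(self):
        n = 128
        seq = m.SequenceParams("FSE", te=80, tr=3000, etl=1, echo_spacing=10)
        k = ksp.forward_kspace(np.random.default_rng(0).random((n, n)))
        out = ksp.apply_etl_attenuation(k, self.slice_maps(n), seq)
        scale = np.abs(out.data) / np.maximum(np.abs(k.data), 1e-300)
        assert scale.max() / scale.min() == pytest.approx(1.0, abs=1e-12)
        assert scale[0, 0] == pytest.approx(np.exp(-80 / 80.0), rel=1e-9)

    def test_etl8_broadens_point_spread_function(self):
        """PSFs computed from the line-weight vectors: ETL 8 is wider than ETL 1."""
        n = 128
        maps = self.slice_maps(n, t2=40.0)
        k = ksp.forward_kspace(point_image(n))
        psfs = {}
        for etl in (1, 8):
            seq = m.SequenceParams("FSE", te=40, tr=3000, etl=etl, echo_spacing=15)
            weights = np.abs(ksp.apply_etl_attenuation(k, maps, seq).data[0]) / np.abs(k.data[0])
            # oracle PSF: inverse transform of the zero-padded weight vector
            padded = np.zeros(8 * n)
            padded[(8 * n - n) // 2 : (8 * n + n) // 2] = weights
            psf = np.abs(np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(padded))))
            psfs[etl] = np.sum(psf >= psf.max() / 2)
        assert psfs[8] >= psfs[1]
        assert psfs[8] > psfs[1]  # strictly broader at this T2/echo spacing

    def test_infinite_t2_is_identity_up_to_global_te_scale(self):
        n = 64
        seq = m.SequenceParams("FSE", te=60, tr=3000, etl=4, echo_spacing=12)
        k = ksp.forward_kspace(np.random.default_rng(1).random((n, n)))
        out = ksp.apply_etl_attenuation(k, self.slice_maps(n, t2=1e12), seq)
        assert np.max(np.abs(out.data - k.data)) < 1e-9 * np.max(np.abs(k.data))

    def test_non_fse_family_rejected(self):
        k = ksp.forward_kspace(point_image(32))
        with pytest.raises(ValidationError):
            ksp.apply_etl_attenuation(k, self.slice_maps(32), m.SequenceParams("SE", te=20, tr=500))


class TestHalfFourier:
    def test_fraction_one_equals_full_reconstruction(self):
        k = ksp.forward_kspace(np.random.default_rng(2).random((64, 64)))
        assert np.array_equal(ksp.half_fourier_recon(k, 1.0), ksp.inverse_recon(k))

    def test_exact_for_zero_phase_images(self):
        img = np.abs(np.random.default_rng(3).random((128, 128)))
        k = ksp.forward_kspace(img)
        rec = ksp.half_fourier_recon(k, 0.55)
        assert np.max(np.abs(rec - img)) < 1e-9

    def test_phase_corrupted_image_reconstructs_worse(self):
        img = np.abs(np.random.default_rng(4).random((128, 128))) + 0.1
        x = np.arange(128) / 128
        phased = img * np.exp(1j * 2 * np.pi * 3 * x)[None, :]
        k_plain = ksp.forward_kspace(img)
        k_phased = ksp.KSpaceSlice(
            np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(phased), norm="ortho"))
        )
        err_plain = np.max(np.abs(ksp.half_fourier_recon(k_plain, 0.55) - img))
        err_phased = np.max(np.abs(ksp.half_fourier_recon(k_phased, 0.55) - np.abs(phased)))
        assert err_phased > err_plain

    def test_fraction_at_or_below_half_rejected(self):
        k = ksp.forward_kspace(point_image(32))
        for bad in (0.5, 0.2):
            with pytest.raises(ValidationError):
                ksp.half_fourier_recon(k, bad)


class TestWraparound:
    def oversampled_geometry(self, n=64, osf=2.0):
        return m.PlanGeometry(
            freq_axis=np.array([1.0, 0, 0]), phase_axis=np.array([0, 1.0, 0]),
            slice_axis=np.array([0, 0, 1.0]), fov_freq=256.0, fov_phase=256.0,
            matrix_freq=n, matrix_phase=n, slice_thickness=5.0, slice_separation=5.0,
            n_slices=1, phase_oversampling=osf,
        )

    def test_object_inside_fov_folds_to_itself(self):
        geom = self.oversampled_geometry()
        img = np.zeros((64, 128))
        img[:, 64 - 20 : 64 + 20] = 1.0  # well inside the nominal 64-pixel FOV
        folded = ksp.apply_wraparound(img, geom, wraparound_on=True)
        crop = ksp.apply_wraparound(img, geom, wraparound_on=False)
        assert np.array_equal(folded, crop)

    def test_point_beyond_half_fov_wraps_to_other_side(self):
        geom = self.oversampled_geometry()
        img = np.zeros((64, 128))
        delta = 5
        img[10, 64 + 32 + delta] = 1.0  # phase coordinate FOV/2 + delta pixels
        folded = ksp.apply_wraparound(img, geom, wraparound_on=True)
        assert folded[10, delta] == 1.0  # reappears at -FOV/2 + delta
        assert folded.sum() == 1.0

    def test_no_phase_wrap_crops_out_the_replica(self):
        geom = self.oversampled_geometry()
        img = np.zeros((64, 128))
        img[10, 64 + 32 + 5] = 1.0
        cropped = ksp.apply_wraparound(img, geom, wraparound_on=False)
        assert np.sum(np.abs(cropped) ** 2) < 1e-9

    def test_edge_energy_warns_of_partial_fold(self):
        geom = self.oversampled_geometry()
        img = np.ones((64, 128))
        with pytest.warns(UserWarning, match="partial"):
            ksp.apply_wraparound(img, geom, wraparound_on=True)
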