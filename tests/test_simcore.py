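"""Three-phase SIM core: band separation, frequency shifting, recombination."""

import numpy as np
import pytest
from numpy.fft import fft2, fftfreq, fftshift, ifft2

from msim import (
    BarElement,
    ConditioningError,
    ParameterError,
    RangeError,
    Raster2D,
    ReconFilterConfig,
    SampleImage,
    element_contrast,
    fwhm,
    make_otf,
    make_usaf_target,
    recombine,
    reconstruct_1d_sim,
    separate_bands,
    shift_band,
    widefield_image,
)
from msim.simcore import FrequencyBands, mixing_matrix

PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def synth_mixtures(sample, kbin, phases, m, otf):
    """Brute-force closed-form mixtures for an integer-bin X carrier."""
    S = fft2(sample)
    frames, terms = [], []
    center = S * otf
    minus = np.roll(S, -kbin, axis=1) * otf  # S(k + k0)
    plus = np.roll(S, kbin, axis=1) * otf  # S(k - k0)
    for phi in phases:
        spec = center + 0.5 * m * np.exp(-1j * phi) * minus + 0.5 * m * np.exp(1j * phi) * plus
        frames.append(np.real(ifft2(spec)))
    return frames, (center, minus, plus)


class TestSeparateBands:
    def test_recovers_closed_form_bands(self):
        """Mixtures built from the closed form unmix to the exact three terms."""
        rng = np.random.default_rng(1)
        n, kbin, m = 8, 2, 0.9
        sample = rng.random((n, n))
        opt = make_otf((n, n), 0.5)
        frames, (center, minus, plus) = synth_mixtures(sample, kbin, PHASES, m, opt.otf_em)
        bands = separate_bands(frames, PHASES, m, (kbin / n, 0.0))
        scale = np.abs(center).max()
        assert np.abs(bands.center - center).max() < 1e-9 * scale
        assert np.abs(bands.minus_band - minus).max() < 1e-9 * scale
        assert np.abs(bands.plus_band - plus).max() < 1e-9 * scale

    def test_matches_per_pixel_linear_solve(self):
        """Independent oracle: an explicit per-frequency 3x3 solve."""
        rng = np.random.default_rng(2)
        n, kbin, m = 16, 3, 0.6
        sample = rng.random((n, n))
        opt = make_otf((n, n), 0.4)
        frames, _ = synth_mixtures(sample, kbin, PHASES, m, opt.otf_em)
        bands = separate_bands(frames, PHASES, m, (kbin / n, 0.0))
        M = mixing_matrix(PHASES, m)
        specs = np.stack([fft2(f) for f in frames])
        for r in range(n):
            for c in range(n):
                u = np.linalg.solve(M, specs[:, r, c])
                assert abs(bands.center[r, c] - u[0]) < 1e-9 * (1 + abs(u[0]))
                assert abs(bands.minus_band[r, c] - u[1]) < 1e-9 * (1 + abs(u[1]))
                assert abs(bands.plus_band[r, c] - u[2]) < 1e-9 * (1 + abs(u[2]))

    def test_unmodulated_frames_put_everything_in_center(self, blob_sample, comm_optics):
        wf = widefield_image(blob_sample, comm_optics).data
        bands = separate_bands([wf, wf, wf], PHASES, 0.8, (0.1, 0.0))
        assert np.abs(bands.center - fft2(wf)).max() < 1e-9 * np.abs(fft2(wf)).max()
        assert np.abs(bands.plus_band).max() < 1e-9 * np.abs(fft2(wf)).max()
        assert np.abs(bands.minus_band).max() < 1e-9 * np.abs(fft2(wf)).max()

    def test_repeated_phases_raise_conditioning_error(self):
        f = [np.ones((8, 8))] * 3
        with pytest.raises(ConditioningError) as exc:
            separate_bands(f, (0.0, 0.0, 2 * np.pi / 3), 0.9, (0.1, 0.0))
        assert exc.value.condition_number > 1e8

    def test_remix_roundtrip(self):
        """Mixing the separated bands with the original matrix returns the inputs."""
        rng = np.random.default_rng(3)
        frames = [rng.random((12, 12)) for _ in range(3)]
        phases = (0.3, 1.9, 4.1)
        m = 0.7
        bands = separate_bands(frames, phases, m, (0.2, 0.0))
        M = mixing_matrix(phases, m)
        stacked = np.stack([bands.center, bands.minus_band, bands.plus_band])
        for n in range(3):
            remixed = sum(M[n, j] * stacked[j] for j in range(3))
            orig = fft2(frames[n])
            assert np.abs(remixed - orig).max() < 1e-9 * np.abs(orig).max()


class TestShiftBand:
    def test_zero_shift_is_identity_embedding(self):
        rng = np.random.default_rng(4)
        spec = fft2(rng.random((8, 8)))
        out = shift_band(spec, (0.0, 0.0), zero_pad_factor=2)
        assert out.shape == (16, 16)
        inner = fftshift(out)[4:12, 4:12]
        assert np.allclose(inner, fftshift(spec))
        outer = fftshift(out).copy()
        outer[4:12, 4:12] = 0
        assert np.abs(outer).max() == 0

    def test_integer_bin_delta_translates(self):
        n, zpf = 16, 2
        spec = np.zeros((n, n), complex)
        spec[0, 3] = 1.0  # delta at kx = 3/16
        out = shift_band(spec, (2 / n, 0.0), zero_pad_factor=zpf)
        # the enlarged grid keeps the original bin spacing 1/16, so the
        # shifted frequency (3+2)/16 sits at index 5
        mags = np.abs(out)
        assert mags[0, 5] == pytest.approx(1.0, abs=1e-10)
        mags[0, 5] = 0
        assert mags.max() < 1e-10

    def test_half_bin_shift_of_gaussian_matches_closed_form(self):
        # Gaussian spectrum with a linear phase placing its field at the
        # window center, so the closed form applies without wrap effects
        n, zpf, sigma = 32, 2, 0.08
        x0 = n / 2
        k = fftfreq(n)
        kx, ky = np.meshgrid(k, k)

        def gauss(kx_, ky_):
            return (np.exp(-(kx_**2 + ky_**2) / (2 * sigma**2))
                    * np.exp(-2j * np.pi * (kx_ + ky_) * x0))

        spec = gauss(kx, ky)
        s = 0.5 / n  # half an original FFT bin
        out = shift_band(spec, (s, 0.0), zero_pad_factor=zpf)
        kf = fftfreq(zpf * n, d=1.0 / zpf)
        kxf, kyf = np.meshgrid(kf, kf)
        expected = gauss(kxf - s, kyf)
        assert np.abs(out - expected).max() < 1e-8

    def test_shift_beyond_enlarged_nyquist_rejected(self):
        with pytest.raises(RangeError):
            shift_band(np.zeros((8, 8), complex), (1.2, 0.0), zero_pad_factor=2)


class TestRecombine:
    def test_center_band_wiener_identity_in_clear_passband(self, blob_sample, comm_optics):
        """With only the center band and w -> 0, the sample spectrum is recovered
        wherever the shifted OTFs do not overlap it."""
        S = fft2(blob_sample.raster.data)
        carrier = (0.1, 0.0)
        bands = FrequencyBands(center=S * comm_optics.otf_em,
                               minus_band=np.zeros_like(S), plus_band=np.zeros_like(S),
                               carrier=carrier, phases=PHASES, modulation=0.5)
        cfg = ReconFilterConfig(wiener_w=1e-12, apodization="none", zero_pad_factor=2)
        out = recombine(bands, comm_optics, cfg)
        F = fft2(out.data) / 4  # zpf^2 scaling of the enlarged grid
        n = blob_sample.raster.shape[0]
        kf = fftfreq(2 * n, d=0.5)
        kxf, kyf = np.meshgrid(kf, kf)
        Hc = comm_optics.otf_at(kxf, kyf)
        Hp = comm_optics.otf_at(kxf + carrier[0], kyf)
        Hm = comm_optics.otf_at(kxf - carrier[0], kyf)
        clear = (Hc > 0.05) & (Hp == 0) & (Hm == 0)
        # compare against the sample spectrum at matching frequencies
        inner = fftshift(F)[n // 2 : n // 2 + n, n // 2 : n // 2 + n]
        mask = fftshift(clear)[n // 2 : n // 2 + n, n // 2 : n // 2 + n]
        ref = fftshift(S)
        err = np.abs(inner - ref)[mask]
        assert err.max() < 1e-6 * np.abs(S).max()

    def test_output_support_limited_to_extended_cutoff(self, comm_stack, comm_optics):
        from msim import params_from_pattern_set, reconstruct_group

        params = params_from_pattern_set(comm_stack.pattern_set)
        rec = reconstruct_group([comm_stack.frames[i] for i in (0, 3, 6)], "y",
                                params, comm_optics, group_index=0)
        F = np.abs(fft2(rec.image.data))
        n = rec.image.shape[0]
        kf = fftfreq(n, d=rec.image.pixel_size)
        kxf, kyf = np.meshgrid(kf, kf)
        k_ext = comm_optics.cutoff + params.k_y
        outside = (np.hypot(kxf, kyf) > k_ext + 1e-9) & (np.hypot(kxf, kyf - params.k_y) > comm_optics.cutoff) & (np.hypot(kxf, kyf + params.k_y) > comm_optics.cutoff)
        assert F[outside].max() < 1e-9 * F.max()


class TestReconstruct1dSim:
    def _stripe_stack(self, sample, n, k, optics, axis="x"):
        from msim import image_under_pattern, make_stripe

        frames = []
        for phi in PHASES:
            p = make_stripe((n, n), k=k, phi=phi, axis=axis, m=0.8)
            frames.append(image_under_pattern(sample, p, optics).data)
        return frames

    def test_constant_sample_gives_constant_output(self):
        n = 48
        k = 6 / n  # bin-aligned carrier: the periodic identities are exact
        opt = make_otf((n, n), 0.2)
        sample = SampleImage(Raster2D(np.full((n, n), 2.0)))
        frames = self._stripe_stack(sample, n, k, opt)
        out = reconstruct_1d_sim(frames, PHASES, (k, 0.0), opt, m=0.8)
        assert out.data.std() < 1e-9 * abs(out.data.mean())

    def test_linearity_in_the_sample(self):
        n = 32
        opt = make_otf((n, n), 0.25)
        rng = np.random.default_rng(5)
        sample = SampleImage(Raster2D(rng.random((n, n))))
        scaled = SampleImage(Raster2D(3.0 * sample.raster.data))
        f1 = self._stripe_stack(sample, n, 0.2, opt)
        f2 = self._stripe_stack(scaled, n, 0.2, opt)
        r1 = reconstruct_1d_sim(f1, PHASES, (0.2, 0.0), opt, m=0.8)
        r2 = reconstruct_1d_sim(f2, PHASES, (0.2, 0.0), opt, m=0.8)
        assert np.allclose(r2.data, 3.0 * r1.data, atol=1e-9 * np.abs(r1.data).max())

    def test_resolution_doubles_along_carrier_axis_only(self):
        """Bars beyond the wide-field cutoff resolve only perpendicular to the
        carrier direction."""
        n, cutoff, k = 96, 0.2, 0.18
        period = 4  # 0.25 cycles/px: beyond cutoff, inside cutoff + carrier
        opt = make_otf((n, n), cutoff)
        cfg = ReconFilterConfig(wiener_w=1e-3, apodization="none")
        el = BarElement(period_px=period, orientation="vertical", position=(30, 30))
        target = make_usaf_target((n, n), [el])
        frames_x = self._stripe_stack(target, n, k, opt, axis="x")
        frames_y = self._stripe_stack(target, n, k, opt, axis="y")
        rx = reconstruct_1d_sim(frames_x, PHASES, (k, 0.0), opt, cfg, m=0.8)
        ry = reconstruct_1d_sim(frames_y, PHASES, (0.0, k), opt, cfg, m=0.8)
        c_perp = element_contrast(rx, el)  # X carrier vs vertical bars
        c_par = element_contrast(ry, el)  # Y carrier cannot see them
        wf_c = element_contrast(widefield_image(target, opt), el)
        assert wf_c < 0.05
        assert c_perp >= 0.1
        assert c_par < 0.05

    def test_point_source_width_shrinks_per_support_bound(self):
        """FWHM along the stripe axis lands in the band predicted by the
        extended support cutoff + |k0| = 1.9 x cutoff (tapered spectrum)."""
        n, cutoff = 128, 0.1
        k = 0.9 * cutoff
        opt = make_otf((n, n), cutoff)
        s = np.zeros((n, n))
        s[n // 2, n // 2] = 1.0
        sample = SampleImage(Raster2D(s))
        frames = self._stripe_stack(sample, n, k, opt, axis="x")
        out = reconstruct_1d_sim(frames, PHASES, (k, 0.0), opt,
                                 ReconFilterConfig(), m=0.8)
        wf = widefield_image(sample, opt)
        ratio = fwhm(out, (n // 2, n // 2), "x") / fwhm(wf, (n // 2, n // 2), "x")
        assert 0.50 <= ratio <= 0.65
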