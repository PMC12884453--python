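"""Single-particle Raman preprocessing and hybridization classification."""

import numpy as np
import pytest
from scipy.integrate import quad

from lcnpkit import raman
from lcnpkit.raman import (
    PreprocessConfig,
    RamanSpectrum,
    SpectrumBatch,
    nearest_rank_percentile,
)
from lcnpkit.synthetic import SyntheticRamanSpec, generate_raman_population


def _grid(n=1500, lo=300.0, hi=1900.0):
    return np.linspace(lo, hi, n)


class TestSpikeRemoval:
    def test_clean_spectrum_unchanged(self):
        wn = _grid()
        rng = np.random.default_rng(0)
        y = 100 + 5 * np.sin(wn / 50) + rng.normal(0, 1, len(wn))
        out = raman.remove_cosmic_spikes(RamanSpectrum(wn, y))
        assert np.allclose(out.intensity, y)

    @pytest.mark.parametrize("spike_channels, amplitude_sd", [([700], 50), ([700, 701], 120)])
    def test_injected_spikes_removed(self, spike_channels, amplitude_sd):
        wn = _grid()
        rng = np.random.default_rng(1)
        noise_sd = 2.0
        y = 50 + 0.01 * wn + rng.normal(0, noise_sd, len(wn))
        spiked = y.copy()
        for ch in spike_channels:
            spiked[ch] += amplitude_sd * noise_sd
        out = raman.remove_cosmic_spikes(RamanSpectrum(wn, spiked))
        off = np.ones(len(wn), bool)
        for ch in spike_channels:
            off[ch - 2 : ch + 3] = False
        # spike gone, the rest essentially untouched
        assert np.all(np.abs(out.intensity[spike_channels] - y[spike_channels]) < 10 * noise_sd)
        rms_off = np.sqrt(np.mean((out.intensity[off] - spiked[off]) ** 2))
        assert rms_off < noise_sd / 10

    def test_double_application_guarded(self):
        wn = _grid()
        s = raman.remove_cosmic_spikes(RamanSpectrum(wn, np.ones(len(wn))))
        with pytest.raises(ValueError, match="already applied"):
            raman.remove_cosmic_spikes(s)


class TestBackgroundSubtraction:
    def test_arithmetic(self):
        wn = _grid(200)
        blank = RamanSpectrum(wn, np.full(200, 10.0))
        s = RamanSpectrum(wn, np.full(200, 20.0))
        assert np.allclose(
            raman.subtract_background(s, blank, 0.0).intensity, 20.0
        )
        assert np.allclose(
            raman.subtract_background(blank, blank, 1.0).intensity, 0.0
        )
        out = raman.subtract_background(s, blank, 0.95)
        assert np.allclose(out.intensity, 20.0 - 0.95 * 10.0)

    def test_grid_mismatch_rejected(self):
        s = RamanSpectrum(_grid(200), np.ones(200))
        blank = RamanSpectrum(_grid(201), np.ones(201))
        with pytest.raises(ValueError, match="grid"):
            raman.subtract_background(s, blank)


class TestPreprocess:
    def test_baseline_only_input_flattened(self):
        """A pure smooth polynomial baseline with no bands is removed to
        well under 1% of its range."""
        wn = _grid()
        x = np.linspace(-1, 1, len(wn))
        y = 200 + 80 * x - 50 * x**2 + 30 * x**3
        s = RamanSpectrum(wn, y)
        cfg = PreprocessConfig()
        out = raman.baseline_correct(
            raman.truncate_roi(raman.remove_cosmic_spikes(s), cfg.roi),
            cfg.baseline_smoothness, cfg.baseline_diff_order,
        )
        assert np.max(np.abs(out.intensity)) < 0.01 * np.ptp(y)

    def test_normalization_contract(self, small_population):
        """Every preprocessed spectrum integrates to 1 over the ROI."""
        _, processed = small_population
        for s in processed:
            area = np.trapezoid(s.intensity, s.wavenumber)
            assert area == pytest.approx(1.0, abs=1e-9)
            assert {"spike-cleaned", "background-subtracted", "truncated",
                    "baselined", "smoothed", "normalized"} <= s.flags

    def test_band_apex_preserved(self):
        """The chain shifts a band apex by less than one channel."""
        wn = _grid()
        x = np.linspace(-1, 1, len(wn))
        center = 1003.0
        y = 100 + 40 * x + 80 * np.exp(-0.5 * ((wn - center) / 5.0) ** 2)
        blank = RamanSpectrum(wn, np.zeros_like(wn))
        out = raman.preprocess(RamanSpectrum(wn, y), blank)
        apex = out.wavenumber[np.argmax(out.intensity)]
        channel = wn[1] - wn[0]
        assert abs(apex - center) < channel

    def test_roi_outside_grid_rejected(self):
        wn = np.linspace(500, 1500, 800)
        with pytest.raises(ValueError, match="ROI"):
            raman.truncate_roi(RamanSpectrum(wn, np.ones(800)), (416.0, 1800.0))


class TestBandIntegration:
    def test_zero_and_constant(self):
        wn = _grid()
        assert raman.integrate_protein_peak(RamanSpectrum(wn, np.zeros(len(wn)))) == 0.0
        c = 3.7
        area = raman.integrate_protein_peak(RamanSpectrum(wn, np.full(len(wn), c)))
        assert area == pytest.approx(c * 7.0, rel=1e-9)

    def test_lorentzian_mass_quadrature_oracle(self):
        """Integral of a narrow unit-area Lorentzian over 1000-1007 cm^-1
        matches adaptive quadrature."""
        gamma, c0 = 0.8, 1003.5
        lorentz = lambda x: (gamma / np.pi) / ((x - c0) ** 2 + gamma**2)
        wn = np.linspace(900, 1100, 8000)
        area = raman.integrate_band(RamanSpectrum(wn, lorentz(wn)), (1000.0, 1007.0))
        expected, _ = quad(lorentz, 1000.0, 1007.0)
        assert area == pytest.approx(expected, rel=1e-4)

    def test_band_outside_range_rejected(self):
        wn = np.linspace(1100, 1800, 500)
        with pytest.raises(ValueError, match="band"):
            raman.integrate_protein_peak(RamanSpectrum(wn, np.ones(500)))


class TestSubpopulationRemoval:
    def test_planted_subpopulation_removed_exactly(self, small_population):
        batch, processed = small_population
        processed = SpectrumBatch(processed.spectra, batch.labels)
        kept, removed = raman.remove_subpopulation(processed)
        assert set(removed.labels) == {"subpop"}
        assert "subpop" not in set(kept.labels)
        assert len(kept) + len(removed) == len(batch)

    def test_threshold_extremes(self, small_population):
        _, processed = small_population
        cfg_hi = PreprocessConfig(subpop_threshold=1e9)
        kept, removed = raman.remove_subpopulation(processed, cfg_hi)
        assert len(removed) == 0
        cfg_lo = PreprocessConfig(subpop_threshold=0.0)
        kept, removed = raman.remove_subpopulation(processed, cfg_lo)
        assert len(kept) == 0


class TestClassification:
    def test_reference_against_itself_flags_exactly_5pct(self):
        rng = np.random.default_rng(0)
        areas = rng.gamma(2.0, 1.0, 200)  # continuous, no ties
        res = raman.classify_hybrids(areas, areas, percentile=95, seed=0)
        assert res.hybrid_fraction == pytest.approx(0.05)

    def test_zero_sample_areas(self):
        res = raman.classify_hybrids(np.zeros(50), np.linspace(0.1, 1, 30), seed=0)
        assert res.hybrid_fraction == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            raman.classify_hybrids([1.0], [])

    def test_monotone_rescaling_invariance(self, pure_reference_areas):
        rng = np.random.default_rng(5)
        sample = rng.gamma(3.0, 2.0, 150)
        ref = pure_reference_areas
        r1 = raman.classify_hybrids(sample, ref, seed=0)
        # strictly monotone map applied identically to both
        f = lambda x: np.log1p(3.0 * np.asarray(x))
        r2 = raman.classify_hybrids(f(sample), f(ref), seed=0)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.hybrid_fraction == r2.hybrid_fraction

    def test_nearest_rank_convention(self):
        v = np.arange(1, 101)  # 1..100
        assert nearest_rank_percentile(v, 95) == 95
        assert nearest_rank_percentile(v, 100) == 100
        assert nearest_rank_percentile([7.0], 95) == 7.0

    def test_planted_fraction_recovered(self, pure_reference_areas):
        """Planted hybrid fraction 0.63 at n = 190 recovered within the
        95% binomial CI, mirroring the real experiment's scale."""
        spec = SyntheticRamanSpec(n_particles=190, hybrid_fraction=0.63, seed=11)
        batch, blank = generate_raman_population(spec)
        processed = raman.preprocess_batch(batch, blank)
        areas = [raman.integrate_protein_peak(s) for s in processed]
        res = raman.classify_hybrids(areas, pure_reference_areas, seed=0)
        half_width = 1.96 * np.sqrt(0.63 * 0.37 / 190)
        assert abs(res.hybrid_fraction - 0.63) < half_width
        lo, hi = res.ci95
        assert lo <= res.hybrid_fraction <= hi

    def test_bootstrap_seeded(self):
        rng = np.random.default_rng(2)
        areas, ref = rng.gamma(2, 1, 100), rng.gamma(2, 1, 100)
        a = raman.classify_hybrids(areas, ref, seed=7)
        b = raman.classify_hybrids(areas, ref, seed=7)
        assert a.ci95 == b.ci95


class TestBatchMean:
    def test_identical_spectra_zero_sd(self):
        wn = _grid(300)
        s = RamanSpectrum(wn, np.sin(wn / 100))
        mean, sd = raman.batch_mean_spectrum(SpectrumBatch([s, s, s]))
        assert np.allclose(sd.intensity, 0.0)
        assert np.allclose(mean.intensity, s.intensity)

    def test_two_spectra_mean(self):
        wn = _grid(300)
        a = RamanSpectrum(wn, np.ones(300))
        b = RamanSpectrum(wn, 3 * np.ones(300))
        mean, _ = raman.batch_mean_spectrum(SpectrumBatch([a, b]))
        assert np.allclose(mean.intensity, 2.0)

    def test_hybrid_mean_shows_protein_band(self, small_population):
        batch, processed = small_population
        hyb = SpectrumBatch(
            [s for s, l in zip(processed.spectra, batch.labels) if l == "hybrid"]
        )
        pure = SpectrumBatch(
            [s for s, l in zip(processed.spectra, batch.labels) if l == "pure"]
        )
        hyb_area = raman.integrate_protein_peak(raman.batch_mean_spectrum(hyb)[0])
        pure_area = raman.integrate_protein_peak(raman.batch_mean_spectrum(pure)[0])
        assert hyb_area > 3 * pure_area

    def test_mixed_grids_rejected(self):
        a = RamanSpectrum(_grid(300), np.ones(300))
        b = RamanSpectrum(_grid(301), np.ones(301))
        with pytest.raises(ValueError, match="grid"):
            raman.batch_mean_spectrum(SpectrumBatch([a, b]))
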