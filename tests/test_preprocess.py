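import numpy as np
import pytest

from seedmsi.msio import MSIDataset, Spectrum
from seedmsi.preprocess import (
    PeakEntry,
    PeakTable,
    attach_images,
    mean_spectrum,
    pick_peaks,
    rms_normalize,
    select_top_n,
)


def continuous_dataset(matrix, axis=None, polarity="negative"):
    matrix = np.asarray(matrix, dtype=np.float32)
    axis = axis if axis is not None else np.linspace(100, 200, matrix.shape[1])
    coords = np.array([(i + 1, 1) for i in range(matrix.shape[0])])
    return MSIDataset(
        coords=coords,
        polarity=polarity,
        mode="continuous",
        mz_axis=np.asarray(axis, dtype=np.float64),
        intensities=matrix,
    )


class TestRmsNormalize:
    def test_three_four_example(self):
        ds = continuous_dataset([[3.0, 4.0]])
        rms = float(np.sqrt((9 + 16) / 2))
        assert round(rms, 4) == 3.5355
        out = rms_normalize(ds)
        np.testing.assert_allclose(out.intensities[0], [0.8485, 1.1314], atol=5e-5)

    def test_all_zero_flagged_and_unchanged(self):
        ds = continuous_dataset([[0.0, 0.0], [1.0, 1.0]])
        out = rms_normalize(ds)
        np.testing.assert_array_equal(out.intensities[0], [0.0, 0.0])
        assert out.meta["rms_zero_pixels"] == [0]

    def test_unit_rms_after_normalization(self, rng):
        ds = continuous_dataset(rng.uniform(0, 9, size=(20, 50)))
        out = rms_normalize(ds)
        rms = np.sqrt((out.intensities.astype(np.float64) ** 2).mean(axis=1))
        np.testing.assert_allclose(rms, 1.0, atol=1e-6)  # float32 storage

    def test_idempotent(self, rng):
        ds = continuous_dataset(rng.uniform(0, 9, size=(10, 30)))
        once = rms_normalize(ds)
        twice = rms_normalize(once)
        np.testing.assert_allclose(
            twice.intensities, once.intensities, rtol=1e-6, atol=0
        )

    def test_processed_mode(self, rng):
        mz = np.sort(rng.uniform(100, 900, size=12))
        spectra = [Spectrum(mz, rng.uniform(0, 5, size=12)) for _ in range(3)]
        ds = MSIDataset(
            coords=np.array([[1, 1], [2, 1], [3, 1]]),
            polarity="positive",
            mode="processed",
            spectra=spectra,
        )
        out = rms_normalize(ds)
        for spec in out.spectra:
            assert float(np.sqrt((spec.intensity.astype(np.float64) ** 2).mean())) == pytest.approx(
                1.0, abs=1e-6
            )


class TestMeanSpectrum:
    def test_two_identical_pixels(self):
        ds = continuous_dataset([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        mean = mean_spectrum(ds)
        np.testing.assert_allclose(mean.intensity, [1.0, 2.0, 3.0])

    def test_single_pixel_identity(self):
        ds = continuous_dataset([[5.0, 0.0, 1.0]])
        mean = mean_spectrum(ds)
        np.testing.assert_allclose(mean.intensity, [5.0, 0.0, 1.0])

    def test_processed_binning_conserves_signal(self, rng):
        mz = np.sort(rng.uniform(110, 190, size=8))
        spectra = [Spectrum(mz, np.full(8, 2.0)) for _ in range(4)]
        ds = MSIDataset(
            coords=np.array([(i + 1, 1) for i in range(4)]),
            polarity="negative",
            mode="processed",
            spectra=spectra,
            mz_range=(100.0, 200.0),
        )
        mean = mean_spectrum(ds, axis_bin_ppm=5.0)
        assert float(mean.intensity.sum()) == pytest.approx(16.0, rel=1e-6)

    def test_phantom_planted_centroids_are_local_maxima(self, phantom_noiseless):
        _, dataset, manifest = phantom_noiseless
        mean = mean_spectrum(dataset)
        for ion in manifest.planted_ions()[:20]:
            idx = int(np.argmin(np.abs(mean.mz - ion.observed_mz)))
            lo, hi = max(idx - 1, 0), min(idx + 2, mean.mz.size)
            assert mean.intensity[idx] == max(mean.intensity[lo:hi])


def gaussian_spectrum(center=500.0, sigma_ppm=14.0, height=100.0, floor=0.5, seconds=None):
    """A clean Gaussian peak on a wide flat noise floor."""
    axis = center * (1 + np.linspace(-400, 400, 801) * 1e-6)
    offsets_ppm = (axis - center) / center * 1e6
    intensity = floor + height * np.exp(-0.5 * (offsets_ppm / sigma_ppm) ** 2)
    return Spectrum(axis, intensity)


class TestPickPeaks:
    def test_single_gaussian(self):
        spec = gaussian_spectrum()
        peaks = pick_peaks(spec, snr_min=3.0, window_ppm=10.0)
        assert len(peaks) == 1
        assert peaks.entries[0].centroid_mz == pytest.approx(500.0, abs=500 * 2e-6)
        assert peaks.entries[0].shape_r2 > 0.9

    def test_two_gaussians_50ppm_apart(self):
        center = 500.0
        axis = center * (1 + np.linspace(-400, 400, 1601) * 1e-6)
        ppm = (axis - center) / center * 1e6
        intensity = (
            0.1
            + 100 * np.exp(-0.5 * (ppm / 5) ** 2)
            + 80 * np.exp(-0.5 * ((ppm - 50) / 5) ** 2)
        )
        peaks = pick_peaks(Spectrum(axis, intensity), snr_min=3.0, window_ppm=10.0)
        assert len(peaks) == 2

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pick_peaks(Spectrum(np.array([]), np.array([])))

    def test_phantom_centroids_match_planted(self, annotated_default, phantom_default):
        config, _, manifest = phantom_default
        peaks = annotated_default["peaks"]
        centroids = np.array([e.centroid_mz for e in peaks.entries])
        for ion in manifest.planted_ions():
            ppm = np.min(np.abs(centroids - ion.theoretical_mz)) / ion.theoretical_mz * 1e6
            assert ppm <= 2 * config.sigma_ppm + 1  # systematic error bound

    def test_normalization_preserves_centroid_set_noiseless(self, phantom_noiseless):
        _, dataset, _ = phantom_noiseless
        raw_peaks = pick_peaks(mean_spectrum(dataset))
        norm_peaks = pick_peaks(mean_spectrum(rms_normalize(dataset)))
        raw = np.array([e.centroid_mz for e in raw_peaks.entries])
        norm = np.array([e.centroid_mz for e in norm_peaks.entries])
        assert raw.size == norm.size
        np.testing.assert_allclose(raw, norm, rtol=5e-7)  # within 0.5 ppm


class TestShapeR2:
    def test_bimodal_merged_peak_scores_low(self):
        # two sharp (2 ppm sigma) ions 8 ppm apart merge under a 10 ppm window
        center = 500.0
        axis = center * (1 + np.linspace(-50, 50, 401) * 1e-6)
        ppm = (axis - center) / center * 1e6
        intensity = (
            0.01
            + 100 * np.exp(-0.5 * (ppm / 2) ** 2)
            + 90 * np.exp(-0.5 * ((ppm - 8) / 2) ** 2)
        )
        peaks = pick_peaks(Spectrum(axis, intensity), snr_min=3.0, window_ppm=10.0)
        assert len(peaks) == 1  # merged
        assert peaks.entries[0].shape_r2 < 0.8

    def test_clean_gaussian_scores_high(self):
        peaks = pick_peaks(gaussian_spectrum(), snr_min=3.0, window_ppm=10.0)
        assert peaks.entries[0].shape_r2 > 0.9


def toy_table(intensities):
    entries = [
        PeakEntry(
            centroid_mz=100.0 + i,
            mean_intensity=float(v),
            max_intensity=float(v),
            shape_r2=1.0,
        )
        for i, v in enumerate(intensities)
    ]
    return PeakTable(entries=entries)


class TestSelectTopN:
    def test_three_of_five(self):
        table = select_top_n(toy_table([5, 1, 4, 2, 3]), 3)
        assert [e.mean_intensity for e in table.entries] == [5, 4, 3]
        assert [e.centroid_mz for e in table.entries] == sorted(
            e.centroid_mz for e in table.entries
        )

    def test_n_larger_than_table(self):
        table = toy_table([1, 2])
        assert len(select_top_n(table, 10)) == 2

    def test_tie_at_cutoff_keeps_lower_mz(self):
        table = select_top_n(toy_table([5, 3, 3]), 2)
        assert [e.centroid_mz for e in table.entries] == [100.0, 101.0]

    def test_subset_and_monotone(self, rng):
        table = toy_table(rng.uniform(0, 10, size=30))
        previous: set = set()
        for n in (1, 5, 10, 30, 40):
            selected = {e.centroid_mz for e in select_top_n(table, n).entries}
            assert previous <= selected
            assert selected <= {e.centroid_mz for e in table.entries}
            previous = selected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            select_top_n(toy_table([1.0]), 0)


class TestPeakTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = toy_table([3.0, 1.0, 2.0])
        path = tmp_path / "peaks.csv"
        table.to_csv(path)
        back = PeakTable.from_csv(path)
        assert [e.centroid_mz for e in back.entries] == [e.centroid_mz for e in table.entries]

    def test_attach_images_sets_max(self):
        ds_matrix = [[1.0, 0.0], [5.0, 0.0]]
        ds = MSIDataset(
            coords=np.array([[1, 1], [2, 1]]),
            polarity="negative",
            mode="continuous",
            mz_axis=np.array([100.0, 150.0]),
            intensities=np.array(ds_matrix, dtype=np.float32),
        )
        table = PeakTable(
            entries=[PeakEntry(100.0, 3.0, 3.0, 1.0)], provenance={"window_ppm": 10.0}
        )
        attached = attach_images(table, ds)
        assert attached.entries[0].max_intensity == pytest.approx(5.0)
        np.testing.assert_allclose(attached.entries[0].image, [1.0, 5.0])
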