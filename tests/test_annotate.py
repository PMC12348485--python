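import math
import warnings

import numpy as np
import pytest

from seedmsi.annotate import (
    AnnotationTable,
    blank_filter,
    match_peaks,
    shape_filter,
    summarize,
)
from seedmsi.chem import (
    CompoundRecord,
    IonCandidate,
    bundled_library,
    build_ion_index,
    default_adducts,
    parse_formula,
)
from seedmsi.msio import MSIDataset
from seedmsi.preprocess import PeakEntry, PeakTable


def peak_table(mzs, r2=1.0):
    entries = [
        PeakEntry(centroid_mz=float(m), mean_intensity=1.0, max_intensity=1.0, shape_r2=r2)
        for m in sorted(mzs)
    ]
    return PeakTable(entries=entries)


def brute_force(peaks, index, tol_ppm):
    """Independent all-pairs matching oracle."""
    out = set()
    for i, entry in enumerate(peaks.entries):
        for candidate in index:
            ppm = abs(entry.centroid_mz - candidate.theoretical_mz) / candidate.theoretical_mz * 1e6
            if ppm <= tol_ppm:
                out.add((i, candidate.compound_id, candidate.adduct_label))
    return out


class TestMatchPeaks:
    def test_rutin_peak(self):
        library = bundled_library()
        index = build_ion_index(library, default_adducts("negative"), (50, 1200))
        table = match_peaks(peak_table([609.1461]), index, 5.0, library)
        rutin = [h for h in table.hits if h.compound_id == "rutin"]
        assert len(rutin) == 1
        assert abs(rutin[0].ppm_error) <= 1.0
        assert rutin[0].is_isomer_group  # schaftoside formate ion is isobaric

    def test_no_hit_outside_tolerance(self):
        index = [IonCandidate(100.0010, "x", "[M+H]+")]
        table = match_peaks(peak_table([100.0000]), index, 5.0)
        assert table.matched_hits() == []
        assert len(table.unmatched_peaks()) == 1

    def test_unsorted_index_rejected(self):
        index = [IonCandidate(200.0, "a", "[M+H]+"), IonCandidate(100.0, "b", "[M+H]+")]
        with pytest.raises(ValueError, match="sorted"):
            match_peaks(peak_table([150.0]), index, 5.0)

    def test_matches_brute_force_random(self, rng):
        for _ in range(20):
            n_cand = int(rng.integers(5, 60))
            index = sorted(
                IonCandidate(float(m), f"c{i}", "[M+H]+")
                for i, m in enumerate(rng.uniform(50, 1200, size=n_cand))
            )
            peaks = peak_table(np.unique(rng.uniform(50, 1200, size=20)))
            tol = float(rng.uniform(1, 500))
            table = match_peaks(peaks, index, tol)
            got = {
                (h.peak_index, h.compound_id, h.adduct_label)
                for h in table.matched_hits()
            }
            assert got == brute_force(peaks, index, tol)

    def test_tolerance_monotonicity(self, rng):
        index = sorted(
            IonCandidate(float(m), f"c{i}", "[M-H]-")
            for i, m in enumerate(rng.uniform(100, 1000, size=40))
        )
        peaks = peak_table(np.unique(rng.uniform(100, 1000, size=15)))
        previous: set = set()
        for tol in (1, 10, 100, 1000):
            got = {
                (h.peak_index, h.compound_id)
                for h in match_peaks(peaks, index, tol).matched_hits()
            }
            assert previous <= got
            previous = got

    def test_hits_ranked_by_abs_ppm(self):
        index = sorted(
            [
                IonCandidate(500.0010, "far", "[M+H]+"),
                IonCandidate(500.0001, "near", "[M+H]+"),
            ]
        )
        table = match_peaks(peak_table([500.0]), index, 5.0)
        assert [h.compound_id for h in table.matched_hits()] == ["near", "far"]


def two_region_dataset():
    """Four pixels: two 'blank' (x<=2) and two 'tissue'; two channels."""
    coords = np.array([[1, 1], [2, 1], [3, 1], [4, 1]])
    axis = np.array([100.0, 200.0])
    # channel 0: uniform everywhere; channel 1: tissue only
    matrix = np.array(
        [[5.0, 0.0], [5.0, 0.0], [5.0, 4.0], [5.0, 4.0]], dtype=np.float32
    )
    ds = MSIDataset(
        coords=coords,
        polarity="negative",
        mode="continuous",
        mz_axis=axis,
        intensities=matrix,
    )
    blank = np.array([True, True, False, False])
    return ds, blank


class TestBlankFilter:
    def _table(self):
        index = [
            IonCandidate(100.0, "uniform", "[M-H]-"),
            IonCandidate(200.0, "tissue", "[M-H]-"),
        ]
        return match_peaks(peak_table([100.0, 200.0]), index, 5.0)

    def test_uniform_ion_excluded(self):
        ds, blank = two_region_dataset()
        table = blank_filter(self._table(), ds, blank, tau=0.5)
        by_id = {h.compound_id: h for h in table.hits}
        assert by_id["uniform"].excluded == "blank"
        assert by_id["uniform"].blank_ratio == pytest.approx(1.0)

    def test_tissue_only_ion_retained(self):
        ds, blank = two_region_dataset()
        table = blank_filter(self._table(), ds, blank, tau=0.5)
        by_id = {h.compound_id: h for h in table.hits}
        assert by_id["tissue"].excluded == "none"
        assert by_id["tissue"].blank_ratio == pytest.approx(0.0)

    def test_infinite_tau_excludes_nothing(self):
        ds, blank = two_region_dataset()
        table = blank_filter(self._table(), ds, blank, tau=math.inf)
        assert all(h.excluded == "none" for h in table.hits)

    def test_zero_tissue_signal_excluded(self):
        ds, blank = two_region_dataset()
        ds.intensities[2:, 0] = 0.0  # uniform ion now blank-only
        table = blank_filter(self._table(), ds, blank, tau=0.5)
        by_id = {h.compound_id: h for h in table.hits}
        assert by_id["uniform"].excluded == "blank"
        assert math.isinf(by_id["uniform"].blank_ratio)

    def test_empty_blank_mask_warns_and_skips(self):
        ds, _ = two_region_dataset()
        with pytest.warns(UserWarning, match="blank"):
            table = blank_filter(self._table(), ds, np.zeros(4, dtype=bool), tau=0.5)
        assert all(h.excluded == "none" for h in table.hits)

    def test_tau_monotonicity(self):
        ds, blank = two_region_dataset()
        excluded_counts = []
        for tau in (0.1, 0.5, 2.0, math.inf):
            table = blank_filter(self._table(), ds, blank, tau=tau)
            excluded_counts.append(sum(h.excluded == "blank" for h in table.hits))
        assert excluded_counts == sorted(excluded_counts, reverse=True)

    def test_matrix_only_phantom_ions_excluded(self, annotated_default, phantom_default):
        _, _, manifest = phantom_default
        table = annotated_default["table"]
        for ion in manifest.matrix_ions():
            near = [
                h
                for h in table.hits
                if abs(h.centroid_mz - ion.observed_mz) / ion.observed_mz * 1e6 < 10
            ]
            assert near, f"matrix ion {ion.compound_id} produced no peak"
            assert all(h.excluded == "blank" for h in near)


class TestShapeFilter:
    def test_low_r2_excluded(self):
        index = [IonCandidate(100.0, "a", "[M-H]-")]
        table = match_peaks(peak_table([100.0], r2=0.4), index, 5.0)
        table = shape_filter(table, r2_min=0.8)
        assert table.hits[0].excluded == "shape"

    def test_zero_threshold_excludes_nothing(self):
        index = [IonCandidate(100.0, "a", "[M-H]-")]
        table = match_peaks(peak_table([100.0], r2=0.0), index, 5.0)
        table = shape_filter(table, r2_min=0.0)
        assert table.hits[0].excluded == "none"

    def test_clean_peak_retained(self):
        index = [IonCandidate(100.0, "a", "[M-H]-")]
        table = match_peaks(peak_table([100.0], r2=0.97), index, 5.0)
        table = shape_filter(table, r2_min=0.8)
        assert table.hits[0].excluded == "none"

    def test_blank_exclusion_not_overwritten(self):
        ds, blank = two_region_dataset()
        index = [IonCandidate(100.0, "uniform", "[M-H]-")]
        table = match_peaks(peak_table([100.0], r2=0.1), index, 5.0)
        table = blank_filter(table, ds, blank, tau=0.5)
        table = shape_filter(table, r2_min=0.8)
        assert table.hits[0].excluded == "blank"


class TestSummarize:
    def test_compound_with_two_adducts_counts_once(self):
        index = sorted(
            [IonCandidate(100.0, "a", "[M-H]-"), IonCandidate(150.0, "a", "[M+Cl]-")]
        )
        table = match_peaks(peak_table([100.0, 150.0]), index, 5.0)
        summary = summarize(table)
        assert summary["n_compounds"] == 1

    def test_empty_table(self):
        summary = summarize(AnnotationTable(hits=[]))
        assert summary["n_compounds"] == 0
        assert summary["per_class"] == {}

    def test_class_counts(self):
        library = [
            CompoundRecord("a", "A", parse_formula("C10H10O2"), "alkaloid"),
            CompoundRecord("b", "B", parse_formula("C11H10O2"), "flavonoid"),
        ]
        index = build_ion_index(library, default_adducts("negative"), (50, 1200))
        mzs = [c.theoretical_mz for c in index]
        table = match_peaks(peak_table(mzs), index, 5.0, library)
        summary = summarize(table)
        assert summary["per_class"] == {"alkaloid": 1, "flavonoid": 1}

    def test_excluded_hits_not_counted(self):
        index = [IonCandidate(100.0, "a", "[M-H]-")]
        table = match_peaks(peak_table([100.0], r2=0.1), index, 5.0)
        table = shape_filter(table, r2_min=0.8)
        assert summarize(table)["n_compounds"] == 0
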