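"""Spectrum normalization, mean-spectrum construction and peak picking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .msio import MSIDataset, Spectrum, ion_vector

__all__ = [
    "PeakEntry",
    "PeakTable",
    "rms_normalize",
    "mean_spectrum",
    "pick_peaks",
    "select_top_n",
    "attach_images",
]

DEFAULT_SNR_MIN = 3.0
DEFAULT_WINDOW_PPM = 10.0
DEFAULT_AXIS_BIN_PPM = 5.0
DEFAULT_TOP_N = 1020


def rms_normalize(dataset: MSIDataset) -> MSIDataset:
    """Divide each pixel's intensities by that spectrum's root mean square.

    RMS is computed per spectrum over all of its channels.  All-zero spectra
    are left unchanged; their pixel indices are flagged in
    ``meta["rms_zero_pixels"]``.  Already-normalized datasets pass through
    unchanged (the operation is idempotent).
    """
    out = dataset.copy()
    zero_pixels: list[int] = []
    if dataset.mode == "continuous":
        sq = dataset.intensities.astype(np.float64) ** 2
        rms = np.sqrt(sq.mean(axis=1))
        zero = rms == 0
        zero_pixels = [int(i) for i in np.flatnonzero(zero)]
        scale = np.where(zero, 1.0, rms)
        out.intensities = (dataset.intensities / scale[:, None]).astype(np.float32)
    else:
        for i, spec in enumerate(dataset.spectra):
            rms = float(np.sqrt(np.mean(spec.intensity.astype(np.float64) ** 2)))
            if rms == 0:
                zero_pixels.append(i)
                continue
            out.spectra[i] = Spectrum(spec.mz, spec.intensity / rms)
    out.meta["normalization"] = "rms"
    out.meta["rms_zero_pixels"] = zero_pixels
    return out


def mean_spectrum(
    dataset: MSIDataset, axis_bin_ppm: float = DEFAULT_AXIS_BIN_PPM
) -> Spectrum:
    """Pixel-wise mean intensity on a common m/z axis.

    Continuous datasets already share an axis; processed-mode spectra are
    accumulated onto a log-spaced axis with ``axis_bin_ppm`` relative bin
    width spanning the dataset's m/z range.
    """
    if dataset.mode == "continuous":
        return Spectrum(
            dataset.mz_axis,
            dataset.intensities.mean(axis=0, dtype=np.float64).astype(np.float32),
        )
    lo, hi = dataset.mz_range
    if not lo < hi:
        lo, hi = float(min(s.mz.min() for s in dataset.spectra)), float(
            max(s.mz.max() for s in dataset.spectra)
        )
        hi = max(hi, lo * (1 + 1e-6))
    step = np.log1p(axis_bin_ppm * 1e-6)
    n_bins = int(np.ceil(np.log(hi / lo) / step)) + 1
    edges = lo * np.exp(step * np.arange(n_bins + 1))
    centers = np.sqrt(edges[:-1] * edges[1:])
    accum = np.zeros(n_bins, dtype=np.float64)
    for spec in dataset.spectra:
        idx = np.clip(np.searchsorted(edges, spec.mz, side="right") - 1, 0, n_bins - 1)
        np.add.at(accum, idx, spec.intensity.astype(np.float64))
    accum /= dataset.n_pixels
    keep = np.ones(n_bins, dtype=bool)  # keep empty bins: they carry the noise floor
    return Spectrum(centers[keep], accum[keep].astype(np.float32))


@dataclass
class PeakEntry:
    """A picked peak on the mean spectrum.

    ``mean_intensity`` is the dataset-mean intensity summed over the peak
    window; ``max_intensity`` is the maximum over pixels of the same window
    sum (requires the dataset, see :func:`attach_images`); ``shape_r2`` is the
    goodness of a symmetric Gaussian fit to the mean-spectrum peak profile.
    """

    centroid_mz: float
    mean_intensity: float
    max_intensity: float
    shape_r2: float
    image: np.ndarray | None = None  # per-pixel window sums, coords-aligned

    def __post_init__(self) -> None:
        if self.centroid_mz <= 0:
            raise ValueError("centroid m/z must be positive")
        if self.mean_intensity > self.max_intensity + 1e-9:
            raise ValueError("mean intensity cannot exceed max intensity")


@dataclass
class PeakTable:
    entries: list[PeakEntry] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mzs = [e.centroid_mz for e in self.entries]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak centroids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centroid_mz": [e.centroid_mz for e in self.entries],
                "mean_intensity": [e.mean_intensity for e in self.entries],
                "max_intensity": [e.max_intensity for e in self.entries],
                "shape_r2": [e.shape_r2 for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakTable":
        frame = pd.read_csv(path)
        entries = [
            PeakEntry(
                centroid_mz=float(row.centroid_mz),
                mean_intensity=float(row.mean_intensity),
                max_intensity=float(row.max_intensity),
                shape_r2=float(row.shape_r2),
            )
            for row in frame.itertuples()
        ]
        return cls(entries=entries, provenance={"source": str(path)})


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _shape_r2(mz: np.ndarray, intensity: np.ndarray, apex_idx: int, window_ppm: float) -> float:
    """R^2 of a symmetric Gaussian fit to the local peak profile.

    The profile window spans +/- 4x the merge window so the full flanks of an
    instrument-width peak are seen.  Windows with fewer than 4 points carry no
    shape evidence and score 1.0.
    """
    center = mz[apex_idx]
    half = center * 4 * window_ppm * 1e-6
    sel = (mz >= center - half) & (mz <= center + half)
    x, y = mz[sel], intensity[sel].astype(np.float64)
    if x.size < 4 or y.max() <= 0:
        return 1.0
    sigma0 = max((x.max() - x.min()) / 6, center * 1e-7)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gaussian,
                x,
                y,
                p0=(float(y.max()), float(x[np.argmax(y)]), sigma0),
                maxfev=2000,
            )
        fitted = _gaussian(x, *popt)
    except (RuntimeError, ValueError):
        return 0.0
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def pick_peaks(
    mean_spec: Spectrum,
    snr_min: float = DEFAULT_SNR_MIN,
    window_ppm: float = DEFAULT_WINDOW_PPM,
) -> PeakTable:
    """Pick local maxima with SNR >= ``snr_min`` on the mean spectrum.

    Noise is 1.4826 x the median absolute deviation of the mean spectrum.
    Centroids are intensity-weighted means over +/- ``window_ppm``; peaks
    closer than ``window_ppm`` are merged keeping the taller.
    """
    mz, intensity = mean_spec.mz, mean_spec.intensity.astype(np.float64)
    if mz.size == 0:
        raise ValueError("mean spectrum is empty")
    mad = float(np.median(np.abs(intensity - np.median(intensity))))
    noise = 1.4826 * mad
    threshold = snr_min * noise

    # An apex is the maximum of its +/- window_ppm neighborhood and strictly
    # above the neighborhood minimum (rejects flat plateaus and staircase
    # artifacts from float32-quantized tails).
    apex = []
    for i in range(mz.size):
        value = intensity[i]
        if value <= 0 or value < threshold:
            continue
        half = mz[i] * window_ppm * 1e-6
        j0 = int(np.searchsorted(mz, mz[i] - half))
        j1 = int(np.searchsorted(mz, mz[i] + half, side="right"))
        window = intensity[j0:j1]
        if value == window.max() and (window.size == 1 or value > window.min()):
            apex.append(i)

    # Merge apexes closer than the window, keeping the taller.
    merged: list[int] = []
    for i in apex:
        if merged and (mz[i] - mz[merged[-1]]) / mz[merged[-1]] * 1e6 < window_ppm:
            if intensity[i] > intensity[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    entries = []
    for i in merged:
        half = mz[i] * window_ppm * 1e-6
        sel = (mz >= mz[i] - half) & (mz <= mz[i] + half)
        weights = intensity[sel]
        centroid = float(np.average(mz[sel], weights=weights)) if weights.sum() > 0 else float(mz[i])
        window_sum = float(weights.sum())
        entries.append(
            PeakEntry(
                centroid_mz=centroid,
                mean_intensity=window_sum,
                max_intensity=window_sum,  # refined by attach_images
                shape_r2=_shape_r2(mz, intensity, i, window_ppm),
            )
        )
    entries.sort(key=lambda e: e.centroid_mz)
    deduped: list[PeakEntry] = []
    for entry in entries:
        if deduped and (entry.centroid_mz - deduped[-1].centroid_mz) / deduped[-1].centroid_mz * 1e6 < window_ppm:
            if entry.mean_intensity > deduped[-1].mean_intensity:
                deduped[-1] = entry
        else:
            deduped.append(entry)
    return PeakTable(
        entries=deduped,
        provenance={"snr_min": snr_min, "window_ppm": window_ppm, "noise": noise},
    )


def attach_images(
    peaks: PeakTable, dataset: MSIDataset, window_ppm: float | None = None
) -> PeakTable:
    """Fill per-pixel window sums and the max-over-pixels intensity per peak."""
    window_ppm = window_ppm or float(peaks.provenance.get("window_ppm", DEFAULT_WINDOW_PPM))
    entries = []
    for entry in peaks.entries:
        vec = ion_vector(dataset, entry.centroid_mz, window_ppm)
        entries.append(
            replace(
                entry,
                image=vec,
                max_intensity=max(float(vec.max()), entry.mean_intensity),
            )
        )
    return PeakTable(entries=entries, provenance=dict(peaks.provenance))


def select_top_n(peaks: PeakTable, n: int = DEFAULT_TOP_N) -> PeakTable:
    """Keep the ``n`` entries with the largest mean intensity, re-sorted by m/z.

    Ties at the cutoff are broken in favor of lower m/z.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(peaks.entries, key=lambda e: (-e.mean_intensity, e.centroid_mz))
    kept = sorted(ranked[:n], key=lambda e: e.centroid_mz)
    provenance = dict(peaks.provenance)
    provenance["top_n"] = n
    return PeakTable(entries=kept, provenance=provenance)
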