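"""Accurate-mass matching of picked peaks against an ion index, plus the two
exclusion filters (blank-control distribution and poor peak shape)."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import CompoundRecord, IonCandidate, candidates_in_window
from .msio import MSIDataset, ion_vector
from .preprocess import PeakTable

__all__ = [
    "AnnotationHit",
    "AnnotationTable",
    "match_peaks",
    "blank_filter",
    "shape_filter",
    "summarize",
]

DEFAULT_TOL_PPM = 5.0
DEFAULT_BLANK_TAU = 0.5
DEFAULT_SHAPE_R2_MIN = 0.8


@dataclass
class AnnotationHit:
    """One (peak, compound, adduct) match; unmatched peaks have no compound."""

    peak_index: int
    centroid_mz: float
    compound_id: str | None
    adduct_label: str | None
    name: str | None = None
    metabolite_class: str | None = None
    theoretical_mz: float = math.nan
    ppm_error: float = math.nan
    blank_ratio: float = math.nan
    shape_r2: float = math.nan
    excluded: str = "none"  # none | blank | shape
    is_isomer_group: bool = False

    @property
    def matched(self) -> bool:
        return self.compound_id is not None

    @property
    def retained(self) -> bool:
        return self.matched and self.excluded == "none"


@dataclass
class AnnotationTable:
    hits: list[AnnotationHit] = field(default_factory=list)
    peaks: PeakTable | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        triples = [
            (h.peak_index, h.compound_id, h.adduct_label) for h in self.hits if h.matched
        ]
        if len(triples) != len(set(triples)):
            raise ValueError("duplicate (peak, compound, adduct) annotation")

    def retained_hits(self) -> list[AnnotationHit]:
        return [h for h in self.hits if h.retained]

    def matched_hits(self) -> list[AnnotationHit]:
        return [h for h in self.hits if h.matched]

    def unmatched_peaks(self) -> list[AnnotationHit]:
        return [h for h in self.hits if not h.matched]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centroid_mz": [h.centroid_mz for h in self.hits],
                "compound_id": [h.compound_id or "" for h in self.hits],
                "name": [h.name or "" for h in self.hits],
                "class": [h.metabolite_class or "" for h in self.hits],
                "adduct": [h.adduct_label or "" for h in self.hits],
                "theoretical_mz": [h.theoretical_mz for h in self.hits],
                "ppm_error": [h.ppm_error for h in self.hits],
                "blank_ratio": [h.blank_ratio for h in self.hits],
                "shape_r2": [h.shape_r2 for h in self.hits],
                "excluded": [h.excluded for h in self.hits],
                "is_isomer_group": [h.is_isomer_group for h in self.hits],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def match_peaks(
    peaks: PeakTable,
    index: Sequence[IonCandidate],
    tol_ppm: float = DEFAULT_TOL_PPM,
    library: Sequence[CompoundRecord] | None = None,
) -> AnnotationTable:
    """Report every candidate within ``tol_ppm`` of each peak centroid.

    Isomers (several compounds on one peak) are retained as a group.  Hits
    within a peak are ranked by |ppm error|, then compound id.  Unmatched
    peaks are kept as compound-less rows, never dropped.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    mzs = [c.theoretical_mz for c in index]
    if any(b < a for a, b in zip(mzs, mzs[1:])):
        raise ValueError("ion index must be sorted by theoretical m/z")
    by_id: Mapping[str, CompoundRecord] = (
        {r.compound_id: r for r in library} if library else {}
    )
    hits: list[AnnotationHit] = []
    for peak_index, entry in enumerate(peaks.entries):
        matches = candidates_in_window(index, entry.centroid_mz, tol_ppm)
        if not matches:
            hits.append(
                AnnotationHit(
                    peak_index=peak_index,
                    centroid_mz=entry.centroid_mz,
                    compound_id=None,
                    adduct_label=None,
                    shape_r2=entry.shape_r2,
                )
            )
            continue
        n_compounds = len({c.compound_id for c in matches})
        ranked = sorted(
            matches,
            key=lambda c: (
                abs(entry.centroid_mz - c.theoretical_mz) / c.theoretical_mz,
                c.compound_id,
                c.adduct_label,
            ),
        )
        for candidate in ranked:
            record = by_id.get(candidate.compound_id)
            ppm = (
                (entry.centroid_mz - candidate.theoretical_mz)
                / candidate.theoretical_mz
                * 1e6
            )
            hits.append(
                AnnotationHit(
                    peak_index=peak_index,
                    centroid_mz=entry.centroid_mz,
                    compound_id=candidate.compound_id,
                    adduct_label=candidate.adduct_label,
                    name=record.name if record else None,
                    metabolite_class=record.metabolite_class if record else None,
                    theoretical_mz=candidate.theoretical_mz,
                    ppm_error=ppm,
                    shape_r2=entry.shape_r2,
                    is_isomer_group=n_compounds > 1,
                )
            )
    return AnnotationTable(hits=hits, peaks=peaks, provenance={"tol_ppm": tol_ppm})


def blank_filter(
    table: AnnotationTable,
    dataset: MSIDataset,
    blank_mask: np.ndarray,
    tau: float = DEFAULT_BLANK_TAU,
    tol_ppm: float | None = None,
) -> AnnotationTable:
    """Flag peaks whose signal sits in the blank control.

    ``blank_mask`` is a boolean vector aligned to ``dataset.coords`` marking
    off-tissue (blank/matrix) pixels.  A peak's blank ratio is its mean ion
    intensity over blank pixels divided by the mean over on-tissue pixels;
    ratios >= ``tau`` are excluded, as are peaks with zero on-tissue signal.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    blank_mask = np.asarray(blank_mask, dtype=bool)
    if blank_mask.shape != (dataset.n_pixels,):
        raise ValueError("blank mask must align with the dataset's pixel list")
    if not blank_mask.any():
        warnings.warn("empty blank mask: blank filter skipped")
        return table
    if blank_mask.all():
        raise ValueError("blank mask covers every pixel; no on-tissue pixels remain")
    tol = tol_ppm or float(table.provenance.get("tol_ppm", DEFAULT_TOL_PPM))

    ratios: dict[int, float] = {}
    for hit in table.hits:
        if hit.peak_index not in ratios:
            vec = ion_vector(dataset, hit.centroid_mz, tol)
            blank_mean = float(vec[blank_mask].mean())
            tissue_mean = float(vec[~blank_mask].mean())
            ratios[hit.peak_index] = (
                blank_mean / tissue_mean if tissue_mean > 0 else math.inf
            )
        hit.blank_ratio = ratios[hit.peak_index]
        if hit.blank_ratio >= tau and hit.excluded == "none":
            hit.excluded = "blank"
    table.provenance["blank_tau"] = tau
    return table


def shape_filter(
    table: AnnotationTable, r2_min: float = DEFAULT_SHAPE_R2_MIN
) -> AnnotationTable:
    """Flag hits whose peak's Gaussian-fit R^2 falls below ``r2_min``."""
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must lie in [0, 1]")
    for hit in table.hits:
        if math.isnan(hit.shape_r2):
            raise ValueError(f"peak {hit.peak_index} lacks a shape_r2 value")
        if hit.shape_r2 < r2_min and hit.excluded == "none":
            hit.excluded = "shape"
    table.provenance["shape_r2_min"] = r2_min
    return table


def summarize(table: AnnotationTable) -> dict:
    """Distinct retained compounds overall and per metabolite class.

    A compound matched by several adducts (or several peaks) counts once.
    Isomer-group members each count as their own listed compound.
    """
    retained = table.retained_hits()
    compounds: dict[str, str] = {}
    for hit in retained:
        compounds.setdefault(hit.compound_id, hit.metabolite_class or "unclassified")
    per_class: dict[str, int] = {}
    for cls in compounds.values():
        per_class[cls] = per_class.get(cls, 0) + 1
    return {
        "n_compounds": len(compounds),
        "per_class": dict(sorted(per_class.items())),
        "n_peaks": len({h.peak_index for h in table.hits}),
        "n_matched_peaks": len({h.peak_index for h in table.matched_hits()}),
        "n_unmatched_peaks": len(table.unmatched_peaks()),
        "n_excluded_blank": len({h.peak_index for h in table.hits if h.excluded == "blank"}),
        "n_excluded_shape": len({h.peak_index for h in table.hits if h.excluded == "shape"}),
    }
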