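"""Per-tissue intensity tables, presence calls, counts and the heatmap matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationTable
from .msio import MSIDataset, ion_vector
from .spatial import ROIMask, TISSUE_LABELS

__all__ = [
    "TissueTable",
    "HeatmapMatrix",
    "roi_intensity_table",
    "presence_calls",
    "tissue_counts",
    "heatmap_matrix",
]

DEFAULT_BETA = 0.10
DEFAULT_GAMMA = 3.0

_EXTRA_COLUMNS = ("cavity", "background")


@dataclass
class TissueTable:
    """Metabolite x region mean-intensity matrix.

    The four tissue columns come first; cavity and background are tracked as
    extra columns but excluded from tissue counts.  Row metadata (name, class,
    representative m/z) ride along for reporting.
    """

    intensities: pd.DataFrame
    classes: pd.Series
    names: pd.Series
    mz: pd.Series
    presence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expected = list(TISSUE_LABELS) + list(_EXTRA_COLUMNS)
        if list(self.intensities.columns) != expected:
            raise ValueError(f"columns must be {expected}")
        values = self.intensities.to_numpy()
        if np.any(values[np.isfinite(values)] < 0):
            raise ValueError("intensities must be non-negative")

    def tissue_intensities(self) -> pd.DataFrame:
        return self.intensities[list(TISSUE_LABELS)]

    def to_csv(self, path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "name", self.names)
        out.insert(1, "class", self.classes)
        out.insert(2, "mz", self.mz)
        out.to_csv(path, index_label="compound_id", float_format="%.6f")


def roi_intensity_table(
    dataset: MSIDataset,
    annotations: AnnotationTable,
    roi: ROIMask,
    tol_ppm: float | None = None,
) -> TissueTable:
    """Mean ion intensity of each retained metabolite over each region's pixels.

    A metabolite's ion signal is the sum of its retained peaks' windows (a
    compound seen as several adducts contributes all of them, but still counts
    as one metabolite downstream).
    """
    tol = tol_ppm or float(annotations.provenance.get("tol_ppm", 5.0))
    region_labels = roi.labels_for(dataset.coords)
    region_masks = {}
    for label in list(TISSUE_LABELS) + list(_EXTRA_COLUMNS):
        mask = region_labels == label
        if label in TISSUE_LABELS and not mask.any():
            warnings.warn(f"tissue {label!r} has zero pixels; column will be NaN")
        region_masks[label] = mask

    per_compound: dict[str, dict] = {}
    for hit in annotations.retained_hits():
        info = per_compound.setdefault(
            hit.compound_id,
            {"peaks": {}, "name": hit.name, "class": hit.metabolite_class, "mz": []},
        )
        info["peaks"][hit.peak_index] = hit.centroid_mz
        info["mz"].append(hit.theoretical_mz)

    rows, classes, names, mzs = [], [], [], []
    index = sorted(per_compound)
    for compound_id in index:
        info = per_compound[compound_id]
        signal = np.zeros(dataset.n_pixels)
        for centroid in info["peaks"].values():
            signal += ion_vector(dataset, centroid, tol)
        row = {}
        for label, mask in region_masks.items():
            row[label] = float(signal[mask].mean()) if mask.any() else np.nan
        rows.append(row)
        classes.append(info["class"] or "unclassified")
        names.append(info["name"] or compound_id)
        mzs.append(min(info["mz"]) if info["mz"] else np.nan)

    columns = list(TISSUE_LABELS) + list(_EXTRA_COLUMNS)
    frame = pd.DataFrame(rows, index=pd.Index(index, name="compound_id"), columns=columns)
    return TissueTable(
        intensities=frame,
        classes=pd.Series(classes, index=frame.index, name="class"),
        names=pd.Series(names, index=frame.index, name="name"),
        mz=pd.Series(mzs, index=frame.index, name="mz"),
    )


def presence_calls(
    table: TissueTable, beta: float = DEFAULT_BETA, gamma: float = DEFAULT_GAMMA
) -> pd.DataFrame:
    """Boolean presence matrix over the four tissues.

    A metabolite is present in tissue T iff its mean there is positive, is at
    least ``beta`` x its maximum tissue mean, and is at least ``gamma`` x its
    background mean.
    """
    if beta < 0 or gamma < 0:
        raise ValueError("beta and gamma must be non-negative")
    tissues = table.tissue_intensities().fillna(0.0)
    background = table.intensities["background"].fillna(0.0)
    row_max = tissues.max(axis=1)
    presence = (
        (tissues > 0)
        & tissues.ge(beta * row_max, axis=0)
        & tissues.ge(gamma * background, axis=0)
    )
    table.presence = presence
    return presence


def tissue_counts(presence: pd.DataFrame, classes: pd.Series) -> dict:
    """Per-tissue totals, overall distinct total and per-class composition."""
    per_tissue = {t: int(presence[t].sum()) for t in TISSUE_LABELS}
    anywhere = presence.any(axis=1)
    composition = {}
    for tissue in TISSUE_LABELS:
        counts = classes[presence[tissue]].value_counts().sort_index()
        composition[tissue] = {str(k): int(v) for k, v in counts.items()}
    overall = classes[anywhere].value_counts().sort_index()
    return {
        "per_tissue": per_tissue,
        "n_distinct": int(anywhere.sum()),
        "class_composition": composition,
        "overall_by_class": {str(k): int(v) for k, v in overall.items()},
    }


@dataclass
class HeatmapMatrix:
    """Row-scaled (max = 1) intensity matrix ordered by class, then m/z."""

    matrix: pd.DataFrame
    row_order: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, index_label="compound_id", float_format="%.6f")

    def render_png(self, path: str | Path, cmap: str = "RdYlBu_r") -> None:
        """Optional thin rendering layer (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(self.matrix)), 3), constrained_layout=True
        )
        data = self.matrix.to_numpy(dtype=float).T
        im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=1)
        ax.set_yticks(range(len(self.matrix.columns)), self.matrix.columns)
        ax.set_xticks(range(len(self.matrix)), self.matrix.index, rotation=90, fontsize=5)
        fig.colorbar(im, ax=ax, label="relative intensity")
        fig.savefig(path, dpi=150)
        plt.close(fig)


def heatmap_matrix(table: TissueTable) -> HeatmapMatrix:
    """Scale each metabolite row to max 1 and order rows by class then m/z.

    All-zero rows stay all-zero.  Scaling is idempotent.
    """
    tissues = table.tissue_intensities().fillna(0.0)
    row_max = tissues.max(axis=1)
    scale = row_max.where(row_max > 0, 1.0)
    scaled = tissues.div(scale, axis=0)
    order = sorted(
        scaled.index,
        key=lambda cid: (str(table.classes[cid]), float(table.mz[cid]), cid),
    )
    return HeatmapMatrix(matrix=scaled.loc[order], row_order=list(order))
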