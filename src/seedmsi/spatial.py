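"""K-means segmentation of MSI data and cluster-to-tissue ROI mapping."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.cluster import KMeans

from .msio import MSIDataset, ion_vector
from .preprocess import PeakTable

__all__ = [
    "TISSUE_LABELS",
    "ROI_LABELS",
    "ROIMask",
    "SegmentationResult",
    "feature_matrix",
    "kmeans_segment",
    "clusters_to_roi",
    "majority_vote_mapping",
    "load_roi_labels",
    "save_roi_labels",
]

TISSUE_LABELS = ("pericarp", "seed_coat", "cotyledon", "plumule")
ROI_LABELS = TISSUE_LABELS + ("cavity", "background")

DEFAULT_K = 10
DEFAULT_N_RESTARTS = 10


@dataclass
class ROIMask:
    """A per-pixel anatomical label image (strings from ``ROI_LABELS``)."""

    labels: np.ndarray  # (height, width) array of label strings

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        unknown = set(np.unique(self.labels)) - set(ROI_LABELS)
        if unknown:
            raise ValueError(f"unknown ROI labels: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: str) -> np.ndarray:
        if label not in ROI_LABELS:
            raise ValueError(f"unknown label {label!r}")
        return self.labels == label

    def labels_for(self, coords: np.ndarray) -> np.ndarray:
        """Label per pixel for 1-based (x, y) coordinate rows."""
        coords = np.asarray(coords)
        return self.labels[coords[:, 1] - 1, coords[:, 0] - 1]

    def pixel_mask_for(self, coords: np.ndarray, label: str) -> np.ndarray:
        return self.labels_for(coords) == label


@dataclass
class SegmentationResult:
    """Cluster assignment (ids 1..k) per pixel, plus provenance."""

    cluster_ids: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int]
    k: int
    inertia: float
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.cluster_ids.shape[0] != self.coords.shape[0]:
            raise ValueError("one cluster id per pixel required")
        if self.cluster_ids.min() < 1 or self.cluster_ids.max() > self.k:
            raise ValueError("cluster ids must lie in 1..k")


def feature_matrix(dataset: MSIDataset, peaks: PeakTable, window_ppm: float | None = None) -> np.ndarray:
    """Per-pixel feature vectors: intensities at the picked peak channels."""
    if len(peaks) == 0:
        raise ValueError("peak table is empty")
    columns = []
    for entry in peaks.entries:
        if entry.image is not None and entry.image.shape == (dataset.n_pixels,):
            columns.append(np.asarray(entry.image, dtype=np.float64))
        else:
            w = window_ppm or float(peaks.provenance.get("window_ppm", 10.0))
            columns.append(ion_vector(dataset, entry.centroid_mz, w))
    return np.column_stack(columns)


def kmeans_segment(
    dataset: MSIDataset,
    peaks: PeakTable,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> SegmentationResult:
    """Lloyd k-means (k-means++ init, best of ``n_restarts``) on peak features.

    Pixels are ordered canonically by (y, x) before clustering so the result
    is invariant to the dataset's pixel enumeration order; assignments are
    returned in the dataset's own pixel order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if dataset.n_pixels < k:
        raise ValueError(f"only {dataset.n_pixels} pixels but k={k}")
    features = feature_matrix(dataset, peaks)
    order = np.lexsort((dataset.coords[:, 0], dataset.coords[:, 1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trigger ConvergenceWarning
        model = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            random_state=seed,
            algorithm="lloyd",
        ).fit(features[order])
    assignments = np.empty(dataset.n_pixels, dtype=np.int64)
    assignments[order] = model.labels_ + 1
    return SegmentationResult(
        cluster_ids=assignments,
        coords=dataset.coords.copy(),
        grid_shape=dataset.grid_shape,
        k=k,
        inertia=float(model.inertia_),
        seed=seed,
        provenance={"n_restarts": n_restarts, "n_features": features.shape[1]},
    )


def clusters_to_roi(
    segmentation: SegmentationResult, mapping: Mapping[int, str]
) -> ROIMask:
    """Relabel clusters to anatomical ROIs; unmapped clusters become background."""
    present = set(np.unique(segmentation.cluster_ids).tolist())
    unknown = set(mapping) - set(range(1, segmentation.k + 1))
    if unknown:
        raise ValueError(f"mapping references unknown cluster ids: {sorted(unknown)}")
    for label in mapping.values():
        if label not in ROI_LABELS:
            raise ValueError(f"unknown tissue label {label!r}")
    grid = np.full(segmentation.grid_shape, "background", dtype="<U16")
    labels = np.array(
        [mapping.get(int(c), "background") for c in segmentation.cluster_ids]
    )
    grid[segmentation.coords[:, 1] - 1, segmentation.coords[:, 0] - 1] = labels
    return ROIMask(grid)


def majority_vote_mapping(
    segmentation: SegmentationResult, truth: ROIMask
) -> dict[int, str]:
    """Map each cluster to the most frequent true ROI label among its pixels."""
    true_labels = truth.labels_for(segmentation.coords)
    mapping: dict[int, str] = {}
    for cluster in np.unique(segmentation.cluster_ids):
        members = true_labels[segmentation.cluster_ids == cluster]
        values, counts = np.unique(members, return_counts=True)
        mapping[int(cluster)] = str(values[np.argmax(counts)])
    return mapping


def save_roi_labels(
    roi: ROIMask, labels_path: str | Path, palette_path: str | Path
) -> None:
    """Write an integer label matrix (TSV) plus a YAML palette."""
    palette = {label: i for i, label in enumerate(ROI_LABELS)}
    codes = np.vectorize(palette.__getitem__)(roi.labels)
    np.savetxt(labels_path, codes, fmt="%d", delimiter="\t")
    with open(palette_path, "w", encoding="utf-8") as handle:
        yaml.safe_dump({int(v): k for k, v in palette.items()}, handle)


def load_roi_labels(
    labels_path: str | Path,
    palette_path: str | Path,
    expected_shape: tuple[int, int] | None = None,
) -> ROIMask:
    """Decode an integer label matrix via its palette into an :class:`ROIMask`."""
    codes = np.atleast_2d(np.loadtxt(labels_path, dtype=np.int64, delimiter="\t"))
    with open(palette_path, "r", encoding="utf-8") as handle:
        palette = yaml.safe_load(handle)
    palette = {int(k): str(v) for k, v in palette.items()}
    if expected_shape is not None and codes.shape != tuple(expected_shape):
        raise ValueError(
            f"label image shape {codes.shape} does not match expected {expected_shape}"
        )
    unknown_codes = set(np.unique(codes).tolist()) - set(palette)
    if unknown_codes:
        raise ValueError(f"label values without palette entry: {sorted(unknown_codes)}")
    missing = set(ROI_LABELS) - set(palette.values())
    if missing:
        warnings.warn(f"palette lacks labels {sorted(missing)}; those tissues are absent")
    grid = np.vectorize(palette.__getitem__)(codes).astype("<U16")
    return ROIMask(grid)
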