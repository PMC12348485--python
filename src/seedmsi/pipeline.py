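"""End-to-end pipeline: normalize -> pick -> annotate -> filter -> segment ->
semi-quantify, driven by a single validated configuration."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import annotate as annotate_mod
from . import chem, msio, preprocess, semiquant, spatial

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]

CONFIG_SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class RunConfig:
    imzml: str = ""
    library: str = ""  # empty -> bundled mini-library
    adducts: str = ""  # empty -> built-in default adduct set
    roi_labels: str = ""
    roi_palette: str = ""
    cluster_map: dict[int, str] = field(default_factory=dict)
    out_dir: str = "results"
    tol_ppm: float = annotate_mod.DEFAULT_TOL_PPM
    tau: float = annotate_mod.DEFAULT_BLANK_TAU
    r2_min: float = annotate_mod.DEFAULT_SHAPE_R2_MIN
    n_top: int = preprocess.DEFAULT_TOP_N
    snr_min: float = preprocess.DEFAULT_SNR_MIN
    window_ppm: float = preprocess.DEFAULT_WINDOW_PPM
    axis_bin_ppm: float = preprocess.DEFAULT_AXIS_BIN_PPM
    k: int = spatial.DEFAULT_K
    n_restarts: int = spatial.DEFAULT_N_RESTARTS
    beta: float = semiquant.DEFAULT_BETA
    gamma: float = semiquant.DEFAULT_GAMMA
    seed: int = 0
    extras: dict[str, Any] = field(default_factory=dict)


_RANGES = {
    "tol_ppm": (0.0, 1000.0),
    "tau": (0.0, float("inf")),
    "r2_min": (0.0, 1.0),
    "n_top": (1, 10**9),
    "snr_min": (0.0, float("inf")),
    "window_ppm": (0.0, 1000.0),
    "axis_bin_ppm": (0.0, 1000.0),
    "k": (2, 10**6),
    "n_restarts": (1, 10**4),
    "beta": (0.0, 1.0),
    "gamma": (0.0, float("inf")),
}


def validate_config(
    raw: Mapping[str, Any] | None,
) -> tuple[RunConfig, list[str], list[str]]:
    """Normalize a raw config mapping into a :class:`RunConfig`.

    Defaults are injected for absent keys; every problem is collected rather
    than failing on the first.  Unknown keys warn and are preserved in
    ``extras``.  Returns (config, errors, warnings).
    """
    raw = dict(raw or {})
    errors: list[str] = []
    notes: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"extras"}
    config = RunConfig()
    for key, value in raw.items():
        if key not in known:
            notes.append(f"unknown config key {key!r} preserved in extras")
            config.extras[key] = value
            continue
        default = getattr(config, key)
        try:
            if isinstance(default, int) and not isinstance(default, bool):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
            elif isinstance(default, dict) and key == "cluster_map":
                value = {int(k): str(v) for k, v in dict(value).items()}
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot coerce {value!r}")
            continue
        setattr(config, key, value)
    for key, (lo, hi) in _RANGES.items():
        value = getattr(config, key)
        if not lo <= value <= hi:
            errors.append(f"{key}: {value} outside allowed range [{lo}, {hi}]")
    if not 0 < config.tol_ppm:
        errors.append("tol_ppm: must be positive")
    if not 0 < config.tau:
        errors.append("tau: must be positive")
    for key in ("imzml", "library", "adducts", "roi_labels", "roi_palette"):
        path = getattr(config, key)
        if path and not Path(path).exists():
            errors.append(f"{key}: file not found: {path}")
    if config.imzml and Path(config.imzml).exists():
        ibd = Path(config.imzml).with_suffix(".ibd")
        if not ibd.exists():
            errors.append(f"imzml: companion ibd missing: {ibd}")
    return config, errors, notes


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, message: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.lines.append(f"{stamp} {message}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _stage(log: _Log, name: str):
    class _Context:
        def __enter__(self):
            log.write(f"stage {name}: start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.write(f"stage {name}: FAILED: {exc}")
                log.flush()
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.write(f"stage {name}: done")
            return False

    return _Context()


def run_pipeline(config: RunConfig, dataset: msio.MSIDataset | None = None) -> dict:
    """Execute the full workflow and write the report bundle to ``out_dir``.

    ``dataset`` may be supplied directly (e.g. a freshly rendered phantom);
    otherwise it is read from ``config.imzml``.  Returns a result dictionary
    with the main in-memory artifacts and the paths written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(out_dir / "run.log")
    log.write(f"config schema {CONFIG_SCHEMA_VERSION}; parameters: "
              + json.dumps({k: v for k, v in dataclasses.asdict(config).items() if k != "extras"},
                           sort_keys=True, default=str))

    with _stage(log, "read"):
        if dataset is None:
            if not config.imzml:
                raise ValueError("no input dataset: set 'imzml' in the config")
            dataset = msio.read_imzml(config.imzml)
        log.write(f"read {dataset.n_pixels} pixels, polarity {dataset.polarity}")

    with _stage(log, "normalize"):
        normalized = preprocess.rms_normalize(dataset)

    with _stage(log, "pick_peaks"):
        mean_spec = preprocess.mean_spectrum(normalized, config.axis_bin_ppm)
        peaks = preprocess.pick_peaks(mean_spec, config.snr_min, config.window_ppm)
        peaks = preprocess.attach_images(peaks, normalized)
        peaks = preprocess.select_top_n(peaks, config.n_top)
        peaks.to_csv(out_dir / "peaks.csv")
        log.write(f"{len(peaks)} peaks after top-{config.n_top} selection")

    with _stage(log, "annotate"):
        library = (
            chem.load_library(config.library) if config.library else chem.bundled_library()
        )
        adducts = (
            chem.load_adducts(config.adducts)
            if config.adducts
            else chem.default_adducts()
        )
        adducts = [a for a in adducts if a.polarity == dataset.polarity]
        index = chem.build_ion_index(library, adducts, dataset.mz_range)
        table = annotate_mod.match_peaks(peaks, index, config.tol_ppm, library)

    with _stage(log, "segment"):
        segmentation = spatial.kmeans_segment(
            normalized, peaks, k=config.k, seed=config.seed, n_restarts=config.n_restarts
        )
        grid = np.zeros(segmentation.grid_shape, dtype=np.int64)
        grid[segmentation.coords[:, 1] - 1, segmentation.coords[:, 0] - 1] = (
            segmentation.cluster_ids
        )
        np.savetxt(out_dir / "segmentation.tsv", grid, fmt="%d", delimiter="\t")

    with _stage(log, "roi"):
        if config.roi_labels:
            roi = spatial.load_roi_labels(
                config.roi_labels,
                config.roi_palette,
                expected_shape=dataset.grid_shape,
            )
        elif config.cluster_map:
            roi = spatial.clusters_to_roi(segmentation, config.cluster_map)
        else:
            raise ValueError("provide either roi_labels/roi_palette or cluster_map")

    with _stage(log, "filter"):
        blank = roi.pixel_mask_for(dataset.coords, "background")
        table = annotate_mod.blank_filter(table, normalized, blank, config.tau)
        table = annotate_mod.shape_filter(table, config.r2_min)
        table.to_csv(out_dir / "annotation.csv")

    with _stage(log, "semiquant"):
        tissue_table = semiquant.roi_intensity_table(normalized, table, roi)
        tissue_table.to_csv(out_dir / "intensity_table.csv")
        presence = semiquant.presence_calls(tissue_table, config.beta, config.gamma)
        presence.astype(int).to_csv(out_dir / "presence.csv", index_label="compound_id")
        counts = semiquant.tissue_counts(presence, tissue_table.classes)
        heatmap = semiquant.heatmap_matrix(tissue_table)
        heatmap.to_csv(out_dir / "heatmap_matrix.csv")

    with _stage(log, "report"):
        summary = annotate_mod.summarize(table)
        retained_ids = {h.compound_id for h in table.retained_hits()}
        summary["tissue_counts"] = counts
        summary["undetected_compounds"] = sorted(
            r.compound_id for r in library if r.compound_id not in retained_ids
        )
        summary["parameters"] = {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("extras",)
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    log.flush()
    return {
        "dataset": dataset,
        "normalized": normalized,
        "peaks": peaks,
        "annotation": table,
        "segmentation": segmentation,
        "roi": roi,
        "tissue_table": tissue_table,
        "presence": presence,
        "counts": counts,
        "summary": summary,
        "out_dir": out_dir,
    }
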