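"""Synthetic seed-section phantoms with known ground truth.

The phantom emulates a seed cross-section on a 50 um pixel grid: a pericarp
ring outermost, a seed-coat ring, a cotyledon body, a central plumule ellipse
separated from the cotyledon by a cavity annulus, and off-tissue matrix
background.  Ions from the bundled compound library are planted with
region-specific abundances, ppm-scale mass error, multiplicative lognormal
intensity noise and an additive baseline, and every planted quantity is
recorded in a ground-truth manifest so each pipeline stage can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .annotate import AnnotationTable
from .chem import CompoundRecord, bundled_library, default_adducts
from .msio import MSIDataset, write_imzml
from .spatial import ROI_LABELS, ROIMask, SegmentationResult, save_roi_labels

__all__ = [
    "PhantomConfig",
    "PlantedIon",
    "GroundTruthManifest",
    "RecoveryScore",
    "make_geometry",
    "apex_mask",
    "default_planting_plan",
    "render",
    "score_recovery",
    "score_segmentation",
]

# Compounds deliberately kept out of every planting plan even though they sit
# in the library: the pipeline must report them as undetected.
UNPLANTED_LIBRARY_COMPOUNDS = ("liensinine", "isoliensinine", "neferine")

# Planted ions of different compounds closer than this are skipped (identical
# formula+adduct groups excepted) so ground-truth presence stays well defined
# and Gaussian peak profiles (2 sigma ~ 28 ppm at RP 30k) do not interfere.
_COLLISION_GUARD_PPM = 70.0


@dataclass
class PhantomConfig:
    width: int = 120
    height: int = 100
    pixel_size_um: float = 50.0
    mz_range: tuple[float, float] = (50.0, 1200.0)
    polarity: str = "negative"
    # geometry (fractions of the outer ellipse's normalized radius)
    outer_rx: float = 0.46  # semi-axis as fraction of grid width
    outer_ry: float = 0.44  # semi-axis as fraction of grid height
    pericarp_width: float = 0.12
    seedcoat_width: float = 0.10
    plumule_frac: float = 0.18  # plumule semi-axes as fraction of outer axes
    cavity_gap: float = 0.45  # annulus width relative to the plumule radius
    apex_angle_deg: float = 70.0
    # noise model
    sigma_ppm: float = 2.0
    sigma_intensity: float = 0.3
    baseline_sigma: float = 0.002
    resolving_power: float = 30000.0
    n_matrix_ions: int = 10
    n_decoy_channels: int = 1000
    seed: int = 42

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("grid too small")
        if min(self.pericarp_width, self.seedcoat_width, self.plumule_frac, self.cavity_gap) <= 0:
            raise ValueError("ring widths and plumule size must be positive")
        if self.pericarp_width + self.seedcoat_width >= 1:
            raise ValueError("pericarp + seed-coat rings exhaust the seed (degenerate)")
        if self.plumule_frac * (1 + self.cavity_gap) >= 1 - self.pericarp_width - self.seedcoat_width:
            raise ValueError("plumule + cavity overlap the seed coat (degenerate)")
        if min(self.sigma_ppm, self.sigma_intensity, self.baseline_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def _radii(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized outer/plumule elliptic radii and polar angle per grid cell."""
    ys, xs = np.mgrid[1 : config.height + 1, 1 : config.width + 1]
    cx, cy = (config.width + 1) / 2, (config.height + 1) / 2
    a, b = config.outer_rx * config.width, config.outer_ry * config.height
    r_outer = np.sqrt(((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2)
    ap, bp = a * config.plumule_frac, b * config.plumule_frac
    r_plumule = np.sqrt(((xs - cx) / ap) ** 2 + ((ys - cy) / bp) ** 2)
    angle = np.arctan2(-(ys - cy), xs - cx)  # 'up' on the image is +pi/2
    return r_outer, r_plumule, angle


def make_geometry(config: PhantomConfig) -> ROIMask:
    """Concentric-region label image for the phantom grid."""
    config.validate()
    r_outer, r_plumule, _ = _radii(config)
    labels = np.full((config.height, config.width), "background", dtype="<U16")
    inside = r_outer <= 1
    labels[inside] = "cotyledon"
    labels[inside & (r_outer > 1 - config.pericarp_width)] = "pericarp"
    ring = inside & (r_outer <= 1 - config.pericarp_width)
    labels[ring & (r_outer > 1 - config.pericarp_width - config.seedcoat_width)] = "seed_coat"
    labels[r_plumule <= 1 + config.cavity_gap] = "cavity"
    labels[r_plumule <= 1] = "plumule"
    roi = ROIMask(labels)
    for label in ROI_LABELS:
        if not roi.mask(label).any():
            raise ValueError(f"degenerate geometry: region {label!r} is empty")
    return roi


def apex_mask(config: PhantomConfig) -> np.ndarray:
    """Pixels in the apex sector of the pericarp ring (top of the seed)."""
    r_outer, _, angle = _radii(config)
    half = math.radians(config.apex_angle_deg) / 2
    in_ring = (r_outer <= 1) & (r_outer > 1 - config.pericarp_width)
    return in_ring & (np.abs(angle - math.pi / 2) <= half)


@dataclass
class PlantedIon:
    compound_id: str
    adduct_label: str | None  # None marks a synthetic matrix ion
    theoretical_mz: float
    region_means: dict[str, float]
    apex_only: bool = False
    is_matrix: bool = False
    observed_mz: float | None = None  # theoretical * (1 + systematic ppm error)


# Qualitative tissue localizations of the bundled compounds (relative means).
# Mass-degenerate isomers share one profile so presence truth stays exact.
_ISOMER_PROFILE = {"pericarp": 1.0, "plumule": 0.7}
_TAXIFOLIN_PROFILE = {"pericarp": 0.9, "seed_coat": 1.0}
_LOCALIZATIONS: dict[str, tuple[dict[str, float], bool]] = {
    "arginine": ({"pericarp": 0.9, "cotyledon": 1.0, "plumule": 0.8}, False),
    "glutathione": ({"pericarp": 1.0, "seed_coat": 0.9, "cotyledon": 0.8, "plumule": 0.9}, False),
    "coclaurine": ({"pericarp": 1.0}, True),
    "armepavine": ({"pericarp": 1.0, "plumule": 0.8}, True),
    "feruloyltyramine": ({"pericarp": 1.0, "seed_coat": 0.6, "plumule": 0.8}, True),
    "xylopine": ({"cotyledon": 1.0, "plumule": 0.9}, False),
    "pheophytin_a": ({"pericarp": 1.0}, True),
    "kaempferol": ({"pericarp": 1.0, "seed_coat": 0.8}, False),
    "catechin": ({"pericarp": 1.0, "seed_coat": 0.8}, False),
    "taxifolin": (_TAXIFOLIN_PROFILE, False),
    "epitaxifolin": (_TAXIFOLIN_PROFILE, False),
    "methyladenosine_5o": ({"pericarp": 1.0, "seed_coat": 0.8, "cavity": 0.6}, False),
    "palmitic_acid": ({"pericarp": 0.9, "cotyledon": 1.0, "plumule": 0.8}, False),
    "oleic_acid": ({"cotyledon": 1.0, "plumule": 0.7}, False),
    "linolenic_acid": ({"pericarp": 1.0, "seed_coat": 0.9}, False),
    "anisic_acid": ({"pericarp": 1.0, "seed_coat": 0.9}, False),
    "myricetin_3_glucoside": ({"pericarp": 1.0, "seed_coat": 0.9}, False),
    "astragalin": ({"pericarp": 1.0, "seed_coat": 0.7, "plumule": 0.9, "cavity": 0.5}, False),
    "rutin": ({"pericarp": 1.0, "plumule": 0.9, "cavity": 0.6}, False),
    "syringetin_3_glucoside": ({"plumule": 1.0, "cavity": 0.6}, False),
    "vitexin": ({"plumule": 1.0, "cavity": 0.5}, False),
    "luteolin_7_rutinoside": ({"plumule": 1.0, "cavity": 0.6}, False),
    # schaftoside's formate adduct is isobaric with rutin [M-H]- (both
    # C27H29O16-), so their images are inseparable; planting it with rutin's
    # pericarp component keeps ground-truth presence well defined.
    "schaftoside": ({"pericarp": 0.7, "plumule": 1.0, "cavity": 0.5}, False),
    "lanuginosine": ({"pericarp": 1.0, "seed_coat": 0.8, "cotyledon": 0.7, "plumule": 0.8}, False),
    "pronuciferine": ({"cotyledon": 1.0}, False),
    "norcoclaurine": ({"pericarp": 1.0}, False),
    "norarmepavine": (_ISOMER_PROFILE, False),
    "methylisococlaurine": (_ISOMER_PROFILE, False),
    "methylcoclaurine": (_ISOMER_PROFILE, False),
}

_ADDUCT_SCALE = (1.0, 0.55, 0.3)


def default_planting_plan(
    polarity: str,
    library: Sequence[CompoundRecord] | None = None,
    mz_range: tuple[float, float] = (50.0, 1200.0),
) -> list[PlantedIon]:
    """A planting plan reproducing the qualitative tissue localizations.

    Every compound with a known localization is planted as each default
    adduct of the polarity (with decreasing abundance), skipping ions that
    would collide in mass with a previously planted ion of a different
    compound.  Bisbenzylisoquinoline dimers stay in the library but are never
    planted.
    """
    library = list(library) if library is not None else bundled_library()
    by_id = {r.compound_id: r for r in library}
    adducts = default_adducts(polarity)
    if not adducts:
        raise ValueError(f"no adducts defined for polarity {polarity!r}")
    lo, hi = mz_range
    plan: list[PlantedIon] = []
    for record in library:
        if record.compound_id in UNPLANTED_LIBRARY_COMPOUNDS:
            continue
        if record.compound_id not in _LOCALIZATIONS:
            continue
        profile, apex_only = _LOCALIZATIONS[record.compound_id]
        for adduct, scale in zip(adducts, _ADDUCT_SCALE):
            mz = record.neutral_mass + adduct.mass_shift
            if not lo <= mz <= hi:
                continue
            collision = False
            for planted in plan:
                if abs(mz - planted.theoretical_mz) / planted.theoretical_mz * 1e6 >= _COLLISION_GUARD_PPM:
                    continue
                same_species = (
                    planted.adduct_label == adduct.label
                    and str(by_id[planted.compound_id].formula) == str(record.formula)
                )
                if not same_species:
                    collision = True
                    break
            if collision:
                continue
            plan.append(
                PlantedIon(
                    compound_id=record.compound_id,
                    adduct_label=adduct.label,
                    theoretical_mz=mz,
                    region_means={k: v * scale for k, v in profile.items()},
                    apex_only=apex_only,
                )
            )
    if not plan:
        raise ValueError(f"planting plan for polarity {polarity!r} is empty")
    return plan


def _matrix_ions(
    config: PhantomConfig, plan: Sequence[PlantedIon], rng: np.random.Generator
) -> list[PlantedIon]:
    """Synthetic matrix-only ions, well away (> 20 ppm) from every library ion.

    An 80 ppm guard keeps matrix peaks from overlapping library peak profiles,
    so blank-filter behavior is never confounded with tolerance behavior.
    """
    library = bundled_library()
    reserved = [
        r.neutral_mass + a.mass_shift
        for r in library
        for a in default_adducts()
    ] + [p.theoretical_mz for p in plan]
    reserved = np.array(sorted(reserved))
    lo, hi = config.mz_range
    ions = []
    while len(ions) < config.n_matrix_ions:
        mz = float(rng.uniform(lo + 5, hi - 5))
        if np.min(np.abs(reserved - mz)) / mz * 1e6 <= 80:
            continue
        level = float(rng.uniform(1.0, 2.0))
        ions.append(
            PlantedIon(
                compound_id=f"matrix_{len(ions) + 1:02d}",
                adduct_label=None,
                theoretical_mz=mz,
                region_means={label: level for label in ROI_LABELS},
                is_matrix=True,
            )
        )
        reserved = np.sort(np.append(reserved, mz))
    return ions


@dataclass
class GroundTruthManifest:
    config: PhantomConfig
    ions: list[PlantedIon]
    roi: ROIMask
    apex_fraction: float

    def planted_ions(self) -> list[PlantedIon]:
        return [i for i in self.ions if not i.is_matrix]

    def matrix_ions(self) -> list[PlantedIon]:
        return [i for i in self.ions if i.is_matrix]

    def expected_presence(self) -> dict[str, set[str]]:
        """compound_id -> set of tissues it was planted in (4 tissues only)."""
        out: dict[str, set[str]] = {}
        for ion in self.planted_ions():
            tissues = {
                t
                for t, v in ion.region_means.items()
                if v > 0 and t in ("pericarp", "seed_coat", "cotyledon", "plumule")
            }
            out.setdefault(ion.compound_id, set()).update(tissues)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "apex_fraction": self.apex_fraction,
            "ions": [asdict(ion) for ion in self.ions],
            "roi_labels": self.roi.labels.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        raw_config = payload["config"]
        raw_config["mz_range"] = tuple(raw_config["mz_range"])
        config = PhantomConfig(**raw_config)
        ions = [PlantedIon(**ion) for ion in payload["ions"]]
        return cls(
            config=config,
            ions=ions,
            roi=ROIMask(np.array(payload["roi_labels"])),
            apex_fraction=payload["apex_fraction"],
        )


def render(
    config: PhantomConfig,
    plan: Sequence[PlantedIon] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[MSIDataset, GroundTruthManifest]:
    """Render the phantom to an in-memory dataset plus its manifest.

    Per pixel, each planted ion's intensity is its region mean times lognormal
    noise; its observed m/z is the theoretical value shifted by a systematic
    per-ion mass error drawn from N(0, sigma_ppm).  Peaks get a Gaussian m/z
    profile whose width follows the configured resolving power, riding on an
    additive baseline.  Fully deterministic given the seed.  With ``out_dir``
    the imzML/ibd pair, manifest JSON and ROI label matrix are also written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roi = make_geometry(config)
    apex = apex_mask(config)

    plan = list(plan) if plan is not None else default_planting_plan(
        config.polarity, mz_range=config.mz_range
    )
    ions = plan + _matrix_ions(config, plan, rng)

    # Systematic per-ion mass error (shared across pixels).
    eps = rng.normal(0.0, config.sigma_ppm * 1e-6, size=len(ions))
    for ion, e in zip(ions, eps):
        ion.observed_mz = ion.theoretical_mz * (1 + float(e))

    on_grid = roi.labels != "__never__"  # all grid cells become pixels
    ys, xs = np.nonzero(on_grid)
    coords = np.column_stack([xs + 1, ys + 1]).astype(np.int64)
    region_per_pixel = roi.labels[ys, xs]
    apex_per_pixel = apex[ys, xs]
    n_pixels = len(coords)

    # Base intensity per (pixel, ion).
    base = np.zeros((n_pixels, len(ions)))
    for j, ion in enumerate(ions):
        for label, mean in ion.region_means.items():
            mask = region_per_pixel == label
            if ion.apex_only and label == "pericarp":
                mask = mask & apex_per_pixel
            base[mask, j] = mean
    if config.sigma_intensity > 0:
        base *= rng.lognormal(0.0, config.sigma_intensity, size=base.shape)

    # Gaussian m/z profile: 5 points at 0, +/-1, +/-2 profile sigmas.
    sigma_prof_rel = 1e6 / (config.resolving_power * 2.3548) * 1e-6
    offsets = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) * sigma_prof_rel
    weights = np.exp(-0.5 * np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) ** 2)

    channel_mz = []
    for ion in ions:
        channel_mz.append(ion.observed_mz * (1 + offsets))
    channel_mz = np.concatenate(channel_mz)
    ion_of_channel = np.repeat(np.arange(len(ions)), offsets.size)
    weight_of_channel = np.tile(weights, len(ions))

    # Decoy baseline-only channels spread over the mass range.
    lo, hi = config.mz_range
    decoys = np.linspace(lo + 1, hi - 1, config.n_decoy_channels)
    decoys = decoys * (1 + rng.normal(0, 2e-6, size=decoys.size))
    channel_mz = np.concatenate([channel_mz, decoys])
    ion_of_channel = np.concatenate(
        [ion_of_channel, np.full(decoys.size, -1, dtype=np.int64)]
    )
    weight_of_channel = np.concatenate([weight_of_channel, np.zeros(decoys.size)])

    order = np.argsort(channel_mz, kind="stable")
    channel_mz = channel_mz[order]
    ion_of_channel = ion_of_channel[order]
    weight_of_channel = weight_of_channel[order]

    intensities = np.zeros((n_pixels, channel_mz.size), dtype=np.float64)
    signal_cols = ion_of_channel >= 0
    intensities[:, signal_cols] = (
        base[:, ion_of_channel[signal_cols]] * weight_of_channel[signal_cols]
    )
    # Mass-degenerate ions (e.g. isomers at zero mass error) share channels.
    unique_mz, inverse = np.unique(channel_mz, return_inverse=True)
    if unique_mz.size < channel_mz.size:
        merged = np.zeros((n_pixels, unique_mz.size), dtype=np.float64)
        np.add.at(merged.T, inverse, intensities.T)
        channel_mz, intensities = unique_mz, merged
    if config.baseline_sigma > 0:
        intensities += np.abs(
            rng.normal(0.0, config.baseline_sigma, size=intensities.shape)
        )

    dataset = MSIDataset(
        coords=coords,
        polarity=config.polarity,
        pixel_size_um=config.pixel_size_um,
        mz_range=config.mz_range,
        mode="continuous",
        mz_axis=channel_mz,
        intensities=intensities.astype(np.float32),
        meta={"phantom_seed": config.seed},
    )
    ring = roi.mask("pericarp")
    manifest = GroundTruthManifest(
        config=config,
        ions=ions,
        roi=roi,
        apex_fraction=float(apex.sum() / max(ring.sum(), 1)),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        uuid_bytes = np.random.default_rng(config.seed).bytes(16)
        write_imzml(dataset, out_dir / "phantom.imzML", uuid_bytes=uuid_bytes)
        manifest.to_json(out_dir / "manifest.json")
        save_roi_labels(roi, out_dir / "roi_labels.tsv", out_dir / "roi_palette.yaml")
    return dataset, manifest


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_planted: int
    n_recovered: int
    n_matched_peaks: int
    n_true_peaks: int
    ppm_errors: dict[str, float]
    empty_annotation: bool = False


def score_recovery(
    table: AnnotationTable, manifest: GroundTruthManifest
) -> RecoveryScore:
    """Precision/recall of retained annotations against the planted ions.

    Recall is ion-level: a planted (compound, adduct) counts as recovered if
    some retained hit names it.  Precision is peak-level: a matched, retained
    peak is a true positive if at least one of its hits names a planted ion.
    """
    planted = {
        (ion.compound_id, ion.adduct_label): ion for ion in manifest.planted_ions()
    }
    retained = table.retained_hits()
    if not retained:
        return RecoveryScore(
            precision=0.0,
            recall=0.0,
            n_planted=len(planted),
            n_recovered=0,
            n_matched_peaks=0,
            n_true_peaks=0,
            ppm_errors={},
            empty_annotation=True,
        )
    recovered = set()
    ppm_errors: dict[str, float] = {}
    peaks_with_hits: dict[int, bool] = {}
    for hit in retained:
        key = (hit.compound_id, hit.adduct_label)
        truthy = key in planted
        peaks_with_hits[hit.peak_index] = peaks_with_hits.get(hit.peak_index, False) or truthy
        if truthy:
            recovered.add(key)
            ion = planted[key]
            ppm_errors[f"{hit.compound_id}|{hit.adduct_label}"] = (
                (hit.centroid_mz - ion.theoretical_mz) / ion.theoretical_mz * 1e6
            )
    n_true_peaks = sum(peaks_with_hits.values())
    return RecoveryScore(
        precision=n_true_peaks / len(peaks_with_hits),
        recall=len(recovered) / len(planted),
        n_planted=len(planted),
        n_recovered=len(recovered),
        n_matched_peaks=len(peaks_with_hits),
        n_true_peaks=n_true_peaks,
        ppm_errors=ppm_errors,
    )


def score_segmentation(
    segmentation: SegmentationResult | ROIMask,
    manifest: GroundTruthManifest,
    coords: np.ndarray | None = None,
) -> float:
    """Adjusted Rand index of a segmentation against the phantom's true regions.

    Accepts either raw cluster assignments or an already-mapped ROI mask.
    """
    if isinstance(segmentation, SegmentationResult):
        coords = segmentation.coords
        predicted = segmentation.cluster_ids
    else:
        if coords is None:
            ys, xs = np.nonzero(np.ones(segmentation.shape, dtype=bool))
            coords = np.column_stack([xs + 1, ys + 1])
        predicted = segmentation.labels_for(coords)
    if manifest.roi.shape[0] < coords[:, 1].max() or manifest.roi.shape[1] < coords[:, 0].max():
        raise ValueError("segmentation coordinates fall outside the phantom grid")
    truth = manifest.roi.labels_for(coords)
    return float(adjusted_rand_score(truth, predicted))
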