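"""Shared fixtures: rendered phantoms and annotated pipelines.

The heavy artifacts are session-scoped so the full-size phantom is rendered
once per run; smaller phantoms back the I/O and determinism tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedmsi import annotate, chem, preprocess
from seedmsi.phantom import PhantomConfig, render


def annotate_phantom(dataset, manifest, tol_ppm=5.0, tau=0.5, r2_min=0.8):
    """Normalize, pick, match and filter a rendered phantom."""
    normalized = preprocess.rms_normalize(dataset)
    mean_spec = preprocess.mean_spectrum(normalized)
    peaks = preprocess.pick_peaks(mean_spec)
    peaks = preprocess.attach_images(peaks, normalized)
    peaks = preprocess.select_top_n(peaks, 1020)
    library = chem.bundled_library()
    index = chem.build_ion_index(
        library, chem.default_adducts(dataset.polarity), dataset.mz_range
    )
    table = annotate.match_peaks(peaks, index, tol_ppm, library)
    blank = manifest.roi.pixel_mask_for(dataset.coords, "background")
    table = annotate.blank_filter(table, normalized, blank, tau)
    table = annotate.shape_filter(table, r2_min)
    return {
        "normalized": normalized,
        "mean_spec": mean_spec,
        "peaks": peaks,
        "library": library,
        "index": index,
        "table": table,
    }


@pytest.fixture(scope="session")
def phantom_default():
    config = PhantomConfig()  # seed 42, sigma_ppm 2, default noise
    dataset, manifest = render(config)
    return config, dataset, manifest


@pytest.fixture(scope="session")
def phantom_noiseless():
    config = PhantomConfig(sigma_ppm=0.0, sigma_intensity=0.0, baseline_sigma=0.0)
    dataset, manifest = render(config)
    return config, dataset, manifest


@pytest.fixture(scope="session")
def phantom_small():
    config = PhantomConfig(width=60, height=50, n_decoy_channels=300, seed=7)
    dataset, manifest = render(config)
    return config, dataset, manifest


@pytest.fixture(scope="session")
def annotated_default(phantom_default):
    _, dataset, manifest = phantom_default
    return annotate_phantom(dataset, manifest)


@pytest.fixture(scope="session")
def annotated_noiseless(phantom_noiseless):
    _, dataset, manifest = phantom_noiseless
    return annotate_phantom(dataset, manifest)


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """A small phantom written to disk as imzML + manifest + ROI labels."""
    out = tmp_path_factory.mktemp("phantom")
    config = PhantomConfig(width=60, height=50, n_decoy_channels=300, seed=7)
    dataset, manifest = render(config, out_dir=out)
    return out, config, dataset, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
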