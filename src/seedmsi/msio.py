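"""imzML 1.1 reading/writing and pixel-indexed access to MSI data.

Both binary layouts of the standard are supported: *continuous* (one shared
m/z axis, per-pixel intensity rows) and *processed* (per-pixel m/z +
intensity pairs).  m/z values are stored as 64-bit floats and intensities as
32-bit floats, the common practice for imzML.  Pixel coordinates are 1-based,
x rightward and y downward, matching the imzML convention.
"""

from __future__ import annotations

import hashlib
import struct
import uuid as uuid_module
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "MSIDataset",
    "IonImage",
    "read_imzml",
    "write_imzml",
    "ion_image",
    "ion_vector",
]


@dataclass
class Spectrum:
    """A single mass spectrum with a strictly ascending m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be 1-D and equally long")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class MSIDataset:
    """A pixel grid of mass spectra of uniform polarity.

    ``coords`` holds 1-based (x, y) integer positions, one row per pixel.
    Continuous datasets carry a shared ``mz_axis`` and an
    ``(n_pixels, n_channels)`` intensity matrix; processed datasets carry one
    :class:`Spectrum` per pixel.  Missing grid positions are simply absent
    from ``coords`` (they are never zero-filled).
    """

    coords: np.ndarray
    polarity: str
    pixel_size_um: float = 50.0
    mz_range: tuple[float, float] = (50.0, 1200.0)
    mode: str = "continuous"
    mz_axis: np.ndarray | None = None
    intensities: np.ndarray | None = None
    spectra: list[Spectrum] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (x, y) positions")
        if len(self.coords) == 0:
            raise ValueError("empty dataset: no pixels")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")
        if np.any(self.coords < 1):
            raise ValueError("coordinates are 1-based and must be >= 1")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if self.mode == "continuous":
            if self.mz_axis is None or self.intensities is None:
                raise ValueError("continuous dataset requires mz_axis and intensities")
            self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
            self.intensities = np.asarray(self.intensities, dtype=np.float32)
            if self.intensities.shape != (len(self.coords), self.mz_axis.size):
                raise ValueError("intensity matrix shape must be (n_pixels, n_channels)")
            if self.mz_axis.size > 1 and not np.all(np.diff(self.mz_axis) > 0):
                raise ValueError("shared m/z axis must be strictly ascending")
        elif self.mode == "processed":
            if self.spectra is None or len(self.spectra) != len(self.coords):
                raise ValueError("processed dataset requires one spectrum per pixel")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) spanned by the pixel coordinates."""
        return int(self.coords[:, 1].max()), int(self.coords[:, 0].max())

    def spectrum(self, i: int) -> Spectrum:
        if self.mode == "continuous":
            return Spectrum(self.mz_axis, self.intensities[i])
        return self.spectra[i]

    def copy(self) -> "MSIDataset":
        return MSIDataset(
            coords=self.coords.copy(),
            polarity=self.polarity,
            pixel_size_um=self.pixel_size_um,
            mz_range=self.mz_range,
            mode=self.mode,
            mz_axis=None if self.mz_axis is None else self.mz_axis.copy(),
            intensities=None if self.intensities is None else self.intensities.copy(),
            spectra=None
            if self.spectra is None
            else [Spectrum(s.mz.copy(), s.intensity.copy()) for s in self.spectra],
            meta=dict(self.meta),
        )


@dataclass
class IonImage:
    """Per-pixel summed intensity in a narrow m/z window, as a 2-D grid.

    Grid cells without a pixel hold NaN.
    """

    values: np.ndarray
    target_mz: float
    tol_ppm: float

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be positive")


def ion_vector(dataset: MSIDataset, target_mz: float, tol_ppm: float) -> np.ndarray:
    """Summed intensity in |mz - target| <= tol_ppm, aligned to ``dataset.coords``."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    lo = target_mz * (1 - tol_ppm * 1e-6)
    hi = target_mz * (1 + tol_ppm * 1e-6)
    if dataset.mode == "continuous":
        i0, i1 = np.searchsorted(dataset.mz_axis, [lo, hi + 0.0])
        i1 = int(np.searchsorted(dataset.mz_axis, hi, side="right"))
        return dataset.intensities[:, i0:i1].sum(axis=1, dtype=np.float64)
    out = np.zeros(dataset.n_pixels, dtype=np.float64)
    for i, spec in enumerate(dataset.spectra):
        j0 = int(np.searchsorted(spec.mz, lo))
        j1 = int(np.searchsorted(spec.mz, hi, side="right"))
        out[i] = spec.intensity[j0:j1].sum(dtype=np.float64)
    return out


def ion_image(dataset: MSIDataset, target_mz: float, tol_ppm: float) -> IonImage:
    """Render the ion image of a target m/z window on the pixel grid."""
    lo, hi = dataset.mz_range
    if not lo <= target_mz <= hi:
        raise ValueError(f"target m/z {target_mz} outside dataset range {dataset.mz_range}")
    vec = ion_vector(dataset, target_mz, tol_ppm)
    height, width = dataset.grid_shape
    grid = np.full((height, width), np.nan)
    grid[dataset.coords[:, 1] - 1, dataset.coords[:, 0] - 1] = vec
    return IonImage(grid, target_mz, tol_ppm)


# --------------------------------------------------------------------------
# imzML writing
# --------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"

_CV_POLARITY = {
    "positive": ("MS:1000130", "positive scan"),
    "negative": ("MS:1000129", "negative scan"),
}


def _cv(parent: ET.Element, ref: str, accession: str, name: str, value: str = "", **extra):
    attrib = {"cvRef": ref, "accession": accession, "name": name, "value": value}
    attrib.update(extra)
    return ET.SubElement(parent, "cvParam", attrib)


def write_imzml(
    dataset: MSIDataset,
    path: str | Path,
    mode: str | None = None,
    uuid_bytes: bytes | None = None,
    resample_axis: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write an imzML/ibd pair; returns the two paths.

    Writing a processed-mode dataset as continuous requires ``resample_axis``
    (intensities are accumulated into the nearest axis channel).  A fixed
    ``uuid_bytes`` makes the output reproducible byte for byte.
    """
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    ibd_path = path.with_suffix(".ibd")
    mode = mode or dataset.mode

    ds = dataset
    if mode == "continuous" and dataset.mode == "processed":
        if resample_axis is None:
            raise ValueError(
                "continuous-mode write of processed data requires a resampling axis"
            )
        ds = _resample_to_axis(dataset, np.asarray(resample_axis, dtype=np.float64))
    if mode == "processed" and dataset.mode == "continuous":
        ds = MSIDataset(
            coords=dataset.coords,
            polarity=dataset.polarity,
            pixel_size_um=dataset.pixel_size_um,
            mz_range=dataset.mz_range,
            mode="processed",
            spectra=[dataset.spectrum(i) for i in range(dataset.n_pixels)],
        )

    if uuid_bytes is None:
        uuid_bytes = uuid_module.uuid4().bytes
    if len(uuid_bytes) != 16:
        raise ValueError("uuid_bytes must be 16 bytes")

    # Binary container first: uuid, then external arrays.
    offsets: list[tuple[int, int, int, int, int, int]] = []
    with open(ibd_path, "wb") as ibd:
        ibd.write(uuid_bytes)
        if mode == "continuous":
            mz_bytes = np.ascontiguousarray(ds.mz_axis, dtype=np.float64).tobytes()
            mz_offset, mz_len = 16, ds.mz_axis.size
            ibd.write(mz_bytes)
            pos = 16 + len(mz_bytes)
            for i in range(ds.n_pixels):
                row = np.ascontiguousarray(ds.intensities[i], dtype=np.float32).tobytes()
                offsets.append((mz_offset, mz_len, mz_len * 8, pos, ds.intensities.shape[1], len(row)))
                ibd.write(row)
                pos += len(row)
        else:
            pos = 16
            for spec in ds.spectra:
                mz_b = np.ascontiguousarray(spec.mz, dtype=np.float64).tobytes()
                in_b = np.ascontiguousarray(spec.intensity, dtype=np.float32).tobytes()
                offsets.append((pos, spec.mz.size, len(mz_b), pos + len(mz_b), spec.intensity.size, len(in_b)))
                ibd.write(mz_b)
                ibd.write(in_b)
                pos += len(mz_b) + len(in_b)

    sha1 = hashlib.sha1(ibd_path.read_bytes()).hexdigest()

    root = ET.Element(
        "mzML",
        {
            "xmlns": _MZML_NS,
            "version": "1.1.0",
        },
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "3"})
    for cv_id, name, uri in [
        ("MS", "Proteomics Standards Initiative Mass Spectrometry Ontology",
         "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
        ("UO", "Unit Ontology", "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"),
        ("IMS", "Imaging MS Ontology", "https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo"),
    ]:
        ET.SubElement(cv_list, "cv", {"id": cv_id, "fullName": name, "URI": uri})

    file_desc = ET.SubElement(root, "fileDescription")
    content = ET.SubElement(file_desc, "fileContent")
    _cv(content, "MS", "MS:1000579", "MS1 spectrum")
    if mode == "continuous":
        _cv(content, "IMS", "IMS:1000030", "continuous")
    else:
        _cv(content, "IMS", "IMS:1000031", "processed")
    _cv(content, "IMS", "IMS:1000080", "universally unique identifier",
        "{" + str(uuid_module.UUID(bytes=uuid_bytes)) + "}")
    _cv(content, "IMS", "IMS:1000091", "ibd SHA-1", sha1)

    rpg_list = ET.SubElement(root, "referenceableParamGroupList", {"count": "2"})
    mz_group = ET.SubElement(rpg_list, "referenceableParamGroup", {"id": "mzArray"})
    _cv(mz_group, "MS", "MS:1000514", "m/z array", unitCvRef="MS",
        unitAccession="MS:1000040", unitName="m/z")
    _cv(mz_group, "MS", "MS:1000523", "64-bit float")
    _cv(mz_group, "MS", "MS:1000576", "no compression")
    _cv(mz_group, "IMS", "IMS:1000101", "external data", "true")
    int_group = ET.SubElement(rpg_list, "referenceableParamGroup", {"id": "intensityArray"})
    _cv(int_group, "MS", "MS:1000515", "intensity array", unitCvRef="MS",
        unitAccession="MS:1000131", unitName="number of detector counts")
    _cv(int_group, "MS", "MS:1000521", "32-bit float")
    _cv(int_group, "MS", "MS:1000576", "no compression")
    _cv(int_group, "IMS", "IMS:1000101", "external data", "true")

    soft_list = ET.SubElement(root, "softwareList", {"count": "1"})
    soft = ET.SubElement(soft_list, "software", {"id": "seedmsi", "version": "0.1.0"})
    _cv(soft, "MS", "MS:1000799", "custom unreleased software tool", "seedmsi")

    scan_settings_list = ET.SubElement(root, "scanSettingsList", {"count": "1"})
    scan_settings = ET.SubElement(scan_settings_list, "scanSettings", {"id": "scanSettings1"})
    height, width = ds.grid_shape
    _cv(scan_settings, "IMS", "IMS:1000042", "max count of pixels x", str(width))
    _cv(scan_settings, "IMS", "IMS:1000043", "max count of pixels y", str(height))
    _cv(scan_settings, "IMS", "IMS:1000046", "pixel size (x)", str(ds.pixel_size_um),
        unitCvRef="UO", unitAccession="UO:0000017", unitName="micrometer")
    _cv(scan_settings, "IMS", "IMS:1000047", "pixel size y", str(ds.pixel_size_um),
        unitCvRef="UO", unitAccession="UO:0000017", unitName="micrometer")

    instr_list = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(instr_list, "instrumentConfiguration", {"id": "IC1"})
    dp_list = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dp_list, "dataProcessing", {"id": "export"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "seedmsi"})
    _cv(pm, "MS", "MS:1000544", "Conversion to mzML")

    run = ET.SubElement(root, "run", {"defaultInstrumentConfigurationRef": "IC1", "id": "run1"})
    spec_list = ET.SubElement(
        run, "spectrumList",
        {"count": str(ds.n_pixels), "defaultDataProcessingRef": "export"},
    )
    pol_acc, pol_name = _CV_POLARITY[ds.polarity]
    for i in range(ds.n_pixels):
        mz_off, mz_len, mz_enc, in_off, in_len, in_enc = offsets[i]
        spectrum_el = ET.SubElement(
            spec_list, "spectrum",
            {"id": f"spectrum={i + 1}", "index": str(i), "defaultArrayLength": str(in_len)},
        )
        _cv(spectrum_el, "MS", "MS:1000579", "MS1 spectrum")
        _cv(spectrum_el, "MS", pol_acc, pol_name)
        scan_list = ET.SubElement(spectrum_el, "scanList", {"count": "1"})
        _cv(scan_list, "MS", "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "IMS", "IMS:1000050", "position x", str(int(ds.coords[i, 0])))
        _cv(scan, "IMS", "IMS:1000051", "position y", str(int(ds.coords[i, 1])))
        bda_list = ET.SubElement(spectrum_el, "binaryDataArrayList", {"count": "2"})
        for group, off, length, enc in (
            ("mzArray", mz_off, mz_len, mz_enc),
            ("intensityArray", in_off, in_len, in_enc),
        ):
            bda = ET.SubElement(bda_list, "binaryDataArray", {"encodedLength": "0"})
            ET.SubElement(bda, "referenceableParamGroupRef", {"ref": group})
            _cv(bda, "IMS", "IMS:1000103", "external array length", str(length))
            _cv(bda, "IMS", "IMS:1000102", "external offset", str(off))
            _cv(bda, "IMS", "IMS:1000104", "external encoded length", str(enc))
            ET.SubElement(bda, "binary")

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)
    return path, ibd_path


def _resample_to_axis(dataset: MSIDataset, axis: np.ndarray) -> MSIDataset:
    """Accumulate processed-mode spectra into the nearest channel of ``axis``."""
    if axis.ndim != 1 or axis.size == 0 or not np.all(np.diff(axis) > 0):
        raise ValueError("resampling axis must be 1-D and strictly ascending")
    matrix = np.zeros((dataset.n_pixels, axis.size), dtype=np.float32)
    for i, spec in enumerate(dataset.spectra):
        idx = np.searchsorted(axis, spec.mz)
        idx = np.clip(idx, 0, axis.size - 1)
        left = np.clip(idx - 1, 0, axis.size - 1)
        use_left = np.abs(spec.mz - axis[left]) < np.abs(spec.mz - axis[idx])
        nearest = np.where(use_left, left, idx)
        np.add.at(matrix[i], nearest, spec.intensity)
    return MSIDataset(
        coords=dataset.coords,
        polarity=dataset.polarity,
        pixel_size_um=dataset.pixel_size_um,
        mz_range=dataset.mz_range,
        mode="continuous",
        mz_axis=axis,
        intensities=matrix,
    )


# --------------------------------------------------------------------------
# imzML reading
# --------------------------------------------------------------------------


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict[str, str]:
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def read_imzml(path: str | Path, strict_checksum: bool = False) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    UUID/SHA-1 mismatches between the XML and the binary container warn by
    default; pass ``strict_checksum=True`` to fail instead.  Spectra with an
    unsorted m/z axis are repaired by sorting (with a warning).
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise FileNotFoundError(f"companion ibd file missing: {ibd_path}")
    tree = ET.parse(path)
    root = tree.getroot()

    mode = "processed"
    declared_uuid = None
    declared_sha1 = None
    pixel_size = 50.0
    for element in root.iter():
        if _local(element.tag) == "fileContent":
            params = _cv_params(element)
            if "IMS:1000030" in params:
                mode = "continuous"
            declared_uuid = params.get("IMS:1000080")
            declared_sha1 = params.get("IMS:1000091")
        elif _local(element.tag) == "scanSettings":
            params = _cv_params(element)
            if "IMS:1000046" in params:
                pixel_size = float(params["IMS:1000046"])

    ibd = ibd_path.read_bytes()
    if declared_uuid:
        file_uuid = str(uuid_module.UUID(bytes=ibd[:16]))
        if file_uuid != declared_uuid.strip("{}").lower():
            message = f"ibd UUID {file_uuid} does not match imzML declaration {declared_uuid}"
            if strict_checksum:
                raise ValueError(message)
            warnings.warn(message)
    if declared_sha1:
        actual = hashlib.sha1(ibd).hexdigest()
        if actual != declared_sha1.lower():
            message = "ibd SHA-1 checksum mismatch"
            if strict_checksum:
                raise ValueError(message)
            warnings.warn(message)

    coords = []
    spectra = []
    polarity = None
    for spectrum_el in root.iter():
        if _local(spectrum_el.tag) != "spectrum":
            continue
        params = _cv_params(spectrum_el)
        if "MS:1000130" in params:
            polarity = polarity or "positive"
        elif "MS:1000129" in params:
            polarity = polarity or "negative"
        x = y = None
        arrays = {}
        for element in spectrum_el.iter():
            tag = _local(element.tag)
            if tag == "scan":
                scan_params = _cv_params(element)
                if "IMS:1000050" in scan_params:
                    x = int(scan_params["IMS:1000050"])
                if "IMS:1000051" in scan_params:
                    y = int(scan_params["IMS:1000051"])
            elif tag == "binaryDataArray":
                group = None
                for child in element:
                    if _local(child.tag) == "referenceableParamGroupRef":
                        group = child.get("ref")
                array_params = _cv_params(element)
                offset = int(array_params["IMS:1000102"])
                length = int(array_params["IMS:1000103"])
                dtype = np.float64 if group == "mzArray" else np.float32
                arrays[group] = np.frombuffer(
                    ibd, dtype=dtype, count=length, offset=offset
                ).copy()
        if x is None or y is None:
            raise ValueError(f"spectrum {spectrum_el.get('id')} lacks pixel coordinates")
        mz = arrays.get("mzArray")
        intensity = arrays.get("intensityArray")
        if mz is None or intensity is None:
            raise ValueError(f"spectrum {spectrum_el.get('id')} lacks binary arrays")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            warnings.warn("unsorted m/z axis repaired by sorting")
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        coords.append((x, y))
        spectra.append(Spectrum(mz, intensity))

    if not spectra:
        raise ValueError(f"empty dataset: {path} contains no spectra")
    if polarity is None:
        raise ValueError(f"{path} declares no scan polarity")

    coords_arr = np.asarray(coords, dtype=np.int64)
    all_mz = np.concatenate([s.mz for s in spectra]) if spectra else np.array([])
    mz_range = (float(all_mz.min()), float(all_mz.max())) if all_mz.size else (0.0, 0.0)

    if mode == "continuous":
        axis = spectra[0].mz
        matrix = np.vstack([s.intensity for s in spectra]).astype(np.float32)
        return MSIDataset(
            coords=coords_arr,
            polarity=polarity,
            pixel_size_um=pixel_size,
            mz_range=mz_range,
            mode="continuous",
            mz_axis=axis,
            intensities=matrix,
        )
    return MSIDataset(
        coords=coords_arr,
        polarity=polarity,
        pixel_size_um=pixel_size,
        mz_range=mz_range,
        mode="processed",
        spectra=spectra,
    )
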