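"""Reading and writing VMI series: DICOM in, array containers in/out.

Everything is normalized to floating HU on load (DICOM stored values
times rescale slope plus intercept).  The array container is a
self-describing ``.npz`` file holding pixels, energies, spacing and a
format version; it is the lossless interchange format used by the CLI
and the test suite.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import CTImage, VMISeries

__all__ = [
    "read_dicom_series",
    "write_dicom",
    "read_array_container",
    "write_array_container",
    "CONTAINER_VERSION",
]

CONTAINER_VERSION = 1

#: rule: a callable(dataset, path) -> float, a DICOM keyword, or a
#: filename regex with one capture group holding the energy in keV
EnergyRule = Callable[[Dataset, Path], float] | str


def _energy_from(rule: EnergyRule, ds: Dataset, path: Path) -> float:
    if callable(rule):
        return float(rule(ds, path))
    if "(" in rule:  # filename regex with a capture group
        m = re.search(rule, path.name)
        if m is None:
            raise ValueError(f"energy regex {rule!r} does not match {path.name!r}")
        return float(m.group(1))
    if not hasattr(ds, rule):
        raise ValueError(f"DICOM attribute {rule!r} missing in {path.name!r}")
    return float(getattr(ds, rule))


def read_dicom_series(
    directory: str | Path, energy_rule: EnergyRule = r"(\d+)\s*keV"
) -> VMISeries:
    """Read single-frame CT DICOM slices as a VMI series sorted by energy.

    ``energy_rule`` extracts the per-slice monochromatic energy: vendors
    encode it inconsistently, so it may be a DICOM keyword, a filename
    regex with one capture group, or a callable.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not paths:
        paths = sorted(p for p in directory.iterdir() if p.is_file())
    if not paths:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    entries = []
    shape = None
    for path in paths:
        ds = pydicom.dcmread(path)
        for attr in ("RescaleSlope", "RescaleIntercept"):
            if not hasattr(ds, attr):
                raise ValueError(f"{path.name}: missing {attr}")
        raw = ds.pixel_array.astype(np.float64)
        if shape is None:
            shape = raw.shape
        elif raw.shape != shape:
            raise ValueError(
                f"{path.name}: shape {raw.shape} differs from {shape}"
            )
        hu = raw * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        try:
            energy = _energy_from(energy_rule, ds, path)
        except ValueError as err:
            raise ValueError(f"cannot determine energy: {err}") from err
        spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", (1.0, 1.0)))
        entries.append(CTImage(hu, spacing, energy, provenance=f"dicom:{path.name}"))
    entries.sort(key=lambda im: im.energy_kev)
    return VMISeries(entries)


def write_dicom(
    img: CTImage, path: str | Path, template: str | Path | None = None
) -> Path:
    """Write one slice as CT DICOM (int16 storage, slope 1/intercept -1024).

    With ``template``, geometry and patient tags are copied from an
    existing slice; otherwise a minimal secondary-capture-style header
    is created.
    """
    path = Path(path)
    if template is not None:
        ds = pydicom.dcmread(template)
    else:
        meta = pydicom.dataset.FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.Modality = "CT"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [img.spacing[0], img.spacing[1]]
    ds.SOPInstanceUID = generate_uid()
    ds.Rows, ds.Columns = img.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    stored = np.round(img.pixels + 1024.0).astype(np.int16)
    ds.PixelData = stored.tobytes()
    if img.energy_kev is not None:
        ds.ImageComments = f"{img.energy_kev:g} keV"
    ds.save_as(path, enforce_file_format=True)
    return path


def write_array_container(obj: VMISeries | CTImage, path: str | Path) -> Path:
    """Lossless round-trip container for a series or single image."""
    path = Path(path)
    if isinstance(obj, VMISeries):
        np.savez(
            path,
            format_version=CONTAINER_VERSION,
            kind="series",
            pixels=np.stack([im.pixels for im in obj]),
            energies_kev=obj.energies_kev,
            spacing=np.asarray(obj.spacing),
            provenance=np.asarray([im.provenance for im in obj]),
        )
    elif isinstance(obj, CTImage):
        np.savez(
            path,
            format_version=CONTAINER_VERSION,
            kind="image",
            pixels=obj.pixels,
            energies_kev=np.asarray(
                [] if obj.energy_kev is None else [obj.energy_kev]
            ),
            spacing=np.asarray(obj.spacing),
            provenance=np.asarray([obj.provenance]),
        )
    else:
        raise TypeError(f"cannot store {type(obj).__name__}")
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_array_container(path: str | Path) -> VMISeries | CTImage:
    """Read back a container written by :func:`write_array_container`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            version = int(z["format_version"])
            if version != CONTAINER_VERSION:
                raise ValueError(
                    f"container version {version} != supported {CONTAINER_VERSION}"
                )
            kind = str(z["kind"])
            pixels = z["pixels"]
            energies = z["energies_kev"]
            spacing = tuple(z["spacing"])
            provenance = [str(s) for s in z["provenance"]]
    except (KeyError, OSError, ValueError) as err:
        if isinstance(err, ValueError) and "container version" in str(err):
            raise
        raise ValueError(f"corrupt or foreign container {path}: {err}") from err
    if kind == "series":
        return VMISeries(
            [
                CTImage(pixels[i], spacing, energies[i], provenance[i])
                for i in range(pixels.shape[0])
            ]
        )
    if kind == "image":
        e = float(energies[0]) if energies.size else None
        return CTImage(pixels, spacing, e, provenance[0])
    raise ValueError(f"unknown container kind {kind!r}")
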