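"""Volume I/O (NRRD / MetaImage / DICOM CT series) and run configuration.

All raster I/O goes through SimpleITK.  Arrays follow this package's
``(z, y, x)`` convention, which matches SimpleITK's ``GetArrayFromImage``;
spacing and origin are carried in millimetres.  NRRD/MetaImage round trips
are bit-exact for the voxel payload; provenance (stage, seed, config hash)
is stored in the image metadata dictionary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .volumes import Volume

_RASTER_SUFFIXES = {".nrrd", ".nhdr", ".mha", ".mhd"}


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NRRD or MetaImage (by extension), with provenance."""
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise ValueError(f"unsupported output format {path.suffix!r}; "
                         f"use one of {sorted(_RASTER_SUFFIXES)}")
    img = sitk.GetImageFromArray(np.asarray(volume.values))
    img.SetSpacing(tuple(float(s) for s in volume.spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in volume.origin[::-1]))
    img.SetMetaData("marct_kind", volume.kind)
    for key, value in volume.meta.items():
        img.SetMetaData(f"marct_{key}", str(value))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def read_volume(path: str | Path) -> Volume:
    """Read NRRD, MetaImage, or a DICOM CT series directory.

    DICOM rescale slope/intercept are applied, producing HU.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix.lower() == ".dcm":
        img = sitk.ReadImage(str(path))
    elif path.suffix.lower() in _RASTER_SUFFIXES:
        img = sitk.ReadImage(str(path))
    else:
        raise ValueError(f"unknown volume format {path.suffix!r}")
    return _to_volume(img)


def _to_volume(img: sitk.Image) -> Volume:
    values = sitk.GetArrayFromImage(img)
    if values.ndim == 2:
        values = values[None]
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    if len(spacing) == 2:
        spacing = (1.0,) + spacing
        origin = (0.0,) + origin
    meta = {}
    kind = "HU"
    for key in img.GetMetaDataKeys():
        if key == "marct_kind":
            kind = img.GetMetaData(key)
        elif key.startswith("marct_"):
            meta[key[len("marct_"):]] = img.GetMetaData(key)
    return Volume(values, spacing, origin, kind=kind, meta=meta)


def _read_dicom_series(directory: Path) -> Volume:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found under {directory}")
    orientations = set()
    for f in files:
        fr = sitk.ImageFileReader()
        fr.SetFileName(f)
        fr.ReadImageInformation()
        if fr.HasMetaDataKey("0020|0037"):
            orientations.add(fr.GetMetaData("0020|0037").strip())
    if len(orientations) > 1:
        raise ValueError(
            f"mixed slice orientations in DICOM series: {sorted(orientations)}")
    reader.SetFileNames(files)
    return _to_volume(reader.Execute())  # rescale applied by the reader


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Study configuration: geometry, physics, MAR and planning parameters.

    The defaults are the desk-scale study conditions: 128x128 in-plane at
    3 mm, 3 slices of 2.5 mm, 180 views over 180 degrees, 2e6 photons/bin.
    """

    configurations: tuple[int, ...] = (1, 2)   # 1 = titanium, 2 = Cerrobend
    ptvs: tuple[str, ...] = ("PTV1", "PTV2", "PTV3")
    n_xy: int = 128
    spacing_mm: float = 3.0
    n_slices: int = 3
    slice_thickness_mm: float = 2.5
    n_views: int = 180
    n0: float = 2.0e6
    prescription_gy: float = 10.0
    beam_energy_mev: float = 2.0
    beamlet_width_mm: float = 5.0
    engine: str = "primary"
    histories: int = 200_000
    master_seed: int = 0
    mar: dict = field(default_factory=dict)    # MarConfig overrides
    output_dir: str | None = None

    def scientific_dict(self) -> dict:
        """Parameters that define the computation (output location excluded)."""
        data = asdict(self)
        data.pop("output_dir", None)
        return data

    def config_hash(self) -> str:
        payload = json.dumps(self.scientific_dict(), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"known keys: {sorted(known)}")
        for key in ("configurations", "ptvs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["configurations"] = list(data["configurations"])
        data["ptvs"] = list(data["ptvs"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
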