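"""Reading and writing of on-disk artifacts.

Vendor viewers export each en-face OCTA slab (SVP, ICP, DCP, CC, choroid)
and the co-registered infrared (IR) image as PNG files; lesion and FAZ
segmentations drawn on the IR image arrive as ITK-Snap-style integer label
maps (NIfTI or PNG).  This module loads those artifacts into plain in-memory
containers (:class:`SlabImage`, :class:`LabelMask`), converts images to
NIfTI-1 for archival/QC, and writes the pipeline's tabular results as CSV.

No resampling or registration is ever performed: all images belonging to one
eye must already share pixel dimensions, and co-registration checks compare
shapes only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

logger = logging.getLogger("octavad")

#: Recognized layer names: the five OCTA slabs, the IR reflectance channel,
#: and the two en-face OCT reconstruction levels.
LAYERS = ("SVP", "ICP", "DCP", "CC", "CHOROID", "IR", "EZ", "OPL")

#: The five slabs quantified for vessel area density.
VAD_LAYERS = ("SVP", "ICP", "DCP", "CC", "CHOROID")

#: Default ITK-Snap label convention: first label (red) = lesion,
#: second (green) = FAZ.
DEFAULT_LABEL_MEANING: Mapping[int, str] = {0: "background", 1: "AMN", 2: "FAZ"}


class FormatError(ValueError):
    """Malformed or unsupported image/label content."""


class CoRegistrationError(ValueError):
    """Images of one eye do not share dimensions."""


@dataclass(frozen=True)
class SlabImage:
    """One 2-D grayscale en-face image of one eye.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities in [0, 255].
    layer
        One of :data:`LAYERS`.
    eye_id
        Opaque identifier; all images of one eye share it.
    pixel_pitch_um
        Optional physical pixel pitch in microns per pixel.
    """

    pixels: np.ndarray
    layer: str
    eye_id: str
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError(f"slab image must be 2-D and non-empty, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(np.isfinite(px)):
                raise FormatError("slab image contains non-finite intensities")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("slab intensities must lie in [0, 255]")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px.astype(np.uint8)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMask:
    """Integer label map co-registered with an eye's IR image."""

    labels: np.ndarray
    label_meaning: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MEANING)
    )

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise FormatError(f"label map must be 2-D and non-empty, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, np.round(lab)):
                raise FormatError("label map contains non-integer values")
            lab = lab.astype(np.int32)
        object.__setattr__(self, "labels", np.ascontiguousarray(lab.astype(np.int32)))
        known = set(self.label_meaning)
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - known)
        if unknown:
            logger.warning("label map contains unexpected labels %s; ignored", unknown)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def _value_of(self, name: str) -> int:
        for value, meaning in self.label_meaning.items():
            if meaning == name:
                return int(value)
        raise KeyError(f"label meaning {name!r} not configured")

    def mask_of(self, name: str) -> np.ndarray:
        """Binary mask of the region whose meaning is ``name`` (e.g. ``"AMN"``)."""
        return self.labels == self._value_of(name)

    def validate_against(self, slab: SlabImage) -> None:
        """Check co-registration (shape equality) with a slab of the same eye."""
        if self.shape != slab.shape:
            raise CoRegistrationError(
                f"label map shape {self.shape} != {slab.layer} slab shape {slab.shape}"
            )
        amn = self.mask_of("AMN")
        faz = self.mask_of("FAZ")
        if np.any(amn & faz):  # impossible for an integer map; kept for subclasses
            warnings.warn("AMN and FAZ masks overlap", stacklevel=2)


def load_slab_png(path: str | Path, layer: str, eye_id: str,
                  pixel_pitch_um: float | None = None) -> SlabImage:
    """Load one exported PNG slab as a grayscale :class:`SlabImage`.

    RGB/RGBA inputs are converted with the Rec. 601 luminance transform
    (L = 0.299 R + 0.587 G + 0.114 B, rounded); the alpha channel is
    discarded.  8- and 16-bit grayscale PNGs load directly (16-bit is
    rescaled to [0, 255]).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.size[0] == 0 or im.size[1] == 0:
                raise FormatError(f"zero-sized image: {path}")
            if im.mode in ("RGB", "RGBA", "P", "LA"):
                im = im.convert("L")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except (FormatError, OSError):
        raise
    except Exception as exc:  # undecodable content
        raise OSError(f"cannot decode PNG {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) * (255.0 / 65535.0)).round().astype(np.uint8)
    return SlabImage(pixels=arr, layer=layer, eye_id=eye_id, pixel_pitch_um=pixel_pitch_um)


def to_nifti(image: SlabImage | LabelMask | np.ndarray, path: str | Path) -> Path:
    """Write an image or label map as a lossless integer NIfTI-1 file.

    The 2-D array is stored with an identity affine; a round-trip through
    :func:`_read_nifti_array` reproduces the array exactly.
    """
    path = Path(path)
    if isinstance(image, SlabImage):
        arr = image.pixels.astype(np.uint8)
    elif isinstance(image, LabelMask):
        arr = image.labels.astype(np.int16)
    else:
        arr = np.asarray(image)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("only integer arrays are written to NIfTI")
    nii = nib.Nifti1Image(np.ascontiguousarray(arr.T), affine=np.eye(4))
    nib.save(nii, str(path))
    return path


def _read_nifti_array(path: str | Path) -> np.ndarray:
    """Read back a 2-D array written by :func:`to_nifti` (row-major view)."""
    nii = nib.load(str(path))
    arr = np.asanyarray(nii.dataobj)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D NIfTI, got shape {arr.shape}")
    return np.ascontiguousarray(arr.T)


def load_label_mask(path: str | Path,
                    label_meaning: Mapping[int, str] | None = None) -> LabelMask:
    """Load an ITK-Snap-style label map from NIfTI (``.nii``/``.nii.gz``) or PNG."""
    path = Path(path)
    if path.suffix == ".png":
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("L", "I", "I;16", "P"):
                raise FormatError(f"label PNG must be single-channel integer, got mode {im.mode}")
            if im.mode == "P":
                im = im.convert("L")
            arr = np.asarray(im)
    else:
        arr = _read_nifti_array(path)
    if not np.issubdtype(np.asarray(arr).dtype, np.integer):
        if not np.array_equal(arr, np.round(arr)):
            raise FormatError(f"label map {path} holds non-integer data")
        arr = np.asarray(arr).astype(np.int32)
    return LabelMask(labels=arr,
                     label_meaning=dict(label_meaning or DEFAULT_LABEL_MEANING))


# --- tabular results -------------------------------------------------------

#: Sort keys per record kind, used for deterministic row order.
_SORT_KEYS = {
    "VADRecord": ["eye_id", "layer", "region"],
    "DiceRecord": ["eye_id", "pair"],
    "CohortResult": ["layer", "comparator"],
}


def write_results_table(records: Sequence, path: str | Path, kind: type | None = None) -> Path:
    """Write a homogeneous collection of result records as a CSV table.

    One row per record, columns in dataclass field order, rows sorted by the
    record kind's natural key.  Floats are written with 17 significant
    digits so a reload reproduces them exactly.  ``kind`` (a record
    dataclass) is only needed to emit a header-only table for an empty
    collection.
    """
    path = Path(path)
    kinds = {type(r).__name__ for r in records}
    if len(kinds) > 1:
        raise TypeError(f"mixed record kinds in one table: {sorted(kinds)}")
    if not records:
        if kind is None:
            raise TypeError("kind= is required to write a header for zero records")
        cols = [f.name for f in fields(kind)]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path
    kind_name = kinds.pop()
    if kind is not None and kind.__name__ != kind_name:
        raise TypeError(f"records are {kind_name}, not {kind.__name__}")
    kind = type(records[0])
    cols = [f.name for f in fields(records[0])]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    sort_by = [k for k in _SORT_KEYS.get(kind.__name__, []) if k in df.columns]
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Load a results CSV written by :func:`write_results_table`."""
    return pd.read_csv(path)


# --- per-eye manifests -----------------------------------------------------

def load_manifest(path: str | Path) -> dict:
    """Load a per-eye YAML manifest.

    Schema::

        eye_id: <str>
        pixel_pitch_um: <float, optional>
        labels: <path to label map>
        slabs:
          SVP: <path>
          ICP: <path>
          ...

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "slabs" not in data or "eye_id" not in data:
        raise FormatError(f"manifest {path} must map 'eye_id' and 'slabs'")
    base = path.parent
    data["slabs"] = {k: str((base / v)) for k, v in data["slabs"].items()}
    if "labels" in data and data["labels"] is not None:
        data["labels"] = str(base / data["labels"])
    return data


def load_eye(manifest_path: str | Path) -> tuple[dict[str, SlabImage], LabelMask | None]:
    """Load all slabs (and the label map, if present) named in a manifest."""
    man = load_manifest(manifest_path)
    pitch = man.get("pixel_pitch_um")
    slabs = {
        layer: load_slab_png(p, layer=layer, eye_id=str(man["eye_id"]), pixel_pitch_um=pitch)
        for layer, p in man["slabs"].items()
    }
    shapes = {s.shape for s in slabs.values()}
    if len(shapes) > 1:
        raise CoRegistrationError(f"slabs of eye {man['eye_id']} differ in shape: {shapes}")
    labels = load_label_mask(man["labels"]) if man.get("labels") else None
    if labels is not None and slabs:
        labels.validate_against(next(iter(slabs.values())))
    return slabs, labels
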