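"""Intra-eye comparator regions for lesion perfusion analysis.

Two control regions are derived from the human segmentations of the lesion
(AMN) and the foveal avascular zone (FAZ), both drawn on the IR image:

* **ATC** (adjacent tissue control): the lesion footprint scaled by a linear
  factor (default 2) about the lesion centroid, minus the lesion itself and
  minus any FAZ pixels — the band of tissue directly adjacent to the lesion.
* **RS** (ring segment): the closed annulus centered on the fovea whose
  inner and outer circles are tangent to the lesion (radii = min and max
  Euclidean distance from the fovea center to lesion pixel centers), minus
  the lesion.  The fovea center is the FAZ-mask centroid.

All geometry uses 0-based row/column pixel-center coordinates.  Regions are
clipped to the image frame; clipped pixel counts are logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import to_nifti

logger = logging.getLogger("octavad")


class DegenerateRegionError(ValueError):
    """A constructed control region is empty; carries diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message + (f" (diagnostics: {diagnostics})" if diagnostics else ""))
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class RegionSet:
    """Binary masks of the lesion, FAZ and derived control regions of one eye."""

    amn: np.ndarray
    faz: np.ndarray
    atc: np.ndarray
    rs: np.ndarray
    fovea_center: tuple[float, float]
    atc_scale: float = 2.0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.amn, self.faz, self.atc, self.rs)}
        if len(shapes) != 1:
            raise ValueError(f"region masks differ in shape: {shapes}")
        if np.any(self.atc & self.amn):
            raise ValueError("ATC overlaps the lesion")
        if np.any(self.atc & self.faz):
            raise ValueError("ATC overlaps the FAZ")
        if np.any(self.rs & self.amn):
            raise ValueError("RS overlaps the lesion")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amn.shape  # type: ignore[return-value]

    def mask(self, region: str) -> np.ndarray:
        return {"AMN": self.amn, "FAZ": self.faz, "ATC": self.atc, "RS": self.rs}[region]

    def to_label_array(self) -> np.ndarray:
        """Multi-label QC map: background 0, AMN 1, FAZ 2, ATC 3, RS 4.

        Later labels never overwrite AMN/FAZ (regions exclude them by
        construction except RS∩FAZ, where FAZ wins for display).
        """
        out = np.zeros(self.shape, dtype=np.int16)
        out[self.rs] = 4
        out[self.atc] = 3
        out[self.faz] = 2
        out[self.amn] = 1
        return out

    def export_nifti(self, path) -> None:
        to_nifti(self.to_label_array(), path)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Mean of pixel-center coordinates of the true pixels."""
    rr, cc = np.nonzero(_as_bool(mask))
    if rr.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    return float(rr.mean()), float(cc.mean())


def fovea_center(faz_mask: np.ndarray) -> tuple[float, float]:
    """Fovea reference point: centroid of the FAZ segmentation."""
    try:
        return centroid(faz_mask)
    except ValueError:
        raise ValueError("no fovea reference: FAZ mask is empty") from None


def scaled_footprint(amn_mask: np.ndarray, scale: float) -> np.ndarray:
    """Lesion mask scaled by ``scale`` in both axes about the lesion centroid.

    Rasterized by inverse-mapping each candidate pixel center into lesion
    coordinates with nearest-neighbor lookup (halves round up), clipped to
    the image frame.
    """
    amn = _as_bool(amn_mask)
    if not amn.any():
        raise ValueError("lesion mask is empty")
    if scale <= 1:
        raise ValueError(f"scale must exceed 1, got {scale}")
    h, w = amn.shape
    cr, cc = centroid(amn)
    rr, cc_idx = np.nonzero(amn)
    # bounding box of the scaled footprint, padded one pixel for rounding
    r_lo = max(0, int(np.floor(cr + scale * (rr.min() - cr))) - 1)
    r_hi = min(h - 1, int(np.ceil(cr + scale * (rr.max() - cr))) + 1)
    c_lo = max(0, int(np.floor(cc + scale * (cc_idx.min() - cc))) - 1)
    c_hi = min(w - 1, int(np.ceil(cc + scale * (cc_idx.max() - cc))) + 1)
    rows = np.arange(r_lo, r_hi + 1)
    cols = np.arange(c_lo, c_hi + 1)
    R, C = np.meshgrid(rows, cols, indexing="ij")
    # inverse map into lesion coordinates; nearest neighbor with half-up ties
    src_r = np.floor(cr + (R - cr) / scale + 0.5).astype(np.int64)
    src_c = np.floor(cc + (C - cc) / scale + 0.5).astype(np.int64)
    inside = (src_r >= 0) & (src_r < h) & (src_c >= 0) & (src_c < w)
    hit = np.zeros_like(inside)
    hit[inside] = amn[src_r[inside], src_c[inside]]
    out = np.zeros((h, w), dtype=bool)
    out[R[hit], C[hit]] = True
    return out


def build_atc(amn_mask: np.ndarray, faz_mask: np.ndarray | None = None,
              scale: float = 2.0) -> np.ndarray:
    """Adjacent tissue control: scaled lesion footprint minus lesion and FAZ."""
    amn = _as_bool(amn_mask)
    foot = scaled_footprint(amn, scale)
    atc = foot & ~amn
    if faz_mask is not None:
        atc &= ~_as_bool(faz_mask)
    if not atc.any():
        raise DegenerateRegionError(
            "degenerate ATC: empty after exclusions",
            lesion_area=int(amn.sum()),
            scaled_area=int(foot.sum()),
            faz_overlap=int((foot & _as_bool(faz_mask)).sum()) if faz_mask is not None else 0,
        )
    return atc


def build_ring_segment(amn_mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Fovea-centered annulus tangent to the lesion, lesion excluded.

    The inner/outer radii are the min/max Euclidean distances from ``center``
    to lesion pixel centers; membership is tested at pixel centers, closed
    interval.  The FAZ is deliberately not excluded; report its overlap as a
    diagnostic if needed.
    """
    amn = _as_bool(amn_mask)
    if not amn.any():
        raise ValueError("lesion mask is empty")
    cr, cc = center
    if not (np.isfinite(cr) and np.isfinite(cc)):
        raise ValueError(f"ring center must be finite, got {center}")
    rr, ci = np.nonzero(amn)
    d_lesion = np.hypot(rr - cr, ci - cc)
    r_min, r_max = float(d_lesion.min()), float(d_lesion.max())
    if r_min == r_max:
        warnings.warn("single-radius lesion: ring segment degenerates to a thin annulus",
                      stacklevel=2)
    h, w = amn.shape
    R, C = np.ogrid[:h, :w]
    dist = np.hypot(R - cr, C - cc)
    rs = (dist >= r_min) & (dist <= r_max) & ~amn
    if not rs.any():
        raise DegenerateRegionError("degenerate RS: annulus fully covered by the lesion",
                                    r_min=r_min, r_max=r_max, lesion_area=int(amn.sum()))
    return rs


def build_region_set(amn_mask: np.ndarray, faz_mask: np.ndarray,
                     atc_scale: float = 2.0) -> RegionSet:
    """Construct the full :class:`RegionSet` from lesion and FAZ masks."""
    amn = _as_bool(amn_mask)
    faz = _as_bool(faz_mask)
    if amn.shape != faz.shape:
        raise ValueError(f"AMN shape {amn.shape} != FAZ shape {faz.shape}")
    if not amn.any():
        raise ValueError("empty lesion: eye is not analyzable")
    if np.any(amn & faz):
        warnings.warn("lesion overlaps the FAZ; expected the lesion to lie outside it",
                      stacklevel=2)
    center = fovea_center(faz)
    atc = build_atc(amn, faz, scale=atc_scale)
    rs = build_ring_segment(amn, center)
    rs_faz = int((rs & faz).sum())
    if rs_faz:
        logger.info("ring segment overlaps FAZ by %d px (kept, reported as diagnostic)", rs_faz)
    return RegionSet(amn=amn, faz=faz, atc=atc, rs=rs,
                     fovea_center=center, atc_scale=atc_scale)
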