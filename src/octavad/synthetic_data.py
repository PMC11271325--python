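"""Seeded synthetic OCTA phantoms.

Real en-face OCTA of a lesioned eye is, for this pipeline's purposes, a set
of co-registered textures: capillary-scale perfusion texture per retinal
plexus with an avascular zone at the fovea, fine granular choriocapillaris
flow, coarse lobular choroidal vasculature, bright large-vessel arcades in
the SVP, and an IR reflectance image on which the lesion appears
hyporeflective.  The phantom generator reproduces exactly this statistical
structure — not the biology: textures are thresholded band-pass noise with
a configured perfused-pixel fraction, optionally reduced inside the lesion
by a per-layer deficit, plus additive Gaussian (or multiplicative speckle)
noise.  Every output is deterministic given the seed, and the generator
records its own ground truth (true perfused fractions per region, the
large-vessel mask) so each analysis stage can be validated against it.

En-face OCT fixtures mirror the anatomy of Henle-fiber obliquity: the EZ
lesion footprint coincides with the IR lesion while the OPL footprint is
displaced away from the fovea (radially, or horizontally for a "nasal"
direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.morphology import disk

from .io_formats import VAD_LAYERS, LabelMask, SlabImage, to_nifti
from .regions import RegionSet, build_region_set, centroid

#: Per-layer intensity model: background level and perfused-pixel contrast.
BACKGROUND_LEVEL = 45.0
VESSEL_CONTRAST = 145.0
LARGE_VESSEL_LEVEL = 235.0
IR_BACKGROUND = 150.0
IR_LESION_LEVEL = 95.0

#: Reference frame size all default geometry is expressed at.
REFERENCE_FRAME = 512


class ConfigError(ValueError):
    """Inconsistent phantom configuration."""


@dataclass(frozen=True)
class LesionSpec:
    """Parafoveal lesion geometry.

    ``center`` is in (row, col) pixels; ``axes`` are the ellipse semi-axes.
    ``shape="blob"`` perturbs the ellipse radius with a smooth random
    Fourier series (star-shaped outline), emulating a ragged manual
    segmentation.
    """

    shape: str = "ellipse"
    center: tuple[float, float] | None = None
    axes: tuple[float, float] = (28.0, 22.0)
    angle_deg: float = 0.0
    blob_amplitude: float = 0.25


@dataclass(frozen=True)
class LayerTexture:
    """Perfusion texture of one slab: perfused fraction and feature scale."""

    base_vessel_fraction: float
    texture_scale_px: float

    def __post_init__(self) -> None:
        if not (0.0 < self.base_vessel_fraction < 1.0):
            raise ConfigError(f"base_vessel_fraction must be in (0,1), "
                              f"got {self.base_vessel_fraction}")


@dataclass(frozen=True)
class VesselArcs:
    """Large SVP vessel arcades: smooth quadratic arcs of fixed width.

    ``curvature`` sets how far the arc bows away from the fovea (the arc's
    midpoint sits at curvature/2 of the frame size from it).  The default
    keeps arcades peripheral to the macula, as in real en-face scans, where
    large vessels skirt rather than cross the parafovea.
    """

    count: int = 4
    width_px: float = 12.0
    curvature: float = 0.9


def _default_textures() -> dict[str, LayerTexture]:
    # Perfused fractions chosen so control-region VAD sits in the range
    # reported for healthy parafoveal tissue on this device class
    # (retina ~0.35-0.40; CC ~0.42 and choroid ~0.39, i.e. the levels that
    # a 27%/41% lesion deficit depresses to ~0.31/~0.23).
    return {
        "SVP": LayerTexture(0.40, 3.0),
        "ICP": LayerTexture(0.35, 2.5),
        "DCP": LayerTexture(0.35, 2.5),
        "CC": LayerTexture(0.42, 1.5),
        "CHOROID": LayerTexture(0.39, 8.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one phantom eye (and its en-face fixtures)."""

    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    fovea_center: tuple[float, float] | None = None
    faz_radius_px: float = 40.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    textures: Mapping[str, LayerTexture] = field(default_factory=_default_textures)
    lesion_deficit: Mapping[str, float] = field(default_factory=dict)
    svp_large_vessels: VesselArcs = field(default_factory=VesselArcs)
    noise_sd: float = 12.0
    speckle: bool = False
    opl_displacement_px: float = 12.0
    opl_direction: str = "radial"  # or "nasal" (fixed horizontal, +col)
    ez_displacement_px: float = 0.0
    atc_scale: float = 2.0

    def __post_init__(self) -> None:
        for layer, d in self.lesion_deficit.items():
            if layer not in VAD_LAYERS:
                raise ConfigError(f"deficit for unknown layer {layer!r}")
            if not (0.0 <= d <= 1.0):
                raise ConfigError(f"lesion_deficit[{layer}] must be in [0,1], got {d}")
        missing = [l for l in VAD_LAYERS if l not in self.textures]
        if missing:
            raise ConfigError(f"missing texture spec for layer(s) {missing}")

    @property
    def fovea(self) -> tuple[float, float]:
        if self.fovea_center is not None:
            return self.fovea_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


def default_config(seed: int = 0, shape: tuple[int, int] = (512, 512),
                   lesion_deficit: Mapping[str, float] | None = None,
                   **overrides) -> SyntheticConfig:
    """A study-condition phantom config with geometry scaled to ``shape``.

    All default geometry (FAZ radius, lesion size and eccentricity, vessel
    width) is defined at a 512 px frame and scaled linearly for smaller
    frames so that desk-scale phantoms keep the same layout.
    """
    s = shape[0] / REFERENCE_FRAME
    fovea = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    eccentricity = 95.0 * s
    lesion = LesionSpec(center=(fovea[0] - 0.45 * eccentricity,
                                fovea[1] + 0.9 * eccentricity),
                        axes=(28.0 * s, 22.0 * s))
    textures = {layer: LayerTexture(t.base_vessel_fraction,
                                    max(0.6, t.texture_scale_px * s))
                for layer, t in _default_textures().items()}
    cfg = SyntheticConfig(
        seed=seed, shape=shape, faz_radius_px=40.0 * s, lesion=lesion,
        textures=textures,
        svp_large_vessels=VesselArcs(width_px=max(3.0, 12.0 * s)),
        opl_displacement_px=12.0 * s,
        **overrides)
    if lesion_deficit:
        cfg = replace(cfg, lesion_deficit=dict(lesion_deficit))
    return cfg


# --- geometry --------------------------------------------------------------

def _faz_mask(config: SyntheticConfig) -> np.ndarray:
    h, w = config.shape
    fr, fc = config.fovea
    R, C = np.ogrid[:h, :w]
    return np.hypot(R - fr, C - fc) <= config.faz_radius_px


def _lesion_mask(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.lesion
    h, w = config.shape
    if spec.center is None:
        raise ConfigError("lesion center must be set (use default_config)")
    cr, cc = spec.center
    a, b = spec.axes
    R, C = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                       indexing="ij")
    th = math.radians(spec.angle_deg)
    u = (R - cr) * math.cos(th) + (C - cc) * math.sin(th)
    v = -(R - cr) * math.sin(th) + (C - cc) * math.cos(th)
    if spec.shape == "ellipse":
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.shape == "blob":
        # star-shaped outline: ellipse radius modulated by a low-order
        # random Fourier series
        phase = np.arctan2(v, u)
        mod = np.ones_like(phase)
        for k in (2, 3, 5):
            amp = spec.blob_amplitude * rng.uniform(0.2, 1.0) / k
            mod += amp * np.cos(k * phase + rng.uniform(0, 2 * np.pi))
        return (u / a) ** 2 + (v / b) ** 2 <= mod ** 2
    raise ConfigError(f"unknown lesion shape {spec.shape!r}")


def _vessel_arcs(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth large-vessel mask: quadratic Bezier arcs skirting the fovea."""
    h, w = config.shape
    spec = config.svp_large_vessels
    fr, fc = config.fovea
    mask = np.zeros((h, w), dtype=bool)
    t = np.linspace(0.0, 1.0, 4 * max(h, w))
    for _ in range(spec.count):
        # endpoints on opposite frame borders, control point pushed away
        # from the fovea to arc around it
        ang = rng.uniform(0, 2 * np.pi)
        p0 = np.array([fr, fc]) + 0.75 * max(h, w) * np.array([np.sin(ang), np.cos(ang)])
        p2 = np.array([fr, fc]) + 0.75 * max(h, w) * np.array([-np.sin(ang), -np.cos(ang)])
        perp = np.array([np.cos(ang), -np.sin(ang)])
        p1 = np.array([fr, fc]) + perp * spec.curvature * max(h, w) * rng.choice([-1.0, 1.0])
        pts = (np.outer((1 - t) ** 2, p0) + np.outer(2 * (1 - t) * t, p1)
               + np.outer(t ** 2, p2))
        ri = np.round(pts[:, 0]).astype(int)
        ci = np.round(pts[:, 1]).astype(int)
        keep = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        mask[ri[keep], ci[keep]] = True
    if mask.any() and spec.width_px > 1:
        mask = binary_dilation(mask, structure=disk(max(1, int(round(spec.width_px / 2)))))
    return mask


# --- textures --------------------------------------------------------------

def _perfusion_texture(shape: tuple[int, int], frac: float, scale_px: float,
                       deficit: float, lesion: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Binary perfusion map: band-pass noise thresholded at the target fraction.

    Outside the lesion the perfused fraction is ``frac``; inside it is
    ``frac * (1 - deficit)``, realized by a stricter threshold on the same
    smooth field (the deficit removes the weakest flow pixels first, as a
    perfusion dropout would).
    """
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=max(0.5, scale_px / 2.0))
    t_base = np.quantile(field_, 1.0 - frac)
    perfused = field_ > t_base
    if deficit > 0 and lesion.any():
        t_lesion = np.quantile(field_, 1.0 - frac * (1.0 - deficit))
        perfused[lesion] = field_[lesion] > t_lesion
    return perfused


def _render(perfused: np.ndarray, noise_sd: float, speckle: bool,
            rng: np.random.Generator, base: float = BACKGROUND_LEVEL,
            contrast: float = VESSEL_CONTRAST) -> np.ndarray:
    img = base + contrast * perfused.astype(np.float64)
    if speckle:
        img *= rng.normal(1.0, noise_sd / 128.0, img.shape)
    else:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# --- phantom assembly ------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, for validating the analysis."""

    base_fractions: dict[str, float]
    deficits: dict[str, float]
    region_fractions: dict[str, dict[str, float]]  # layer -> region -> true fraction
    large_vessel_mask: np.ndarray
    lesion_mask: np.ndarray
    faz_mask: np.ndarray


@dataclass(frozen=True)
class EyePhantom:
    """One synthetic eye: slabs + IR, label map, regions, and ground truth."""

    eye_id: str
    config: SyntheticConfig
    slabs: dict[str, SlabImage]
    label_mask: LabelMask
    regions: RegionSet
    truth: GroundTruth


def generate_eye(config: SyntheticConfig, eye_id: str | None = None) -> EyePhantom:
    """Generate one phantom eye deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    eye_id = eye_id or f"eye{config.seed}"
    faz = _faz_mask(config)
    lesion = _lesion_mask(config, rng)
    if not lesion.any():
        raise ConfigError("configured lesion rasterizes to an empty mask")
    if np.any(lesion & faz):
        raise ConfigError("configured lesion overlaps the FAZ")
    regions = build_region_set(lesion, faz, atc_scale=config.atc_scale)
    vessel_mask = _vessel_arcs(config, rng)

    slabs: dict[str, SlabImage] = {}
    region_fracs: dict[str, dict[str, float]] = {}
    for layer in VAD_LAYERS:
        tex = config.textures[layer]
        deficit = float(config.lesion_deficit.get(layer, 0.0))
        perfused = _perfusion_texture(config.shape, tex.base_vessel_fraction,
                                      tex.texture_scale_px, deficit, lesion, rng)
        if layer in ("SVP", "ICP", "DCP"):
            perfused &= ~faz  # retinal plexuses are avascular at the fovea
        img = _render(perfused, config.noise_sd, config.speckle, rng)
        if layer == "SVP":
            img = img.astype(np.float64)
            img[vessel_mask] = LARGE_VESSEL_LEVEL
            img = np.clip(np.round(img + (rng.normal(0.0, config.noise_sd,
                                                     img.shape) * vessel_mask)),
                          0, 255).astype(np.uint8)
        slabs[layer] = SlabImage(pixels=img, layer=layer, eye_id=eye_id)
        region_fracs[layer] = {
            name: float(perfused[regions.mask(name)].mean())
            for name in ("AMN", "ATC", "RS")
        }

    ir = np.full(config.shape, IR_BACKGROUND)
    ir[lesion] = IR_LESION_LEVEL
    ir = np.clip(np.round(ir + rng.normal(0.0, config.noise_sd / 2.0, config.shape)),
                 0, 255).astype(np.uint8)
    slabs["IR"] = SlabImage(pixels=ir, layer="IR", eye_id=eye_id)

    labels = np.zeros(config.shape, dtype=np.int16)
    labels[faz] = 2
    labels[lesion] = 1  # disjoint by construction
    truth = GroundTruth(
        base_fractions={l: config.textures[l].base_vessel_fraction for l in VAD_LAYERS},
        deficits={l: float(config.lesion_deficit.get(l, 0.0)) for l in VAD_LAYERS},
        region_fractions=region_fracs,
        large_vessel_mask=vessel_mask, lesion_mask=lesion, faz_mask=faz)
    return EyePhantom(eye_id=eye_id, config=config, slabs=slabs,
                      label_mask=LabelMask(labels=labels), regions=regions, truth=truth)


# --- en-face fixtures ------------------------------------------------------

def circle_overlap_dice(radius: float, offset: float) -> float:
    """Closed-form Dice of two equal disks of ``radius`` at center ``offset``.

    The intersection is a lens of area
    2 r^2 cos^-1(d / 2r) - (d/2) sqrt(4 r^2 - d^2); Dice = lens / (pi r^2).
    """
    if offset >= 2 * radius:
        return 0.0
    lens = (2 * radius ** 2 * math.acos(offset / (2 * radius))
            - (offset / 2.0) * math.sqrt(4 * radius ** 2 - offset ** 2))
    return lens / (math.pi * radius ** 2)


def displacement_for_dice(radius: float, target_dice: float) -> float:
    """Disk-center offset giving a target Dice for equal disks (bisection)."""
    if not (0.0 < target_dice < 1.0):
        raise ValueError("target_dice must be in (0,1)")
    lo, hi = 0.0, 2.0 * radius
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if circle_overlap_dice(radius, mid) > target_dice:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _shift_mask(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    dr, dc = offset
    rr, cc = np.nonzero(mask)
    nr, nc = rr + dr, cc + dc
    h, w = mask.shape
    if nr.min() < 0 or nr.max() >= h or nc.min() < 0 or nc.max() >= w:
        raise ConfigError("displacement pushes the en-face footprint out of frame")
    out = np.zeros_like(mask)
    out[nr, nc] = True
    return out


def _displacement_vector(config: SyntheticConfig, lesion: np.ndarray,
                         magnitude: float) -> tuple[int, int]:
    if magnitude == 0:
        return (0, 0)
    if config.opl_direction == "nasal":
        direction = np.array([0.0, 1.0])
    elif config.opl_direction == "radial":
        lc = np.array(centroid(lesion))
        fv = np.array(config.fovea)
        vec = lc - fv
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ConfigError("lesion centroid coincides with the fovea; "
                              "radial direction undefined")
        direction = vec / norm
    else:
        raise ConfigError(f"unknown opl_direction {config.opl_direction!r}")
    dr, dc = np.floor(direction * magnitude + 0.5).astype(int)
    return int(dr), int(dc)


def generate_enface(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """En-face lesion footprints (IR, EZ, OPL) for one phantom eye.

    The IR footprint is the lesion mask; the EZ footprint coincides with it
    (up to an optional ``ez_displacement_px`` emulating segmentation
    disagreement); the OPL footprint is displaced by
    ``opl_displacement_px`` away from the fovea (Henle-fiber obliquity).
    """
    rng = np.random.default_rng(config.seed)
    ir = _lesion_mask(config, rng)
    if not ir.any():
        raise ConfigError("configured lesion rasterizes to an empty mask")
    ez = _shift_mask(ir, _displacement_vector(config, ir, config.ez_displacement_px))
    opl = _shift_mask(ir, _displacement_vector(config, ir, config.opl_displacement_px))
    return ir, ez, opl


# --- cohorts ---------------------------------------------------------------

def generate_cohort(n_eyes: int = 6, seed: int = 0,
                    shape: tuple[int, int] = (512, 512),
                    lesion_deficit: Mapping[str, float] | None = None,
                    jitter: float = 0.15,
                    base_config: SyntheticConfig | None = None) -> list[EyePhantom]:
    """Generate ``n_eyes`` independent phantom eyes with jittered geometry.

    Each eye gets its own child seed; lesion size, eccentricity and
    orientation are jittered by a relative ``jitter`` so the cohort carries
    realistic between-eye variability.
    """
    if n_eyes < 2:
        raise ConfigError(f"a cohort needs at least 2 eyes, got {n_eyes}")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_eyes)]
    jrng = np.random.default_rng(ss.spawn(1)[0])
    eyes = []
    for i, child in enumerate(child_seeds):
        cfg = base_config or default_config(seed=child, shape=shape,
                                            lesion_deficit=lesion_deficit)
        s = shape[0] / REFERENCE_FRAME
        fovea = cfg.fovea
        ecc = 95.0 * s * (1.0 + jitter * jrng.uniform(-1, 1))
        ang = jrng.uniform(0, 2 * np.pi)
        # keep the lesion parafoveal, clear of both the FAZ and the frame
        ecc = max(ecc, cfg.faz_radius_px + 1.25 * max(cfg.lesion.axes))
        center = (fovea[0] + ecc * math.sin(ang), fovea[1] + ecc * math.cos(ang))
        axes = tuple(a * (1.0 + jitter * jrng.uniform(-1, 1)) for a in cfg.lesion.axes)
        lesion = replace(cfg.lesion, center=center, axes=axes,
                         angle_deg=float(jrng.uniform(0, 180)))
        cfg = replace(cfg, seed=child, lesion=lesion)
        eyes.append(generate_eye(cfg, eye_id=f"eye{i:02d}"))
    return eyes


# --- on-disk export (CLI backend) ------------------------------------------

def write_eye(phantom: EyePhantom, out_dir: str | Path) -> Path:
    """Write one phantom eye as PNG slabs + NIfTI labels + YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slab_paths = {}
    for layer, slab in phantom.slabs.items():
        p = out_dir / f"{phantom.eye_id}_{layer}.png"
        Image.fromarray(slab.pixels, mode="L").save(p)
        slab_paths[layer] = p.name
    labels_path = out_dir / f"{phantom.eye_id}_labels.nii.gz"
    to_nifti(phantom.label_mask, labels_path)
    manifest = {
        "eye_id": phantom.eye_id,
        "labels": labels_path.name,
        "slabs": slab_paths,
    }
    man_path = out_dir / f"{phantom.eye_id}_manifest.yaml"
    man_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return man_path


def write_enface(config: SyntheticConfig, eye_id: str, out_dir: str | Path) -> dict[str, Path]:
    """Write the IR/EZ/OPL en-face lesion masks of one eye as PNG files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ir, ez, opl = generate_enface(config)
    paths = {}
    for name, mask in (("IR", ir), ("EZ", ez), ("OPL", opl)):
        p = out_dir / f"{eye_id}_enface_{name}.png"
        Image.fromarray((mask.astype(np.uint8)), mode="L").save(p)
        paths[name] = p
    return paths
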