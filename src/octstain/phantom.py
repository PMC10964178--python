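"""Synthetic coronary phantoms: unpaired OCT-like and H&E-like image pairs.

Clinical OCT/histology archives of coronary arteries are rarely shareable,
so this module fabricates specimens with known ground truth.  Each phantom
is a locally planar three-layer tissue slab (intima, media, adventitia
under a lumen/background region) rendered twice:

* **OCT domain** — per-layer mean reflectivity, exponential depth
  attenuation from the tissue surface, and multiplicative gamma speckle
  (unit mean, shape ``1/contrast**2``), the first-order statistics of OCT
  speckle.
* **H&E domain** — per-layer pink/purple palette colours with Gaussian
  pixel noise.

Pathology is modelled as elliptical inclusions: lipid pools render as
near-white holes in H&E and diffuse low-signal voids in OCT; calcifications
render as dark-purple sharp-bordered regions in H&E and low-signal regions
with a bright specular rim in OCT.  Every sample carries the exact geometry
used to draw it, so labels and masks can be re-derived independently.

The planar (rather than annular) geometry matches the statistics of small
training patches cropped from B-scans, which are locally laminar; no vessel
lumen curvature is modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .staining import read_image, write_image

__all__ = [
    "PhantomConfigError", "HePalette", "PhantomGeometry", "PhantomSpec",
    "PhantomSample", "generate_phantom", "generate_dataset",
    "check_pathology_label", "rasterize_layers", "load_manifest",
    "MANIFEST_COLUMNS", "DEFAULT_REFLECTIVITY",
]

MANIFEST_COLUMNS = ("id", "domain", "path", "mask_path", "pathology_label", "seed")

# per-layer OCT mean reflectivity: intima, media, adventitia, background
DEFAULT_REFLECTIVITY = np.array([0.62, 0.30, 0.48, 0.04], dtype=np.float32)
_ATTENUATION_PER_PIXEL = 0.006   # exponential decay with depth below the surface

_LIPID_HE = np.array([0.97, 0.96, 0.94], dtype=np.float32)     # "white holes"
_CALCIUM_HE = np.array([0.36, 0.20, 0.46], dtype=np.float32)   # dark purple
_LIPID_OCT = 0.06
_CALCIUM_OCT = 0.08
_CALCIUM_RIM_OCT = 0.90


class PhantomConfigError(ValueError):
    """A :class:`PhantomSpec` violated its invariants."""


@dataclass(frozen=True)
class HePalette:
    """Per-layer RGB means and standard deviations, rows ordered
    intima, media, adventitia, background; values in [0, 1]."""

    means: np.ndarray = field(default_factory=lambda: np.array(
        [[0.90, 0.60, 0.70],
         [0.75, 0.45, 0.66],
         [0.93, 0.76, 0.82],
         [0.97, 0.96, 0.97]], dtype=np.float32))
    stds: np.ndarray = field(default_factory=lambda: np.full((4, 3), 0.025, dtype=np.float32))

    def validate(self) -> None:
        if np.asarray(self.means).shape != (4, 3) or np.asarray(self.stds).shape != (4, 3):
            raise PhantomConfigError("he_palette means/stds must have shape (4, 3)")
        if np.any(np.asarray(self.means) < 0) or np.any(np.asarray(self.means) > 1):
            raise PhantomConfigError("he_palette means must lie in [0, 1]")
        if np.any(np.asarray(self.stds) < 0):
            raise PhantomConfigError("he_palette stds must be non-negative")


@dataclass(frozen=True)
class PhantomGeometry:
    """Exact geometry a phantom was drawn from.

    ``boundaries`` has shape (3, width): per-column rows of the
    background/intima, intima/media and media/adventitia interfaces.
    ``inclusions`` is a list of (cx, cy, rx, ry, theta) ellipses.
    """

    boundaries: np.ndarray
    inclusions: tuple[tuple[float, float, float, float, float], ...]
    kind: str


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom specimen."""

    height: int = 64
    width: int = 64
    layer_fractions: tuple[float, float, float] = (0.18, 0.30, 0.32)
    pathology_kind: Literal["none", "lipid", "calcium"] = "none"
    pathology_count: int = 0
    pathology_radius_range: tuple[float, float] = (4.0, 9.0)
    speckle_contrast: float = 0.35
    he_palette: HePalette = field(default_factory=HePalette)
    labeled: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise PhantomConfigError("image must be at least 8x8 pixels")
        f = np.asarray(self.layer_fractions, dtype=float)
        if f.shape != (3,) or np.any(f <= 0):
            raise PhantomConfigError("layer_fractions must be three strictly positive reals")
        if f.sum() > 1.0 + 1e-9:
            raise PhantomConfigError("layer_fractions must sum to at most 1")
        if (self.pathology_kind == "none") != (self.pathology_count == 0):
            raise PhantomConfigError(
                "pathology_kind 'none' requires pathology_count 0 and vice versa")
        if self.pathology_count < 0:
            raise PhantomConfigError("pathology_count must be non-negative")
        lo, hi = self.pathology_radius_range
        if not (1.0 <= lo <= hi <= min(self.height, self.width) / 2):
            raise PhantomConfigError(
                "pathology_radius_range must lie within [1, min(height, width)/2]")
        if self.speckle_contrast <= 0:
            raise PhantomConfigError("speckle_contrast must be positive")
        if self.seed < 0:
            raise PhantomConfigError("seed must be non-negative")
        self.he_palette.validate()


@dataclass(frozen=True)
class PhantomSample:
    """One rendered specimen (both domains share the same geometry)."""

    oct_image: np.ndarray                 # (H, W) float32 in [0, 1]
    he_image: np.ndarray                  # (H, W, 3) float32 in [0, 1]
    layer_mask: np.ndarray | None         # (H, W) uint8 in {0,1,2,3}, or None
    pathology_label: int                  # 1 iff at least one inclusion placed
    seed: int
    geometry: PhantomGeometry


def rasterize_layers(boundaries: np.ndarray, height: int) -> np.ndarray:
    """Layer-class mask from per-column interface rows.

    Classes: 0 intima, 1 media, 2 adventitia, 3 background (above the
    tissue surface).  Vectorised; an independent per-pixel oracle lives in
    the test suite.
    """
    width = boundaries.shape[1]
    rows = np.arange(height, dtype=np.float32)[:, None]
    b0, b1, b2 = boundaries[0][None, :], boundaries[1][None, :], boundaries[2][None, :]
    mask = np.full((height, width), 3, dtype=np.uint8)
    mask[(rows >= b0) & (rows < b1)] = 0
    mask[(rows >= b1) & (rows < b2)] = 1
    mask[rows >= b2] = 2
    return mask


def _ellipse_mask(height: int, width: int,
                  ellipse: tuple[float, float, float, float, float]) -> np.ndarray:
    cx, cy, rx, ry, theta = ellipse
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    return u * u + v * v <= 1.0


def _draw_geometry(spec: PhantomSpec, rng: np.random.Generator) -> PhantomGeometry:
    h, w = spec.height, spec.width
    f = np.asarray(spec.layer_fractions, dtype=np.float32)
    surface = h * (1.0 - f.sum())
    base = np.array([surface, surface + h * f[0], surface + h * (f[0] + f[1])],
                    dtype=np.float32)
    # gentle common tilt/undulation of the slab plus per-interface waviness
    x = np.arange(w, dtype=np.float32) / max(w - 1, 1)
    tilt = rng.uniform(-0.03, 0.03) * h * (x - 0.5)
    wave = (rng.uniform(0.005, 0.02) * h
            * np.sin(2 * np.pi * (rng.uniform(0.5, 1.5) * x + rng.uniform(0, 1))))
    boundaries = np.empty((3, w), dtype=np.float32)
    for i in range(3):
        jitter = (rng.uniform(0.002, 0.008) * h
                  * np.sin(2 * np.pi * (rng.uniform(0.5, 2.0) * x + rng.uniform(0, 1))))
        boundaries[i] = np.clip(base[i] + tilt + wave + jitter, 0, h - 1)
    # keep interfaces ordered after jitter
    boundaries = np.sort(boundaries, axis=0)

    inclusions: list[tuple[float, float, float, float, float]] = []
    if spec.pathology_count > 0:
        lo, hi = spec.pathology_radius_range
        top = float(boundaries[0].max())
        for _ in range(spec.pathology_count):
            rx = float(rng.uniform(lo, hi))
            ry = float(rng.uniform(lo, hi))
            cx = float(rng.uniform(rx, w - 1 - rx)) if w - 1 > 2 * rx else (w - 1) / 2
            ylo = min(top + ry, h - 1 - ry)
            cy = float(rng.uniform(ylo, h - 1 - ry)) if h - 1 - ry > ylo else (top + h) / 2
            theta = float(rng.uniform(0, np.pi))
            inclusions.append((cx, cy, rx, ry, theta))
    return PhantomGeometry(boundaries=boundaries, inclusions=tuple(inclusions),
                           kind=spec.pathology_kind)


def _render_oct(spec: PhantomSpec, geom: PhantomGeometry, mask: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    signal = DEFAULT_REFLECTIVITY[mask].astype(np.float32)
    depth = np.maximum(np.arange(h, dtype=np.float32)[:, None] - geom.boundaries[0][None, :], 0.0)
    signal = signal * np.exp(-_ATTENUATION_PER_PIXEL * depth)
    for ell in geom.inclusions:
        m = _ellipse_mask(h, w, ell)
        if geom.kind == "lipid":
            soft = ndimage.gaussian_filter(m.astype(np.float32), sigma=1.5)
            soft = np.clip(soft, 0.0, 1.0)
            signal = signal * (1.0 - soft) + soft * _LIPID_OCT
        else:  # calcium: sharp border, low interior, bright specular rim
            rim = m & ~ndimage.binary_erosion(m, iterations=2)
            signal[m] = _CALCIUM_OCT
            signal[rim] = _CALCIUM_RIM_OCT
    k = 1.0 / (spec.speckle_contrast ** 2)
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=(h, w)).astype(np.float32)
    return np.clip(signal * speckle, 0.0, 1.0).astype(np.float32)


def _render_he(spec: PhantomSpec, geom: PhantomGeometry, mask: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    means = np.asarray(spec.he_palette.means, dtype=np.float32)
    stds = np.asarray(spec.he_palette.stds, dtype=np.float32)
    img = means[mask] + rng.standard_normal((h, w, 3)).astype(np.float32) * stds[mask]
    for ell in geom.inclusions:
        m = _ellipse_mask(h, w, ell)
        if geom.kind == "lipid":
            soft = np.clip(ndimage.gaussian_filter(m.astype(np.float32), sigma=1.5), 0, 1)
            img = img * (1.0 - soft[..., None]) + soft[..., None] * _LIPID_HE[None, None]
        else:
            img[m] = _CALCIUM_HE
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom deterministically from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geom = _draw_geometry(spec, rng)
    mask = rasterize_layers(geom.boundaries, spec.height)
    oct_image = _render_oct(spec, geom, mask, rng)
    he_image = _render_he(spec, geom, mask, rng)
    label = int(len(geom.inclusions) > 0)
    return PhantomSample(
        oct_image=oct_image, he_image=he_image,
        layer_mask=mask if spec.labeled else None,
        pathology_label=label, seed=spec.seed, geometry=geom)


def check_pathology_label(sample: PhantomSample) -> bool:
    """Blinded rule-based label check from stored geometry.

    Re-rasterises every stored inclusion and tests whether any pathological
    pixel actually lies inside the image; returns True iff this agrees with
    ``sample.pathology_label``.
    """
    h, w = sample.oct_image.shape[:2]
    n_pix = 0
    for ell in sample.geometry.inclusions:
        n_pix += int(_ellipse_mask(h, w, ell).sum())
    return (n_pix > 0) == bool(sample.pathology_label)


def generate_dataset(n_normal: int, n_pathological: int, base_spec: PhantomSpec,
                     labeled_fraction: float, seed: int,
                     out_dir: str | Path) -> Path:
    """Write an unpaired two-domain phantom dataset to ``out_dir``.

    One image per sample; domains alternate across samples with independent
    geometries, so the OCT and H&E pools are unpaired by construction.
    Exactly ``round(labeled_fraction * n)`` samples carry pixel masks.
    Returns the manifest path (CSV with columns ``id,domain,path,mask_path,
    pathology_label,seed``; image paths are relative to the manifest).
    """
    if n_normal < 0 or n_pathological < 0:
        raise PhantomConfigError("sample counts must be non-negative")
    if not (0.0 <= labeled_fraction <= 1.0):
        raise PhantomConfigError("labeled_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    n = n_normal + n_pathological
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_normal + [1] * n_pathological)
    rng.shuffle(labels)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    labeled_ids = set(rng.choice(n, size=int(round(labeled_fraction * n)),
                                 replace=False).tolist()) if n else set()

    rows = []
    for i in range(n):
        pathological = bool(labels[i])
        if pathological:
            kind = (base_spec.pathology_kind if base_spec.pathology_kind != "none"
                    else ("lipid" if rng.random() < 0.5 else "calcium"))
            count = base_spec.pathology_count if base_spec.pathology_count > 0 else \
                int(rng.integers(1, 4))
        else:
            kind, count = "none", 0
        spec = replace(base_spec, pathology_kind=kind, pathology_count=count,
                       labeled=i in labeled_ids, seed=int(child_seeds[i]))
        sample = generate_phantom(spec)
        domain = "oct" if i % 2 == 0 else "he"
        img = sample.oct_image if domain == "oct" else sample.he_image
        img_rel = f"images/{i:05d}_{domain}.png"
        write_image(out_dir / img_rel, img)
        mask_rel = ""
        if sample.layer_mask is not None:
            mask_rel = f"masks/{i:05d}_mask.png"
            write_image(out_dir / mask_rel, sample.layer_mask, codes=True)
        rows.append({"id": f"{i:05d}", "domain": domain, "path": img_rel,
                     "mask_path": mask_rel, "pathology_label": int(pathological),
                     "seed": int(child_seeds[i])})

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def load_manifest(manifest_path: str | Path) -> list[dict]:
    """Read a dataset manifest; image/mask arrays are loaded lazily by path."""
    manifest_path = Path(manifest_path)
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != MANIFEST_COLUMNS:
            raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
        rows = []
        for row in reader:
            row["pathology_label"] = int(row["pathology_label"])
            row["seed"] = int(row["seed"])
            rows.append(row)
    return rows


def load_sample_arrays(manifest_path: str | Path, row: dict) -> tuple[np.ndarray, np.ndarray | None]:
    """Image (and mask, if present) for one manifest row, scaled to [0, 1]."""
    base = Path(manifest_path).parent
    img = read_image(base / row["path"])
    mask = read_image(base / row["mask_path"], codes=True) if row["mask_path"] else None
    return img, mask
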