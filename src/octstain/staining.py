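"""Inference-time virtual staining and image/volume I/O.

Images travel through the package as float arrays in [0, 1]: grayscale OCT
as (H, W), H&E as (H, W, 3).  On disk, images are 8-bit PNG/TIFF (or 16-bit
grayscale TIFF) and 3-D volumes are multi-page TIFF stacks, quantised with
round-half-away-from-zero.  Large inputs are stained tile-by-tile with
linear feathering across tile overlaps so no seams appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "Volume", "read_image", "write_image", "read_volume", "write_volume",
    "stain_image", "stain_volume", "quantize",
]


def quantize(img: np.ndarray, bits: int = 8) -> np.ndarray:
    """[0,1] float -> integer codes, round half away from zero."""
    top = (1 << bits) - 1
    out = np.floor(np.clip(img, 0.0, 1.0) * top + 0.5)
    return out.astype(np.uint8 if bits == 8 else np.uint16)


def write_image(path: str | Path, img: np.ndarray, codes: bool = False,
                bits: int = 8) -> None:
    """Write a [0,1] float image (or, with ``codes=True``, raw integer codes
    such as a layer mask) as PNG or TIFF, chosen by file suffix."""
    path = Path(path)
    if codes:
        arr = np.asarray(img).astype(np.uint8)
    else:
        arr = quantize(np.asarray(img), bits=bits)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_image(path: str | Path, codes: bool = False) -> np.ndarray:
    """Read an image written by :func:`write_image` back to [0,1] floats
    (or raw integer codes with ``codes=True``)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if codes:
        return arr.astype(np.uint8)
    top = 65535.0 if arr.dtype == np.uint16 else 255.0
    return (arr.astype(np.float32) / top)


@dataclass
class Volume:
    """An ordered stack of same-sized slices plus axis spacing metadata."""

    data: np.ndarray                       # (S, H, W) or (S, H, W, 3), [0,1]
    spacing_um: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (slice, row, col)

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("volume data must be (S, H, W) or (S, H, W, C)")
        if self.data.shape[0] == 0:
            raise ValueError("volume has no slices")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def write_volume(path: str | Path, volume: Volume, bits: int = 8) -> None:
    """Multi-page TIFF with spacing recorded in the image description."""
    arr = quantize(volume.data, bits=bits)
    meta = {"spacing_um": list(volume.spacing_um)}
    photometric = "rgb" if arr.ndim == 4 else "minisblack"
    tifffile.imwrite(Path(path), arr, metadata=meta, photometric=photometric)


def read_volume(path: str | Path) -> Volume:
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    spacing = tuple(meta.get("spacing_um", (2.0, 2.0, 2.0)))
    top = 65535.0 if arr.dtype == np.uint16 else 255.0
    return Volume(data=arr.astype(np.float32) / top, spacing_um=spacing)


def _feather_profile(n: int, overlap: int, has_before: bool, has_after: bool) -> np.ndarray:
    """Per-pixel blend weight along one axis of a tile: linear ramps over the
    overlap at interior edges, flat 1 elsewhere."""
    w = np.ones(n, dtype=np.float32)
    if overlap > 0:
        ramp = (np.arange(1, overlap + 1, dtype=np.float32)) / (overlap + 1)
        if has_before:
            w[:overlap] = ramp
        if has_after:
            w[-overlap:] = ramp[::-1]
    return w


def _tile_starts(total: int, tile: int, overlap: int) -> list[int]:
    if tile >= total:
        return [0]
    step = tile - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than tile size")
    starts = list(range(0, total - tile, step))
    starts.append(total - tile)  # last tile flush with the border
    return starts


def stain_image(oct_image: np.ndarray, model, tile: int | None = None,
                overlap: int = 0) -> np.ndarray:
    """Translate one OCT image to the H&E domain, tiling large inputs.

    ``model`` is any object with ``translate(image) -> image`` semantics
    (e.g. a trained OCT->H&E :class:`~octstain.ctgen.Generator`).  With
    ``tile=None`` or a tile covering the whole image, this is exactly one
    un-tiled forward pass; otherwise overlapping tiles are blended with
    linear feathering and the blend weights are normalised to sum to 1.
    """
    img = np.asarray(oct_image, dtype=np.float32)
    h, w = img.shape[:2]
    if tile is None or (tile >= h and tile >= w):
        return model.translate(img)
    ty, tx = min(tile, h), min(tile, w)
    ys = _tile_starts(h, ty, overlap)
    xs = _tile_starts(w, tx, overlap)
    out: np.ndarray | None = None
    weight = np.zeros((h, w), dtype=np.float32)
    for y0 in ys:
        for x0 in xs:
            patch = img[y0:y0 + ty, x0:x0 + tx]
            stained = model.translate(patch)
            if out is None:
                ch = 1 if stained.ndim == 2 else stained.shape[2]
                out = np.zeros((h, w, ch), dtype=np.float32)
            wy = _feather_profile(ty, overlap, y0 != ys[0], y0 != ys[-1])
            wx = _feather_profile(tx, overlap, x0 != xs[0], x0 != xs[-1])
            wpatch = wy[:, None] * wx[None, :]
            out[y0:y0 + ty, x0:x0 + tx] += (
                stained.reshape(ty, tx, -1) * wpatch[..., None])
            weight[y0:y0 + ty, x0:x0 + tx] += wpatch
    assert out is not None
    out /= weight[..., None]
    return np.clip(out.squeeze(), 0.0, 1.0).astype(np.float32)


def stain_volume(volume: Volume, model, tile: int | None = None,
                 overlap: int = 0) -> Volume:
    """Slice-by-slice virtual staining of a 3-D OCT volume."""
    if volume.n_slices == 0:
        raise ValueError("volume has no slices")
    stained = [stain_image(volume.data[i], model, tile=tile, overlap=overlap)
               for i in range(volume.n_slices)]
    return Volume(data=np.stack(stained, axis=0), spacing_um=volume.spacing_um)
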