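"""Image pyramids and co-centered multi-magnification patch extraction.

A whole-slide-style RGB image is downsampled 2× per level by bilinear
interpolation; a fixed sliding window then cuts patches from two levels
such that the high-magnification patch sits at the centre of the
low-magnification patch's field of view. A retention filter keeps only
patches whose footprint touches annotated structures (duct, artery, vein,
fibrosis), which counteracts the dominance of plain parenchyma tiles.

Conventions: 0-based (row, col) coordinates, half-open windows
``[origin, origin + window)``, half-pixel-center bilinear resampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .nn.tensor import linear_interp_matrix

logger = logging.getLogger(__name__)

STRUCTURE_CLASSES = ("duct", "artery", "vein", "fibrosis")

__all__ = [
    "ImagePyramid", "PatchPair", "PatchIndexRecord",
    "resize_bilinear", "build_pyramid", "extract_patch_pairs",
    "filter_patches", "write_patch_pairs", "read_image", "read_mask",
]


def resize_bilinear(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of an (H, W) or (H, W, C) image.

    Uses half-pixel sample centers with edge clamping; float inputs are
    resampled in float64, uint8 inputs are rounded back to uint8.
    """
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D image")
    h, w = image.shape[:2]
    ar = linear_interp_matrix(h, out_h).astype(np.float64)
    ac = linear_interp_matrix(w, out_w).astype(np.float64)
    data = image.astype(np.float64)
    if image.ndim == 2:
        out = ar @ data @ ac.T
    else:
        out = np.einsum("oh,hwc->owc", ar, data)
        out = np.einsum("pw,owc->opc", ac, out)
    if image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(image.dtype, copy=False)


@dataclass
class ImagePyramid:
    """Ordered stack of progressively 2×-downsampled images.

    Level 0 is the input at base magnification (nominally 40×); level k
    halves each spatial dimension of level k−1 (ceil division on odd
    sizes).
    """

    levels: list[np.ndarray]
    base_magnification: float = 40.0
    factor_per_level: int = 2

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def level_shapes(self) -> list[tuple[int, int]]:
        return [lvl.shape[:2] for lvl in self.levels]

    def magnification(self, level: int) -> float:
        return self.base_magnification / self.factor_per_level**level


@dataclass
class PatchPair:
    """Co-centered high/low magnification window pair.

    ``center_base`` is the shared centre in level-0 pixel coordinates; the
    high patch's field of view is the central 1/r fraction of the low
    patch's, r = 2**(low_level - high_level).
    """

    high_patch: np.ndarray
    low_patch: np.ndarray
    center_base: tuple[int, int]
    high_level: int
    low_level: int
    mask_patch: np.ndarray | None = None

    @property
    def magnification_ratio(self) -> int:
        return 2 ** (self.low_level - self.high_level)


@dataclass
class PatchIndexRecord:
    patch_id: str
    center_base: tuple[int, int]
    retained: bool
    structure_flags: set[str] = field(default_factory=set)


def build_pyramid(image: np.ndarray, n_levels: int,
                  base_magnification: float = 40.0) -> ImagePyramid:
    """Build an ``n_levels``-deep bilinear image pyramid from ``image``."""
    if not isinstance(n_levels, (int, np.integer)) or n_levels < 1:
        raise ValueError(f"n_levels must be a positive integer, got {n_levels}")
    if image.ndim not in (2, 3) or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have positive spatial dimensions")
    min_dim = 2 ** (n_levels - 1)
    if image.shape[0] < min_dim or image.shape[1] < min_dim:
        raise ValueError(
            f"image of shape {image.shape[:2]} too small for {n_levels} "
            f"pyramid levels (needs ≥ {min_dim} px per side)")
    levels = [image]
    for _ in range(1, n_levels):
        prev = levels[-1]
        oh = math.ceil(prev.shape[0] / 2)
        ow = math.ceil(prev.shape[1] / 2)
        levels.append(resize_bilinear(prev, oh, ow))
    return ImagePyramid(levels=levels, base_magnification=base_magnification)


def _reflect_window(image: np.ndarray, r0: int, c0: int, size: int) -> np.ndarray:
    """Extract a ``size``×``size`` window, reflection-padding out-of-bounds."""
    h, w = image.shape[:2]
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + size - h)
    pad_right = max(0, c0 + size - w)
    if pad_top or pad_left or pad_bottom or pad_right:
        pad = ((pad_top, pad_bottom), (pad_left, pad_right))
        if image.ndim == 3:
            pad = pad + ((0, 0),)
        image = np.pad(image, pad, mode="reflect")
        r0 += pad_top
        c0 += pad_left
    return image[r0:r0 + size, c0:c0 + size]


def extract_patch_pairs(pyramid: ImagePyramid, high_level: int, low_level: int,
                        window: int = 256, stride: int | None = None,
                        mask: np.ndarray | None = None) -> list[PatchPair]:
    """Tile the high-magnification level and pair each tile with the
    co-centered window of the low-magnification level.

    High-level windows tile with ``stride`` (default: non-overlapping,
    stride = window). The low window is centred at the same base-level
    location, mapped by halving coordinates once per level; parts falling
    outside the low level are reflection-padded. ``mask`` is an optional
    base-level binary ground truth, cut aligned to the high patch.
    """
    if not (0 <= high_level < low_level < pyramid.n_levels):
        raise ValueError(
            f"need high_level < low_level < n_levels, got "
            f"{high_level}, {low_level}, {pyramid.n_levels}")
    stride = window if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    hi_img = pyramid.levels[high_level]
    lo_img = pyramid.levels[low_level]
    hh, hw = hi_img.shape[:2]
    if hh < window or hw < window:
        logger.warning(
            "level %d image (%dx%d) smaller than window %d; no patches",
            high_level, hh, hw, window)
        return []

    hi_scale = 2**high_level
    lo_scale = 2**low_level
    mask_hi = None
    if mask is not None:
        if high_level == 0:
            mask_hi = mask
        else:  # nearest-neighbour label downsampling to the high level
            rr = (np.arange(hh) + 0.5) * mask.shape[0] / hh - 0.5
            cc = (np.arange(hw) + 0.5) * mask.shape[1] / hw - 0.5
            ri = np.clip(np.rint(rr).astype(int), 0, mask.shape[0] - 1)
            ci = np.clip(np.rint(cc).astype(int), 0, mask.shape[1] - 1)
            mask_hi = mask[np.ix_(ri, ci)]

    pairs: list[PatchPair] = []
    half = window // 2
    for r0 in range(0, hh - window + 1, stride):
        for c0 in range(0, hw - window + 1, stride):
            center_hi = (r0 + half, c0 + half)
            center_base = (center_hi[0] * hi_scale, center_hi[1] * hi_scale)
            lo_r = int(round(center_base[0] / lo_scale - half))
            lo_c = int(round(center_base[1] / lo_scale - half))
            low_patch = _reflect_window(lo_img, lo_r, lo_c, window)
            mask_patch = None
            if mask_hi is not None:
                mask_patch = mask_hi[r0:r0 + window, c0:c0 + window]
            pairs.append(PatchPair(
                high_patch=hi_img[r0:r0 + window, c0:c0 + window],
                low_patch=low_patch,
                center_base=center_base,
                high_level=high_level,
                low_level=low_level,
                mask_patch=mask_patch,
            ))
    return pairs


def filter_patches(pairs: list[PatchPair],
                   annotations: dict[str, np.ndarray] | None,
                   min_pixels: int = 1,
                   window: int = 256,
                   ) -> tuple[list[PatchPair], list[PatchIndexRecord]]:
    """Retain patch pairs whose high-patch footprint contains annotated
    structure (duct, artery, vein or fibrosis) pixels.

    A pair is retained iff ≥ ``min_pixels`` pixels of any structure class
    fall inside its base-level footprint. With no annotations, every pair
    is retained and a warning is logged.
    """
    index: list[PatchIndexRecord] = []
    retained: list[PatchPair] = []
    if not annotations:
        logger.warning("no structure annotations given; retaining all %d pairs",
                       len(pairs))
        for i, p in enumerate(pairs):
            index.append(PatchIndexRecord(f"patch_{i:06d}", p.center_base, True))
        return list(pairs), index

    for i, p in enumerate(pairs):
        scale = 2**p.high_level
        fov = window * scale
        r0 = p.center_base[0] - fov // 2
        c0 = p.center_base[1] - fov // 2
        flags: set[str] = set()
        for name, amask in annotations.items():
            rs, re = max(0, r0), min(amask.shape[0], r0 + fov)
            cs, ce = max(0, c0), min(amask.shape[1], c0 + fov)
            if rs < re and cs < ce and \
                    int(np.count_nonzero(amask[rs:re, cs:ce])) >= min_pixels:
                flags.add(name)
        keep = bool(flags)
        index.append(PatchIndexRecord(f"patch_{i:06d}", p.center_base, keep, flags))
        if keep:
            retained.append(p)
    return retained, index


# -- image / index I/O ---------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image (PNG/TIFF), dropping any alpha channel."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel binary mask; {0,255} is normalised to {0,1}."""
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[:, :, 0]
    m = np.asarray(m)
    if m.max() > 1:
        m = (m > 127).astype(np.uint8)
    return m.astype(np.uint8)


def write_patch_pairs(pairs: list[PatchPair], index: list[PatchIndexRecord],
                      outdir: str | Path) -> Path:
    """Write ``<id>_hi.png`` / ``<id>_lo.png`` / ``<id>_mask.png`` files for
    the retained pairs and a CSV index for all records; returns the index
    path. ``pairs`` must be the retained list, ordered as in ``index``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    retained_ids = [rec.patch_id for rec in index if rec.retained]
    for pid, pair in zip(retained_ids, pairs):
        iio.imwrite(outdir / f"{pid}_hi.png", _to_u8(pair.high_patch))
        iio.imwrite(outdir / f"{pid}_lo.png", _to_u8(pair.low_patch))
        if pair.mask_patch is not None:
            iio.imwrite(outdir / f"{pid}_mask.png",
                        (pair.mask_patch.astype(np.uint8) * 255))
    for rec in index:
        rows.append({
            "patch_id": rec.patch_id,
            "center_row": rec.center_base[0],
            "center_col": rec.center_base[1],
            "high_level": pairs[0].high_level if pairs else -1,
            "low_level": pairs[0].low_level if pairs else -1,
            "retained": rec.retained,
            "structure_flags": "|".join(sorted(rec.structure_flags)),
        })
    index_path = outdir / "patch_index.csv"
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path


def _to_u8(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
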