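"""Redness quantification of intraoperative aneurysm images.

Thin-walled aneurysm regions appear reddish under the operating microscope.
To score redness objectively, the image is converted from sRGB to CIELAB
(D65 illuminant, 2 degree observer), each pixel is compared with a
clinician-annotated reference patch on normal vessel using the CIEDE2000
color difference dE00, and dE00 is projected onto the red-green (a*) axis:

    dE_m = dE00 * a2^2 / (L2^2 + a2^2)

where (L2, a2) are the reference-patch means.  The factor is constant per
image, so dE_m preserves pixel rankings while discounting differences that
are not redness-driven.  The pixel (patch) with the highest dE_m marks the
presumed thin-walled area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

__all__ = [
    "RegionAnnotation",
    "ReferenceColor",
    "DeltaEMap",
    "srgb_to_lab",
    "ciede2000",
    "reference_color",
    "delta_e_map",
    "modify_delta_e",
    "reddest_region",
]

Role = Literal["reference", "more_dangerous", "less_dangerous", "roi"]


@dataclass(frozen=True)
class RegionAnnotation:
    """Circular pixel region; (cx, cy) 0-based, origin top-left, x = column."""

    cx: float
    cy: float
    radius: float
    role: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("annotation radius must be positive")
        if self.role not in ("reference", "more_dangerous", "less_dangerous", "roi"):
            raise ValueError(f"unknown annotation role {self.role!r}")

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (H, W) mask of pixels inside the circle."""
        h, w = shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2
        if not mask.any():
            raise ValueError("annotation circle contains no image pixels")
        return mask


@dataclass(frozen=True)
class ReferenceColor:
    """Mean Lab color of the normal-vessel reference patch."""

    L2: float
    a2: float
    b2: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.L2, self.a2, self.b2])):
            raise ValueError("reference color must be finite")
        if not 0.0 <= self.L2 <= 100.0:
            raise ValueError("reference L* must be in [0, 100]")

    @property
    def lab(self) -> np.ndarray:
        return np.array([self.L2, self.a2, self.b2])


@dataclass(frozen=True)
class DeltaEMap:
    """Per-pixel color difference from the reference; raw dE00 or dE_m."""

    values: np.ndarray
    modified: bool
    redness_factor: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("DeltaEMap values must be 2-D")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("DeltaEMap values must be finite and >= 0")
        object.__setattr__(self, "values", v)


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("expected 8-bit sRGB values in [0, 255]")
    return img


def srgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Decode 8-bit sRGB to CIELAB (D65, 2 degree observer), per pixel."""
    img = _validate_rgb(image)
    return _skcolor.rgb2lab(img.astype(float) / 255.0)


def ciede2000(lab_a, lab_b) -> float:
    """CIEDE2000 color difference with kL = kC = kH = 1."""
    a = np.asarray(lab_a, dtype=float)
    b = np.asarray(lab_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("expected Lab triples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("Lab values must be finite")
    return float(_skcolor.deltaE_ciede2000(a, b))


def reference_color(lab: np.ndarray, annotation: RegionAnnotation) -> ReferenceColor:
    """Unweighted mean Lab over the reference circle."""
    if annotation.role != "reference":
        raise ValueError("reference_color needs an annotation with role 'reference'")
    mask = annotation.pixel_mask(lab.shape[:2])
    mean = lab[mask].mean(axis=0)
    return ReferenceColor(float(mean[0]), float(mean[1]), float(mean[2]))


def delta_e_map(lab: np.ndarray, ref: ReferenceColor) -> DeltaEMap:
    """Per-pixel CIEDE2000 difference from the reference color."""
    ref_img = np.broadcast_to(ref.lab, lab.shape)
    values = _skcolor.deltaE_ciede2000(lab, ref_img)
    return DeltaEMap(values, modified=False)


def redness_factor(ref: ReferenceColor, variant: str = "printed") -> float:
    """Projection factor of dE_m: a2^2/(L2^2+a2^2), or the cosine variant
    |a2|/sqrt(L2^2+a2^2) behind ``variant='projection'``."""
    denom = ref.L2**2 + ref.a2**2
    if denom == 0:
        raise ValueError("reference L2 and a2 are both zero; dE_m undefined")
    if variant == "printed":
        return ref.a2**2 / denom
    if variant == "projection":
        return abs(ref.a2) / np.sqrt(denom)
    raise ValueError(f"unknown dE_m variant {variant!r}")


def modify_delta_e(
    dmap: DeltaEMap, ref: ReferenceColor, variant: str = "printed"
) -> DeltaEMap:
    """Scale raw dE00 by the reference redness factor to obtain dE_m."""
    if dmap.modified:
        raise ValueError("map is already modified")
    c = redness_factor(ref, variant)
    return DeltaEMap(dmap.values * c, modified=True, redness_factor=c)


def reddest_region(
    dmap: DeltaEMap,
    roi: RegionAnnotation,
    patch_radius: float = 5.0,
) -> tuple[tuple[int, int], float]:
    """Peak of the disk-mean-filtered dE_m map inside the ROI.

    Returns ``((x, y), patch_mean)`` where (x, y) is the peak pixel
    (column, row).  The disk mean is computed over ROI pixels only; ties
    break row-major (smallest row, then column).  ``patch_radius = 0``
    degenerates to the raw argmax.
    """
    values = dmap.values
    mask = roi.pixel_mask(values.shape)
    if patch_radius > 0:
        r = int(np.ceil(patch_radius))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (xx**2 + yy**2 <= patch_radius**2).astype(float)
        num = ndimage.convolve(values * mask, disk, mode="constant")
        den = ndimage.convolve(mask.astype(float), disk, mode="constant")
        with np.errstate(invalid="ignore"):
            means = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    else:
        means = values
    candidate = np.where(mask, means, -np.inf)
    flat = int(np.argmax(candidate))  # first occurrence == row-major tie-break
    row, col = np.unravel_index(flat, values.shape)
    return (int(col), int(row)), float(means[row, col])
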