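"""ROI-patch construction and scanner-noise normalization.

The classifier never sees a whole MR slice: from the annotated bounding boxes
of the left and right iliac bones, a medially shifted region of interest is
derived on each side so that it covers the SIJ joint space plus the adjacent
half of the sacrum, where bone marrow edema appears.  The two crops are
height-matched, concatenated side by side, and resized to the network input
size.  Synthetic scanner noise (Gaussian + Poisson-derived) is added to every
image, independent of whether it is used for training, validation or testing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .phantom import Box


@dataclasses.dataclass(frozen=True)
class RoiBoxes:
    left_roi: Box
    right_roi: Box
    shift_fraction: float = 0.8


@dataclasses.dataclass
class RoiPatch:
    """Horizontally combined left+right joint-region crop."""

    image: np.ndarray
    left_roi: Box | None = None
    right_roi: Box | None = None

    @property
    def shape(self):
        return self.image.shape


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Acquisition-noise model: additive zero-mean Gaussian noise with the
    given variance (on the [0,1] intensity scale) plus a Poisson-derived
    component.

    ``poisson_rule``:

    * ``"single_pixel"`` — per image, one pixel value ``p`` is drawn uniformly
      at random, the Poisson mean is set to ``(ln(255 p + 1))^4`` on the 8-bit
      scale, one deviate is sampled per pixel and rescaled by 1/255;
    * ``"per_pixel"`` — same mean rule but evaluated per pixel from its own
      value;
    * ``"disabled"`` — no Poisson component.

    Note the default ``gaussian_variance`` of 0.3 is far above the intensity
    dynamic range and essentially whitens the image; realistic pipelines use
    variances of order 1e-3 to 1e-2 (see the methods note).
    """

    gaussian_variance: float = 0.3
    poisson_rule: str = "single_pixel"
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_variance < 0:
            raise ValueError("gaussian_variance must be >= 0")
        if self.poisson_rule not in ("single_pixel", "per_pixel", "disabled"):
            raise ValueError(f"unknown poisson_rule {self.poisson_rule!r}")


def poisson_mean(p: np.ndarray | float) -> np.ndarray | float:
    """Poisson expectation for pixel value(s) ``p`` in [0,1], 8-bit scale."""
    return np.log(255.0 * np.asarray(p) + 1.0) ** 4


def compute_roi_boxes(
    left_iliac_box: Box,
    right_iliac_box: Box,
    shift_fraction: float = 0.8,
    image_shape: tuple[int, int] | None = None,
) -> RoiBoxes:
    """Derive the two joint-region ROIs from the iliac bounding boxes.

    Each ROI keeps the rows of its iliac box and spans, column-wise, from the
    iliac-box center medially (toward the sacrum) for ``shift_fraction`` times
    the iliac-box width.  The right ROI is the mirror construction of the left
    one, so symmetric annotations produce symmetric ROIs.
    """
    lb, rb = left_iliac_box, right_iliac_box
    if lb.width <= 0 or rb.width <= 0:
        raise ValueError("iliac boxes must have positive width")
    if lb.c1 > rb.c0:
        raise ValueError("left iliac box must lie entirely left of the right one")

    wl = int(np.floor(shift_fraction * lb.width))
    wr = int(np.floor(shift_fraction * rb.width))
    if wl < 1 or wr < 1:
        raise ValueError("shift_fraction too small: degenerate zero-width ROI")

    ml = (lb.c0 + lb.c1) // 2
    mr = -((-(rb.c0 + rb.c1)) // 2)  # ceil: mirror image of the floor'd left center
    left = Box(lb.r0, lb.r1, ml, ml + wl)
    right = Box(rb.r0, rb.r1, mr - wr, mr)

    if image_shape is not None:
        h, w = image_shape
        left = _clip_box(left, h, w)
        right = _clip_box(right, h, w)
    return RoiBoxes(left_roi=left, right_roi=right, shift_fraction=shift_fraction)


def _clip_box(b: Box, h: int, w: int) -> Box:
    r0, r1 = max(b.r0, 0), min(b.r1, h)
    c0, c1 = max(b.c0, 0), min(b.c1, w)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"ROI {b} clipped to empty by image bounds {(h, w)}")
    return Box(r0, r1, c0, c1)


def _extend_rows(box: Box, target_height: int, image_height: int) -> Box:
    """Symmetrically grow a box's row span (within the image) to target height."""
    deficit = target_height - box.height
    if deficit <= 0:
        return box
    top = deficit // 2
    bottom = deficit - top
    r0 = box.r0 - top
    r1 = box.r1 + bottom
    if r0 < 0:
        r1 = min(r1 - r0, image_height)
        r0 = 0
    if r1 > image_height:
        r0 = max(r0 - (r1 - image_height), 0)
        r1 = image_height
    if r1 - r0 != target_height:
        raise ValueError("image too short to height-match the ROI crops")
    return Box(r0, r1, box.c0, box.c1)


def extract_roi_patch(image: np.ndarray, roi_boxes: RoiBoxes) -> RoiPatch:
    """Crop both ROIs and concatenate them horizontally (left then right).

    If the two crops differ in height, the shorter one is symmetrically
    extended from the source image to the taller height, so no pixel is
    interpolated at this stage.
    """
    h, w = image.shape
    left = _clip_box(roi_boxes.left_roi, h, w)
    right = _clip_box(roi_boxes.right_roi, h, w)
    target_h = max(left.height, right.height)
    left = _extend_rows(left, target_h, h)
    right = _extend_rows(right, target_h, h)
    patch = np.concatenate(
        [image[left.r0 : left.r1, left.c0 : left.c1], image[right.r0 : right.r1, right.c0 : right.c1]],
        axis=1,
    )
    return RoiPatch(image=patch, left_roi=left, right_roi=right)


def add_scanner_noise(
    image: np.ndarray,
    params: NoiseParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add Gaussian + Poisson-derived noise; output clipped to [0, 1].

    Applied identically to training, validation and test images.  With the
    Gaussian variance at 0 and the Poisson component disabled this is the
    identity.  Deterministic for a fixed seed.
    """
    img = np.asarray(image, dtype=np.float64)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    out = img.copy()
    if params.gaussian_variance > 0:
        out = out + rng.normal(0.0, np.sqrt(params.gaussian_variance), size=img.shape)
    if params.poisson_rule == "single_pixel":
        p = img.flat[rng.integers(img.size)]
        out = out + rng.poisson(poisson_mean(p), size=img.shape) / 255.0
    elif params.poisson_rule == "per_pixel":
        out = out + rng.poisson(poisson_mean(img)) / 255.0
    return np.clip(out, 0.0, 1.0)


def resize_patch(patch: RoiPatch | np.ndarray, target_size: tuple[int, int] = (224, 224)) -> RoiPatch:
    """Bilinear resize of a patch to the classifier input size."""
    img = patch.image if isinstance(patch, RoiPatch) else np.asarray(patch)
    if img.size == 0:
        raise ValueError("empty patch")
    out = _sk_resize(img, target_size, order=1, mode="edge", anti_aliasing=None, preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    if isinstance(patch, RoiPatch):
        return RoiPatch(image=out, left_roi=patch.left_roi, right_roi=patch.right_roi)
    return RoiPatch(image=out)


def augment(
    patch: np.ndarray,
    rng: np.random.Generator | int | None = None,
    rotation_range: float = 15.0,
    flip_probability: float = 0.5,
) -> np.ndarray:
    """Random horizontal flip and rotation; never crops.

    Rotation uses replicate-border fill so the patch keeps its dimensions and
    no lesion can be lost at the boundary (random crop is deliberately not
    offered, since a peripheral lesion could be cut off).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.asarray(patch, dtype=np.float64)
    if rng.random() < flip_probability:
        out = out[:, ::-1]
    angle = float(rng.uniform(-rotation_range, rotation_range))
    if angle != 0.0:
        out = _sk_rotate(out, angle, mode="edge", preserve_range=True, order=1)
    return np.clip(out, 0.0, 1.0)
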