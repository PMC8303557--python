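"""Grad-CAM saliency over the last convolutional stage.

For a trained classifier, the class-score gradient with respect to the final
convolutional feature maps is spatially averaged into per-channel weights;
the rectified weighted sum of the maps, bilinearly upsampled to the patch
size and max-normalized, highlights the image regions that drove the
decision.  On positive slices the hot region should coincide with the
lesion; failure cases (e.g. bright sacral bone) are expected occasionally.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize as _sk_resize

from .model import Classifier

POSITIVE_CLASS = "positive"
NEGATIVE_CLASS = "negative"


@dataclasses.dataclass
class SaliencyMap:
    heatmap: np.ndarray  # [0,1], same spatial size as the input patch
    target_class: str

    @property
    def peak(self) -> tuple[int, int]:
        """(row, col) of the hottest location."""
        return tuple(np.unravel_index(int(self.heatmap.argmax()), self.heatmap.shape))


def grad_cam(classifier: Classifier, patch: np.ndarray, target_class: str = POSITIVE_CLASS) -> SaliencyMap:
    """Grad-CAM map for one patch.

    Channel weights are the spatial global average of the target-class
    logit's gradient w.r.t. the last convolutional feature maps; the map is
    the ReLU of the weighted sum, bilinearly upsampled and max-normalized.
    """
    if target_class not in (POSITIVE_CLASS, NEGATIVE_CLASS):
        raise ValueError(f"unknown target class {target_class!r}")
    x = np.asarray(patch, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("patch must be a 2-D grayscale image")
    feats = classifier.features.forward(classifier._check_input(x[None]), train=False)
    if feats.ndim != 4:
        raise ValueError("classifier has no convolutional feature maps")
    logits = classifier.head.forward(feats, train=False)

    grad_out = np.zeros_like(logits)
    if classifier.config.n_outputs == 2:
        grad_out[0, 1 if target_class == POSITIVE_CLASS else 0] = 1.0
    else:
        # single positive-class logit: the negative-class score is its negation
        grad_out[0, 0] = 1.0 if target_class == POSITIVE_CLASS else -1.0
    classifier.zero_grad()
    grad_feats = classifier.head.backward(grad_out)
    classifier.zero_grad()

    weights = grad_feats[0].mean(axis=(1, 2))  # (channels,)
    cam = np.maximum((weights[:, None, None] * feats[0]).sum(axis=0), 0.0)
    cam = _sk_resize(cam, x.shape, order=1, mode="edge", preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return SaliencyMap(heatmap=cam, target_class=target_class)


def overlay(saliency: SaliencyMap, patch: np.ndarray, alpha: float = 0.6, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the color-mapped heatmap over the grayscale patch.

    Returns an RGB float image in [0,1] with the patch's dimensions.  The
    blend weight scales with heat, so an all-zero map reproduces the
    grayscale patch; colors run red (hottest) through orange/yellow/green to
    blue (coldest) under the default colormap.
    """
    import matplotlib

    patch = np.asarray(patch, dtype=np.float64)
    if saliency.heatmap.shape != patch.shape:
        raise ValueError("saliency map and patch sizes differ")
    heat_rgb = matplotlib.colormaps[cmap](saliency.heatmap)[..., :3]
    gray_rgb = np.repeat(np.clip(patch, 0, 1)[..., None], 3, axis=2)
    w = (alpha * saliency.heatmap)[..., None]
    return np.clip(gray_rgb * (1.0 - w) + heat_rgb * w, 0.0, 1.0)


def peak_in_lesion(saliency: SaliencyMap, lesion_mask: np.ndarray, dilate: int = 2) -> bool:
    """Whether the map's peak falls inside (a slightly dilated) lesion mask."""
    from scipy.ndimage import binary_dilation

    mask = np.asarray(lesion_mask, dtype=bool)
    if dilate > 0:
        mask = binary_dilation(mask, iterations=dilate)
    r, c = saliency.peak
    return bool(mask[r, c])
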