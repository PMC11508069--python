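"""Class-level Grad-CAM++ saliency maps for a fitted CNN.

The per-sample map is a weighted combination of the last convolutional
layer's feature maps, with weights built from the positive partial
derivatives of the (linear, pre-softmax) class score with respect to those
maps, rectified and bilinearly upsampled to the input resolution. The
class-level map averages the raw per-sample maps over all test samples of
one class and then max-normalizes, so every map lives in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom


class SaliencyUnsupportedError(TypeError):
    """The model does not expose convolutional feature maps."""


@dataclass
class SaliencyMap:
    plane: str
    class_index: int
    values: np.ndarray  # 2-D, in [0, 1]
    n_samples: int


def _check_model(model) -> None:
    if not getattr(model, "supports_saliency", False) or not hasattr(model, "conv_maps_and_grads"):
        raise SaliencyUnsupportedError(
            "saliency requires a model exposing last-conv feature maps and gradients"
        )


def _raw_cams(model, images: np.ndarray, class_index: int) -> np.ndarray:
    """Unnormalized Grad-CAM++ maps for a batch, upsampled to input size."""
    a_maps, grads = model.conv_maps_and_grads(images, class_index)
    # Grad-CAM++ alpha weights: grads^2 / (2 grads^2 + sum_spatial(A) * grads^3),
    # zero-denominator positions fall back to a unit denominator.
    second = grads**2
    third = grads**3
    global_sum = a_maps.sum(axis=(1, 2), keepdims=True)
    denom = 2.0 * second + third * global_sum
    denom = np.where(denom == 0.0, 1.0, denom)
    alphas = second / denom
    weights = (alphas * np.maximum(grads, 0.0)).sum(axis=(1, 2))  # (N, K)
    cams = np.maximum(np.einsum("nxyk,nk->nxy", a_maps, weights), 0.0)
    h, w = images.shape[1:3]
    ch, cw = cams.shape[1:3]
    out = np.stack([zoom(c, (h / ch, w / cw), order=1, grid_mode=True, mode="nearest") for c in cams])
    return out


def gradcam_pp(model, image: np.ndarray, class_index: int) -> np.ndarray:
    """Per-sample Grad-CAM++ map (non-negative, input resolution, raw scale)."""
    _check_model(model)
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D slice")
    return _raw_cams(model, img[None], class_index)[0]


def class_saliency(model, images: np.ndarray, class_index: int, plane: str = "axial") -> SaliencyMap:
    """Mean of the raw per-sample maps over one class, then max-normalized."""
    _check_model(model)
    imgs = np.asarray(images)
    if imgs.ndim != 3 or imgs.shape[0] < 1:
        raise ValueError("expected a non-empty (n, H, W) stack of slices")
    mean_map = _raw_cams(model, imgs, class_index).mean(axis=0)
    peak = mean_map.max()
    if peak > 0:
        mean_map = mean_map / peak
    return SaliencyMap(plane=plane, class_index=class_index, values=mean_map, n_samples=imgs.shape[0])


def difference_map(s1: SaliencyMap, s2: SaliencyMap) -> np.ndarray:
    """Elementwise absolute difference between two class maps."""
    if s1.values.shape != s2.values.shape or s1.plane != s2.plane:
        raise ValueError("saliency maps must share shape and plane")
    return np.abs(s1.values - s2.values)


def render(map_2d: np.ndarray, path, cmap: str = "jet") -> None:
    """Save a map as a PNG heatmap (thin plotting utility)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(map_2d), cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
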