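"""Dynamic joint-node plots: merged keypoint heatmaps and sampling diagnostics.

A DJNP accumulates a unit-mass isotropic 2D Gaussian kernel at every
confident keypoint location across the sampled frames of a walk, on a grid
downscaled from source-pixel resolution.  Unit-mass kernels (rather than
unit-peak) make the plot additive: total grid mass equals the number of
contributing keypoints whenever the kernels lie fully inside the grid.
Kernels are clipped at grid edges without renormalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pose_io import PoseSequence, sample_frames

__all__ = ["DJNP", "build_djnp", "sampling_sufficiency", "save_png", "save_array"]

DEFAULT_SIGMA_PX = 3.0
DEFAULT_DOWNSCALE = 4
DEFAULT_CONF_THRESHOLD = 0.1


@dataclass
class DJNP:
    """A merged joint-node heatmap."""

    grid: np.ndarray  # (height, width), downscaled
    sigma_px: float  # kernel sd in source pixels
    downscale: int
    n_frames_merged: int
    extent: tuple[int, int]  # source (width, height)

    @property
    def mass(self) -> float:
        return float(self.grid.sum())


def _add_kernel(grid: np.ndarray, cx: float, cy: float, sigma: float) -> None:
    """Add a unit-mass Gaussian at grid coordinates (cx, cy), clipped at edges."""
    radius = max(1, int(math.ceil(4.0 * sigma)))
    ix, iy = int(round(cx)), int(round(cy))
    gx = np.arange(ix - radius, ix + radius + 1)
    gy = np.arange(iy - radius, iy + radius + 1)
    kx = np.exp(-((gx - cx) ** 2) / (2 * sigma**2))
    ky = np.exp(-((gy - cy) ** 2) / (2 * sigma**2))
    kernel = np.outer(ky, kx)
    kernel /= kernel.sum()  # unit mass over the full (untruncated) window
    h, w = grid.shape
    x0, x1 = max(0, gx[0]), min(w, gx[-1] + 1)
    y0, y1 = max(0, gy[0]), min(h, gy[-1] + 1)
    if x0 >= x1 or y0 >= y1:
        return
    grid[y0:y1, x0:x1] += kernel[y0 - gy[0] : y1 - gy[0], x0 - gx[0] : x1 - gx[0]]


def build_djnp(
    seq: PoseSequence,
    sigma_px: float = DEFAULT_SIGMA_PX,
    downscale: int = DEFAULT_DOWNSCALE,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    image_size: tuple[int, int] = (1920, 1080),
) -> DJNP:
    """Merge per-frame keypoint heatmaps of an (already sampled) sequence."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    if downscale < 1:
        raise ValueError("downscale must be >= 1")
    width, height = image_size
    grid = np.zeros((math.ceil(height / downscale), math.ceil(width / downscale)))
    sigma = sigma_px / downscale
    n_points = 0
    for frame in seq.frames:
        kp = frame.keypoints
        for x, y, c in kp[kp[:, 2] > conf_threshold]:
            _add_kernel(grid, x / downscale, y / downscale, sigma)
            n_points += 1
    if n_points == 0:
        raise ValueError("empty DJNP: no keypoints above the confidence threshold")
    return DJNP(
        grid=grid,
        sigma_px=sigma_px,
        downscale=downscale,
        n_frames_merged=len(seq.frames),
        extent=(width, height),
    )


def sampling_sufficiency(
    seq: PoseSequence,
    interval_s: float,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> float:
    """Silhouette-overlap score of a sampling interval, in [0, 1].

    For each consecutive pair of sampled frames, compare the distance between
    bounding-box centres with the pair's mean box width:
    ``max(0, 1 - gap / width)`` averaged over pairs.  1 means heavily
    overlapping silhouettes (dense sampling); 0 means disjoint ones.
    """
    from .features_tsr import frame_bounding_boxes

    sampled = sample_frames(seq, interval_s)
    boxes, valid = frame_bounding_boxes(sampled, conf_threshold)
    boxes = boxes[valid]
    if len(boxes) < 2:
        raise ValueError("need >= 2 sampled frames with a valid bounding box")
    xmin, xmax, ymin, ymax = boxes.T
    centres = np.column_stack([(xmin + xmax) / 2, (ymin + ymax) / 2])
    widths = xmax - xmin
    gaps = np.linalg.norm(np.diff(centres, axis=0), axis=1)
    pair_widths = (widths[:-1] + widths[1:]) / 2
    return float(np.mean(np.maximum(0.0, 1.0 - gaps / pair_widths)))


def save_png(djnp: DJNP, path: str | Path) -> None:
    """Export the plot as a PNG image (perceptually-uniform colormap)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.imshow(djnp.grid, cmap="viridis", origin="upper", interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def save_array(djnp: DJNP, path: str | Path) -> None:
    """Export the raw grid (``.npy``) with a JSON metadata sidecar."""
    path = Path(path)
    np.save(path, djnp.grid)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "sigma_px": djnp.sigma_px,
                "downscale": djnp.downscale,
                "n_frames_merged": djnp.n_frames_merged,
                "extent": list(djnp.extent),
            },
            fh,
            indent=2,
        )
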