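"""Point <-> voxel-grid target codec.

Landmarks are encoded as per-channel Gaussian heatmaps evaluated at voxel
centers, ``exp(-||world(v) - p||^2 / (2 sigma^2))``, peak 1 at the landmark.
Decoding takes the intensity-weighted centroid over the voxels at or above a
fraction of the channel maximum, which gives sub-voxel accuracy and a
deterministic tie-break (plateau voxels all enter the centroid; the channel
maximum itself is located at the lowest linear index on exact ties).  A
channel whose maximum is <= 0 decodes to an absent landmark with a warning
flag rather than an arbitrary position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TASK_LANDMARKS, PointSet, Volume


@dataclass(frozen=True)
class HeatmapEncoding:
    sigma_mm: float = 3.0
    threshold_frac: float = 0.5
    mode: str = "centroid"  # "centroid" | "argmax"

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be > 0")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must lie in (0, 1)")


DEFAULT_ENCODING = HeatmapEncoding()


def task_landmarks(task: str) -> tuple[str, ...]:
    try:
        return TASK_LANDMARKS[task]
    except KeyError:
        raise ValueError(f"task {task!r} has no landmark channels") from None


def encode_points(points: PointSet, grid: Volume, enc: HeatmapEncoding, task: str) -> np.ndarray:
    """Encode a task's landmarks as a (C, *grid.shape) heatmap stack."""
    names = task_landmarks(task)
    missing = [n for n in names if n not in points]
    if missing:
        raise ValueError(f"landmarks missing for task {task}: {missing}")
    ax = grid.voxel_centers()
    out = np.empty((len(names),) + grid.shape, dtype=float)
    extent_lo = grid.origin
    extent_hi = grid.index_to_world(np.array(grid.shape) - 1)
    for c, name in enumerate(names):
        p = points[name]
        if np.any(p < extent_lo - 1e-9) or np.any(p > extent_hi + 1e-9):
            raise ValueError(f"landmark {name} at {p} lies outside the grid extent")
        d2 = (
            (ax[0] - p[0])[:, None, None] ** 2
            + (ax[1] - p[1])[None, :, None] ** 2
            + (ax[2] - p[2])[None, None, :] ** 2
        )
        out[c] = np.exp(-d2 / (2.0 * enc.sigma_mm**2))
    return out


def decode_points(prediction: np.ndarray, grid: Volume, enc: HeatmapEncoding, task: str) -> tuple[PointSet, list[str]]:
    """Decode heatmaps back to world-mm landmarks.

    Returns the point set and a list of warnings; degenerate channels
    (max <= 0) yield an absent landmark plus a warning.
    """
    names = task_landmarks(task)
    pred = np.asarray(prediction, dtype=float)
    if pred.shape != (len(names),) + grid.shape:
        raise ValueError(
            f"prediction shape {pred.shape} does not match ({len(names)},)+{grid.shape}"
        )
    points = PointSet()
    warnings: list[str] = []
    ax = grid.voxel_centers()
    for c, name in enumerate(names):
        ch = pred[c]
        peak = float(ch.max())
        if peak <= 0.0:
            warnings.append(f"channel {name}: non-positive maximum, landmark absent")
            continue
        if enc.mode == "argmax":
            flat = int(np.argmax(ch))  # numpy argmax returns the lowest index on ties
            idx = np.unravel_index(flat, ch.shape)
            points[name] = grid.index_to_world(np.array(idx))
            continue
        support = ch >= enc.threshold_frac * peak
        w = np.where(support, ch, 0.0)
        total = w.sum()
        coords = np.array(
            [
                (w.sum(axis=(1, 2)) * ax[0]).sum(),
                (w.sum(axis=(0, 2)) * ax[1]).sum(),
                (w.sum(axis=(0, 1)) * ax[2]).sum(),
            ]
        )
        points[name] = coords / total
    return points, warnings


def binarize_mask(prediction: np.ndarray, grid: Volume, threshold: float = 0.5) -> Volume:
    """Threshold a 1-channel prediction into a binary mask volume."""
    pred = np.asarray(prediction, dtype=float)
    if pred.ndim == 4:
        if pred.shape[0] != 1:
            raise ValueError(f"expected a single channel, got {pred.shape[0]}")
        pred = pred[0]
    if pred.shape != grid.shape:
        raise ValueError(f"prediction shape {pred.shape} does not match grid {grid.shape}")
    return Volume((pred >= threshold).astype(np.float32), grid.spacing.copy(), grid.origin.copy())


def downsample_target(target: np.ndarray, level: int, soft: bool) -> np.ndarray:
    """Downsample a (C, D, H, W) target by 2**level per axis.

    Soft targets (heatmaps) are block-averaged; hard targets (masks) use
    nearest-neighbour striding so labels stay binary.
    """
    out = target
    for _ in range(level):
        if soft:
            c, d, h, w = out.shape
            out = out.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
        else:
            out = out[:, ::2, ::2, ::2]
    return out


__all__ = [
    "HeatmapEncoding", "DEFAULT_ENCODING", "encode_points", "decode_points",
    "binarize_mask", "downsample_target", "task_landmarks",
]
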