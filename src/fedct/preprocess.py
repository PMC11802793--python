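"""Harmonized preprocessing and file I/O.

CT volumes are normalized with a fixed scheme: intensities are clipped to the
5th/95th HU percentiles of the reference distribution and standardised with
its mean and standard deviation,

    x_norm = (clip(X, lo, hi) - mu) / max(sigma, eps)

with mu = -438.61 HU, sigma = 520.98 HU, lo = -1024, hi = 696.  The constants
are fixed reference values, not recomputed per dataset, so every federation
client applies the identical mapping.

Volumes travel as NIfTI, landmarks as MITK-compatible point-set XML (.mps).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import ALL_LANDMARKS, PointSet, Volume


@dataclass(frozen=True)
class NormalizationParams:
    """Fixed CT normalization constants (HU)."""

    mu: float = -438.61
    sigma: float = 520.98
    lo: float = -1024.0
    hi: float = 696.0
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"lo must be < hi, got {self.lo} >= {self.hi}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


DEFAULT_NORMALIZATION = NormalizationParams()


def normalize_ct(volume: Volume, params: NormalizationParams = DEFAULT_NORMALIZATION) -> Volume:
    """Clip to [lo, hi] and standardise; geometry is untouched."""
    vals = volume.values
    n_bad = int(np.size(vals) - np.isfinite(vals).sum())
    if n_bad:
        raise ValueError(f"volume contains {n_bad} non-finite voxels")
    out = (np.clip(vals, params.lo, params.hi) - params.mu) / max(params.sigma, params.eps)
    return Volume(out, volume.spacing.copy(), volume.origin.copy())


def crop_to_mask(volume: Volume, mask: Volume, margin_mm: float = 0.0) -> tuple[Volume, np.ndarray]:
    """Crop to the tight bounding box of ``mask`` plus a world-mm margin.

    Returns the cropped volume and the voxel offset of its corner in the
    original grid.  The origin is updated so retained voxels keep their world
    coordinates.
    """
    if not volume.same_grid(mask):
        raise ValueError("mask must share the volume's grid")
    fg = np.asarray(mask.values) > 0
    if not fg.any():
        raise ValueError("cannot crop to an empty mask")
    lo = np.empty(3, dtype=int)
    hi = np.empty(3, dtype=int)
    for a in range(3):
        axes = tuple(i for i in range(3) if i != a)
        proj = fg.any(axis=axes)
        idx = np.nonzero(proj)[0]
        m = int(math.ceil(margin_mm / volume.spacing[a]))
        lo[a] = max(0, idx[0] - m)
        hi[a] = min(volume.shape[a], idx[-1] + 1 + m)
    cropped = volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    new_origin = volume.origin + lo * volume.spacing
    return Volume(cropped.copy(), volume.spacing.copy(), new_origin), lo


def resample(volume: Volume, target_spacing_mm, interpolation: str = "linear") -> Volume:
    """Resample onto an axis-aligned grid with the requested spacing.

    The first voxel center is preserved and the output covers the original
    world extent to within one voxel.  ``linear`` for images, ``nearest`` for
    masks.
    """
    target = np.asarray(target_spacing_mm, dtype=float).reshape(3)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    if np.allclose(target, volume.spacing):
        return volume.copy()
    order = {"linear": 1, "nearest": 0}[interpolation]
    extent = (np.array(volume.shape) - 1) * volume.spacing
    new_shape = np.maximum(1, np.floor(extent / target + 1e-9).astype(int) + 1)
    # output voxel i sits at origin + i*target; map to input index space
    coords = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, volume.spacing)],
        indexing="ij",
    )
    vals = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float), np.stack(coords), order=order, mode="nearest"
    )
    return Volume(vals, target, volume.origin.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_nifti(volume: Volume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_nifti(path) -> Volume:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diagonal(rot)), atol=1e-6):
        raise ValueError(f"{path}: non-axis-aligned orientation is not supported")
    spacing = np.abs(np.diagonal(rot))
    return Volume(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])


# ---------------------------------------------------------------------------
# MITK point-set I/O
#
# The .mps format stores points by integer id; landmark names are written as
# an extra <label> element (ignored by MITK).  Files without labels are read
# back using the canonical landmark order.


def write_pointset(points: PointSet, path) -> None:
    root = ET.Element("point_set_file")
    ET.SubElement(root, "file_version").text = "0.1"
    pset = ET.SubElement(root, "point_set")
    ts = ET.SubElement(pset, "time_series")
    ET.SubElement(ts, "time_series_id").text = "0"
    for i, (name, coord) in enumerate(points.items()):
        pt = ET.SubElement(ts, "point")
        ET.SubElement(pt, "id").text = str(i)
        ET.SubElement(pt, "label").text = name
        ET.SubElement(pt, "specification").text = "0"
        for axis, value in zip("xyz", coord):
            ET.SubElement(pt, axis).text = repr(float(value))
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8")


def read_pointset(path) -> PointSet:
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed point-set file {path}: {exc}") from exc
    points = PointSet()
    elems = root.findall(".//point")
    for i, pt in enumerate(elems):
        label = pt.findtext("label")
        if label is None:
            idx = int(pt.findtext("id", default=str(i)))
            if idx >= len(ALL_LANDMARKS):
                raise ValueError(f"{path}: unlabeled point id {idx} exceeds canonical order")
            label = ALL_LANDMARKS[idx]
        try:
            coord = [float(pt.findtext(ax)) for ax in "xyz"]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed point in {path}: {exc}") from exc
        points[label] = coord
    return points


__all__ = [
    "NormalizationParams", "DEFAULT_NORMALIZATION",
    "normalize_ct", "crop_to_mask", "resample",
    "read_nifti", "write_nifti", "read_pointset", "write_pointset",
]
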