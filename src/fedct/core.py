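"""Core containers shared by every stage of the pipeline.

World coordinates are millimetres.  Voxel indices are 0-based and the world
position of voxel ``(i, j, k)`` is ``origin + index * spacing`` (identity
orientation throughout; files with a non-trivial direction are reoriented on
read).  Landmarks live in world mm everywhere; the voxel grid only appears
inside the label codec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

# Task identifiers and the fixed landmark channel order per task.
TASK_HCO = "HCO"  # hinge points + coronary ostia (5 landmarks)
TASK_MS = "MS"    # membranous septum (2 landmarks)
TASK_CALC = "CALC"  # calcification segmentation (1 channel)
TASKS = (TASK_HCO, TASK_MS, TASK_CALC)

HCO_LANDMARKS = ("RCC", "LCC", "NCC", "RCO", "LCO")
MS_LANDMARKS = ("MS1", "MS2")
ALL_LANDMARKS = HCO_LANDMARKS + MS_LANDMARKS

TASK_LANDMARKS = {TASK_HCO: HCO_LANDMARKS, TASK_MS: MS_LANDMARKS}
TASK_CHANNELS = {TASK_HCO: 5, TASK_MS: 2, TASK_CALC: 1}


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and world origin (both mm)."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"Volume values must be 3D, got shape {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a world-mm position."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (1D each)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing.copy(), self.origin.copy())

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


class PointSet:
    """Named anatomical landmarks in world mm.

    Behaves as a mapping name -> (3,) float array.  Missing landmarks are
    simply absent; every consumer must tolerate partial sets.
    """

    def __init__(self, points: Mapping[str, np.ndarray] | None = None):
        self._points: dict[str, np.ndarray] = {}
        if points:
            for name, coord in points.items():
                self[name] = coord

    def __setitem__(self, name: str, coord: np.ndarray) -> None:
        arr = np.asarray(coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite coordinate for landmark {name!r}: {arr}")
        self._points[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self._points[name]

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __iter__(self) -> Iterator[str]:
        return iter(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PointSet):
            return NotImplemented
        return self.names == other.names and all(
            np.array_equal(self[n], other[n]) for n in self
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._points)

    def get(self, name: str, default=None):
        return self._points.get(name, default)

    def items(self):
        return self._points.items()

    def subset(self, names) -> "PointSet":
        return PointSet({n: self._points[n] for n in names if n in self._points})

    def copy(self) -> "PointSet":
        return PointSet({n: c.copy() for n, c in self._points.items()})

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={c.round(2).tolist()}" for n, c in self.items())
        return f"PointSet({inner})"


@dataclass
class Label:
    """One task annotation attached to a sample.

    ``payload`` is a :class:`PointSet` for point tasks and a binary
    :class:`Volume` for segmentation tasks — identical format whether the
    label came from a human annotator or from a teacher network; only the
    provenance fields differ.
    """

    task: str
    payload: object
    source: str = "human"            # "human" | "pseudo"
    annotator: str | None = None
    teacher_id: str | None = None
    degenerate: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def is_pseudo(self) -> bool:
        return self.source == "pseudo"


@dataclass
class Sample:
    """One patient-equivalent: image, heart mask, labels, provenance.

    ``points_true``/``calc_true`` hold the generator's ground truth.  They
    exist purely for oracle evaluation and are never visible to any training
    stage, which read only :attr:`labels`.
    """

    sample_id: str
    client_id: str
    volume: Volume
    heart_mask: Volume
    points_true: PointSet
    calc_true: Volume
    labels: dict[str, Label] = field(default_factory=dict)
    # extra oracle-only masks (e.g. the blood-pool tube for transfer tasks)
    aux: dict = field(default_factory=dict)
    # cache of the normalized 2-channel network input, filled lazily
    _net_input: np.ndarray | None = field(default=None, repr=False, compare=False)

    def has_label(self, task: str, include_pseudo: bool = True) -> bool:
        lab = self.labels.get(task)
        if lab is None or lab.degenerate:
            return False
        return include_pseudo or not lab.is_pseudo

    def label_tasks(self, include_pseudo: bool = True) -> tuple[str, ...]:
        return tuple(t for t in TASKS if self.has_label(t, include_pseudo))


__all__ = [
    "TASK_HCO", "TASK_MS", "TASK_CALC", "TASKS",
    "HCO_LANDMARKS", "MS_LANDMARKS", "ALL_LANDMARKS",
    "TASK_LANDMARKS", "TASK_CHANNELS",
    "Volume", "PointSet", "Label", "Sample", "replace",
]
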