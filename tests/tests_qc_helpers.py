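"""Shared geometry helpers for QC tests."""

import numpy as np
from scipy.spatial.transform import Rotation

from fedct.core import PointSet
from fedct.geometry_qc import qc_records


def ideal_ring(r=10.0, center=(0, 0, 0), angles=(0.0, 120.0, 240.0)):
    c = np.asarray(center, dtype=float)
    pts = {}
    for name, a in zip(("RCC", "LCC", "NCC"), angles):
        t = np.radians(a)
        pts[name] = c + r * np.array([np.cos(t), np.sin(t), 0.0])
    pts["RCO"] = c + np.array([6.0, 0.0, 8.0])
    pts["LCO"] = c + np.array([-3.0, 5.0, 8.0])
    pts["MS1"] = c + np.array([4.0, -5.0, -2.0])
    pts["MS2"] = c + np.array([4.0, -5.0, -5.0])
    return PointSet(pts)


def rigid_move(points: PointSet, seed: int) -> PointSet:
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return PointSet({n: R @ c + t for n, c in points.items()})


def clean_records(seed: int, n_loc=5, n_per_loc=3, swap_loc=None):
    """Low-noise annotations across locations; optionally one location with
    its MS ids exchanged."""
    rng = np.random.default_rng(seed)
    records = []
    for li in range(n_loc):
        loc = f"L{li}"
        sets = []
        for _ in range(n_per_loc):
            pts = ideal_ring(angles=tuple(a + rng.normal(0, 0.3) for a in (0, 120, 240)))
            moved = {n: c + rng.normal(0, 0.05, 3) for n, c in pts.items()}
            if loc == swap_loc:
                moved["MS1"], moved["MS2"] = moved["MS2"], moved["MS1"]
            sets.append(PointSet(moved))
        records.extend(qc_records(loc, sets))
    return records
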