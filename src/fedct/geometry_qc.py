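"""Privacy-preserving label-geometry quality control.

Works on landmark coordinates only — no image voxels ever enter this module,
so annotations from different hospitals can be pooled and compared without
disclosing patient imagery.

Registration: the annulus plane is defined by the three hinge points; the
centroid is registered to the origin and the in-plane rotation is chosen to
minimize the summed squared angular distance of RCC/LCC/NCC from their
ideal directions at 0/120/240 degrees (assignment fixed by name, so id
mix-ups surface as large residuals instead of being hidden).  The plane
normal is oriented toward the coronary ostia (fallback: toward MS1), making
"up" well defined; MS1 is by definition the upper membranous-septum point,
so a registered MS1 below MS2 flags a suspected id swap.  Outliers are
flagged by a median-absolute-deviation rule on registered coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PointSet

IDEAL_ANGLES_DEG = {"RCC": 0.0, "LCC": 120.0, "NCC": 240.0}


def _wrap_deg(a):
    """Wrap to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


@dataclass
class CanonicalFrame:
    center: np.ndarray
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    rotation_deg: float
    residuals_deg: dict[str, float]

    def register(self, points: PointSet) -> dict[str, np.ndarray]:
        """Express points in the canonical (e1, e2, normal) frame."""
        basis = np.stack([self.e1, self.e2, self.normal])
        return {n: basis @ (c - self.center) for n, c in points.items()}


def optimal_rotation(delta_deg) -> tuple[float, np.ndarray]:
    """Minimize sum_i wrap(delta_i - phi)^2 over the in-plane rotation phi.

    ``delta_deg``: angular deviations of the hinge points from their ideal
    directions.  Coarse grid search picks the wrap configuration; the exact
    quadratic minimum is then closed-form (the mean of the wrapped
    deviations).  Returns (phi, residuals).
    """
    delta = np.atleast_1d(np.asarray(delta_deg, dtype=float))
    grid = np.arange(-180.0, 180.0, 0.25)
    res = _wrap_deg(delta[None, :] - grid[:, None])
    best = grid[np.argmin((res**2).sum(axis=1))]
    phi = best + float(np.mean(_wrap_deg(delta - best)))
    return float(_wrap_deg(phi)), _wrap_deg(delta - phi)


def fit_canonical_frame(points: PointSet) -> CanonicalFrame:
    """Fit the annulus frame from the three hinge points."""
    for n in IDEAL_ANGLES_DEG:
        if n not in points:
            raise ValueError(f"hinge point {n} is required to fit the annulus frame")
    p = {n: points[n] for n in IDEAL_ANGLES_DEG}
    center = np.mean(list(p.values()), axis=0)
    v1 = p["LCC"] - p["RCC"]
    v2 = p["NCC"] - p["RCC"]
    cr = np.cross(v1, v2)
    norm = np.linalg.norm(cr)
    if norm < 1e-9 * max(np.linalg.norm(v1), np.linalg.norm(v2), 1.0):
        raise ValueError("hinge points are collinear; annulus plane undefined")
    n = cr / norm
    # orient the normal toward the ostia side (fallback: toward MS1)
    ref = None
    ostia = [points[k] for k in ("RCO", "LCO") if k in points]
    if ostia:
        ref = np.mean(ostia, axis=0)
    elif "MS1" in points:
        ref = points["MS1"]
    if ref is not None and np.dot(n, ref - center) < 0:
        n = -n

    d = {k: v - center for k, v in p.items()}
    u0 = d["RCC"] - np.dot(d["RCC"], n) * n
    u0 = u0 / np.linalg.norm(u0)
    v0 = np.cross(n, u0)
    theta = {k: np.degrees(np.arctan2(np.dot(dd, v0), np.dot(dd, u0))) for k, dd in d.items()}
    delta = np.array([_wrap_deg(theta[k] - IDEAL_ANGLES_DEG[k]) for k in IDEAL_ANGLES_DEG])
    phi, residuals = optimal_rotation(delta)

    t = np.radians(phi)
    e1 = np.cos(t) * u0 + np.sin(t) * v0
    e2 = np.cross(n, e1)
    res_map = {k: float(r) for k, r in zip(IDEAL_ANGLES_DEG, residuals)}
    return CanonicalFrame(center=center, normal=n, e1=e1, e2=e2,
                          rotation_deg=float(_wrap_deg(phi)), residuals_deg=res_map)


def register_ms(points: PointSet) -> dict[str, np.ndarray]:
    """MS1/MS2 in the similarity frame of the RCC-NCC segment.

    Origin at the RCC-NCC midpoint, x along RCC->NCC, coordinates scaled by
    the RCC-NCC distance.  The out-of-plane axis comes from the annulus
    normal when LCC is available, else from the MS1 direction.
    """
    for nm in ("RCC", "NCC", "MS1", "MS2"):
        if nm not in points:
            raise ValueError(f"landmark {nm} is required for MS registration")
    rcc, ncc = points["RCC"], points["NCC"]
    seg = ncc - rcc
    s = np.linalg.norm(seg)
    if s < 1e-9:
        raise ValueError("RCC and NCC coincide; MS frame undefined")
    origin = (rcc + ncc) / 2.0
    x = seg / s
    if "LCC" in points:
        frame = fit_canonical_frame(points)
        z = frame.normal - np.dot(frame.normal, x) * x
    else:
        w = points["MS1"] - origin
        z = w - np.dot(w, x) * x
    zn = np.linalg.norm(z)
    if zn < 1e-12:
        raise ValueError("cannot orient the MS frame (degenerate reference)")
    z = z / zn
    y = np.cross(z, x)
    basis = np.stack([x, y, z])
    return {nm: basis @ (points[nm] - origin) / s for nm in ("MS1", "MS2")}


# ---------------------------------------------------------------------------
# QC records and anomaly rules


@dataclass
class QCRecord:
    location_id: str
    sample_id: str
    landmark: str
    coord: np.ndarray                     # registered canonical-frame coordinate (mm)
    group: str = "human"                  # "human" | "model"
    angular_residual_deg: float = float("nan")
    flags: list[str] = field(default_factory=list)


def qc_records(location_id: str, pointsets: list[PointSet], group: str = "human",
               sample_ids: list[str] | None = None) -> list[QCRecord]:
    """Register each point set to its own annulus frame and emit records."""
    out = []
    for i, ps in enumerate(pointsets):
        sid = sample_ids[i] if sample_ids else f"{location_id}-{i:04d}"
        frame = fit_canonical_frame(ps)
        reg = frame.register(ps)
        for name, coord in reg.items():
            out.append(
                QCRecord(
                    location_id=location_id,
                    sample_id=sid,
                    landmark=name,
                    coord=np.asarray(coord, dtype=float),
                    group=group,
                    angular_residual_deg=frame.residuals_deg.get(name, float("nan")),
                )
            )
    return out


def detect_anomalies(records: list[QCRecord], mad_multiple: float = 3.0,
                     min_deviation_mm: float = 0.5,
                     check_swaps: bool = True) -> list[QCRecord]:
    """Flag suspected MS id swaps and coordinate outliers (in place).

    Swap rule: within one (location, sample), MS1's coordinate along the
    annulus normal must not lie below MS2's (MS1 is the upper point).
    Outlier rule: a registered coordinate further from the per-landmark
    federation median than ``mad_multiple`` times the median absolute
    deviation (median distance from the median point).  The MAD rule alone
    is scale-free, so a floor of ``min_deviation_mm`` keeps sub-millimetre
    scatter from ever being flagged.
    """
    if check_swaps:
        by_sample: dict[tuple[str, str, str], dict[str, QCRecord]] = {}
        for r in records:
            if r.landmark in ("MS1", "MS2"):
                by_sample.setdefault((r.location_id, r.sample_id, r.group), {})[r.landmark] = r
        for pair in by_sample.values():
            if "MS1" in pair and "MS2" in pair:
                if pair["MS1"].coord[2] < pair["MS2"].coord[2]:
                    for r in pair.values():
                        if "id-swap-suspect" not in r.flags:
                            r.flags.append("id-swap-suspect")
    by_landmark: dict[tuple[str, str], list[QCRecord]] = {}
    for r in records:
        by_landmark.setdefault((r.group, r.landmark), []).append(r)
    for recs in by_landmark.values():
        coords = np.stack([r.coord for r in recs])
        med = np.median(coords, axis=0)
        d = np.linalg.norm(coords - med, axis=1)
        mad = float(np.median(d))
        cut = max(mad_multiple * mad, min_deviation_mm)
        for r, di in zip(recs, d):
            if di > cut and "outlier" not in r.flags:
                r.flags.append("outlier")
    return [r for r in records if r.flags]


def qc_report(records: list[QCRecord], out_dir=None, mad_multiple: float = 3.0) -> pd.DataFrame:
    """Per-location scatter summaries and flags — coordinates only.

    Returns a tidy table; when ``out_dir`` is given, writes it as CSV along
    with canonical-frame scatter figures (one overlay per group).
    """
    detect_anomalies(records, mad_multiple=mad_multiple)
    df = pd.DataFrame(
        {
            "location": r.location_id,
            "sample": r.sample_id,
            "group": r.group,
            "landmark": r.landmark,
            "x": r.coord[0],
            "y": r.coord[1],
            "z": r.coord[2],
            "angular_residual_deg": r.angular_residual_deg,
            "flags": ";".join(r.flags),
        }
        for r in records
    )
    if out_dir is not None:
        from pathlib import Path
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "qc_registered_coordinates.csv", index=False)
        for group, gdf in df.groupby("group"):
            fig, axes = plt.subplots(1, 2, figsize=(11, 5))
            for name, ldf in gdf[gdf.landmark.isin(IDEAL_ANGLES_DEG)].groupby("landmark"):
                axes[0].scatter(ldf.x, ldf.y, s=12, label=name, alpha=0.6)
            axes[0].set_title(f"hinge points, annulus frame ({group})")
            axes[0].set_xlabel("mm")
            axes[0].set_ylabel("mm")
            axes[0].axis("equal")
            axes[0].legend()
            ms = gdf[gdf.landmark.isin(("MS1", "MS2"))]
            for name, ldf in ms.groupby("landmark"):
                axes[1].scatter(ldf.x, ldf.z, s=12, label=name, alpha=0.6)
            axes[1].set_title(f"membranous septum ({group})")
            axes[1].set_xlabel("mm")
            axes[1].set_ylabel("mm (annulus normal)")
            axes[1].legend()
            fig.tight_layout()
            fig.savefig(out / f"qc_scatter_{group}.png", dpi=120)
            plt.close(fig)
    return df


def spread_statistic(records: list[QCRecord], group: str) -> float:
    """Mean registered distance from the per-landmark centroid."""
    by_landmark: dict[str, list[np.ndarray]] = {}
    for r in records:
        if r.group == group:
            by_landmark.setdefault(r.landmark, []).append(r.coord)
    dists = []
    for coords in by_landmark.values():
        arr = np.stack(coords)
        c = arr.mean(axis=0)
        dists.extend(np.linalg.norm(arr - c, axis=1))
    return float(np.mean(dists))


__all__ = [
    "CanonicalFrame", "QCRecord", "fit_canonical_frame", "optimal_rotation", "register_ms",
    "qc_records", "detect_anomalies", "qc_report", "spread_statistic",
    "IDEAL_ANGLES_DEG",
]
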