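"""Metrics and result tables.

Point tasks are scored as Euclidean distance in world mm per landmark;
segmentation as Dice overlap.  Results are aggregated into two splits per
task and model tag: the local test sets of the clients a model was trained
on ("training") and the samples of held-out clients ("other").  Pooling is
over samples, not over client means (configurable), and the table reports
mean +/- sd per (task, model tag, split).

Inter-observer variability is the distance of each annotator's landmark
from the across-annotator mean landmark, pooled over landmarks and samples.
For k annotators with isotropic Gaussian scatter sigma the expected value is
sigma * 2*sqrt(2/pi) * sqrt((k-1)/k), which the simulation tests check
against a Monte-Carlo oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PointSet, Volume


@dataclass
class MetricsRecord:
    task: str
    model_tag: str
    client_id: str
    split: str  # "training" | "other"
    sample_id: str
    value: float
    missing: int = 0  # landmarks absent in the prediction


def point_error_mm(pred: PointSet, truth: PointSet) -> tuple[dict[str, float], float, list[str]]:
    """Per-landmark Euclidean distance in mm over the shared names.

    Landmarks present in truth but absent in pred are reported as missing
    and excluded from the mean (but counted).
    """
    shared = [n for n in truth if n in pred]
    missing = [n for n in truth if n not in pred]
    if not shared:
        raise ValueError("no shared landmarks between prediction and truth")
    dists = {n: float(np.linalg.norm(pred[n] - truth[n])) for n in shared}
    return dists, float(np.mean(list(dists.values()))), missing


def dice(pred: Volume, truth: Volume) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks score 1.0."""
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    a = np.asarray(pred.values) > 0
    b = np.asarray(truth.values) > 0
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def aggregate_results(records: list[MetricsRecord], pooling: str = "samples") -> pd.DataFrame:
    """Mean +/- sd per (task, model tag, split).

    ``pooling="samples"`` pools every per-sample value across clients within
    a split; ``pooling="clients"`` averages client means weighted equally.
    """
    if not records:
        return pd.DataFrame(columns=["task", "model_tag", "split", "mean", "sd", "n", "n_missing"])
    df = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for (task, tag, split), grp in df.groupby(["task", "model_tag", "split"], sort=True):
        if pooling == "samples":
            vals = grp["value"].to_numpy(dtype=float)
        elif pooling == "clients":
            vals = grp.groupby("client_id")["value"].mean().to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        rows.append(
            {
                "task": task,
                "model_tag": tag,
                "split": split,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
                "n_missing": int(grp["missing"].sum()),
            }
        )
    return pd.DataFrame(rows)


def interobserver(annotations: dict[str, dict[str, PointSet]]) -> tuple[float, float, pd.DataFrame]:
    """Distance-from-mean across annotators.

    ``annotations``: annotator id -> sample id -> PointSet.  For each
    (sample, landmark) with >= 2 annotators, each annotator's distance from
    the across-annotator mean point enters the pool.  Returns overall mean,
    sd, and the per-annotator breakdown.
    """
    if len(annotations) < 2:
        raise ValueError("inter-observer analysis needs >= 2 annotators")
    sample_ids = sorted({sid for per in annotations.values() for sid in per})
    rows = []
    for sid in sample_ids:
        present = {a: ps[sid] for a, ps in annotations.items() if sid in ps}
        names = sorted({n for ps in present.values() for n in ps})
        for name in names:
            coords = {a: ps[name] for a, ps in present.items() if name in ps}
            if len(coords) < 2:
                continue
            center = np.mean(list(coords.values()), axis=0)
            for a, c in coords.items():
                rows.append(
                    {"annotator": a, "sample_id": sid, "landmark": name,
                     "distance_mm": float(np.linalg.norm(c - center))}
                )
    if not rows:
        raise ValueError("no (sample, landmark) pair has >= 2 annotators")
    df = pd.DataFrame(rows)
    return float(df["distance_mm"].mean()), float(df["distance_mm"].std(ddof=1)), df


def expected_distance_from_mean(sigma: float, k: int) -> float:
    """Closed-form expectation for k annotators with isotropic 3D noise."""
    return sigma * 2.0 * np.sqrt(2.0 / np.pi) * np.sqrt((k - 1) / k)


__all__ = [
    "MetricsRecord", "point_error_mm", "dice", "aggregate_results",
    "interobserver", "expected_distance_from_mean",
]
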