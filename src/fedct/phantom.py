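"""Synthetic cardiac-CT phantom federation.

The phantom is a stylised aortic root: a contrast-filled cylinder (blood
pool) whose axis is the annulus normal, three hinge points (RCC, LCC, NCC)
on a ring in the annulus plane at nominally 120 deg spacing, two coronary
ostia above the plane, two membranous-septum points below the RCC-NCC
midpoint, and a handful of high-HU calcific blobs near the ring.  It is a
proxy, not a deformable heart model: what it must reproduce faithfully is
the *label structure* of a multi-centre federation — skewed per-client
label availability, per-annotator bias and scatter, occasional MS1/MS2 id
swaps, large unlabeled fractions — so that every training stage can be
exercised and scored against known ground truth.

Random streams are split hierarchically (federation seed -> client seed ->
sample seed), so adding a client never changes another client's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    ALL_LANDMARKS,
    HCO_LANDMARKS,
    MS_LANDMARKS,
    TASK_CALC,
    TASK_HCO,
    TASK_MS,
    TASKS,
    Label,
    PointSet,
    Sample,
    Volume,
)
from .federation import ClientShard, FederationPlan


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    annulus_radius_mm: float = 12.0
    annulus_center_mm: tuple[float, float, float] = (32.0, 32.0, 28.0)
    ostia_height_mm: float = 8.0
    ms_offset_mm: tuple[float, float, float] = (0.0, -5.0, -2.0)
    ms_gap_mm: float = 4.0
    hu_background: float = -50.0
    hu_blood: float = 300.0
    hu_calc: float = 900.0
    noise_sd_hu: float = 25.0
    n_calc_blobs: int = 3
    calc_radius_range_mm: tuple[float, float] = (1.5, 3.0)
    jitter_deg: float = 5.0
    center_jitter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.annulus_radius_mm <= 0:
            raise ValueError("annulus_radius_mm must be positive")
        if self.calc_radius_range_mm[0] > self.calc_radius_range_mm[1]:
            raise ValueError("calc_radius_range_mm must be (min, max) with min <= max")
        if not (self.hu_calc > self.hu_blood > self.hu_background):
            raise ValueError(
                "intensities must satisfy hu_calc > hu_blood > hu_background "
                f"(got {self.hu_calc}, {self.hu_blood}, {self.hu_background})"
            )

    def check_fits(self) -> None:
        """The annulus ring (plus jitter and blob extent) must fit the grid."""
        reach = self.annulus_radius_mm + self.calc_radius_range_mm[1] + self.center_jitter_mm
        for a, name in enumerate("xyz"):
            extent = (self.grid_shape[a] - 1) * self.spacing_mm[a]
            c = self.annulus_center_mm[a]
            if a < 2:
                lo, hi = c - reach, c + reach
            else:
                lo = c + min(self.ms_offset_mm[2] - self.ms_gap_mm, 0) - reach / 2
                hi = c + self.ostia_height_mm + self.center_jitter_mm
            if lo < 0 or hi > extent:
                raise ValueError(
                    f"grid too small along {name}: structures span [{lo:.1f}, {hi:.1f}] mm "
                    f"but axis extent is [0, {extent:.1f}] mm"
                )


def _ideal_angles() -> dict[str, float]:
    # fixed name -> angle assignment; RCC at 0, LCC at 120, NCC at 240 deg
    return {"RCC": 0.0, "LCC": 120.0, "NCC": 240.0}


def make_phantom(config: PhantomConfig, seed: int, sample_id: str = "phantom", client_id: str = "") -> Sample:
    """Generate one phantom sample with ground-truth landmarks and masks.

    Deterministic given ``(config, seed)``.
    """
    config.check_fits()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, seed & 0x7FFFFFFF]))
    spacing = np.asarray(config.spacing_mm, dtype=float)
    shape = tuple(config.grid_shape)

    center = np.asarray(config.annulus_center_mm, dtype=float) + rng.uniform(
        -config.center_jitter_mm, config.center_jitter_mm, size=3
    )
    r = config.annulus_radius_mm

    # --- landmarks -------------------------------------------------------
    points = PointSet()
    angles = {}
    for name, ideal in _ideal_angles().items():
        ang = ideal + (rng.uniform(-config.jitter_deg, config.jitter_deg) if config.jitter_deg else 0.0)
        angles[name] = ang
        t = np.deg2rad(ang)
        points[name] = center + r * np.array([np.cos(t), np.sin(t), 0.0])
    for name, ref in (("RCO", "RCC"), ("LCO", "LCC")):
        t = np.deg2rad(angles[ref])
        points[name] = center + 0.8 * r * np.array([np.cos(t), np.sin(t), 0.0]) + np.array(
            [0.0, 0.0, config.ostia_height_mm]
        )
    mid = (points["RCC"] + points["NCC"]) / 2.0
    ms1 = mid + np.asarray(config.ms_offset_mm, dtype=float)
    points["MS1"] = ms1
    points["MS2"] = ms1 - np.array([0.0, 0.0, config.ms_gap_mm])

    # --- voxel grid ------------------------------------------------------
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    values = np.full(shape, config.hu_background, dtype=float)

    radial = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
    z_lo = center[2] - 4.0 - max(0.0, -config.ms_offset_mm[2]) - config.ms_gap_mm
    z_hi = center[2] + config.ostia_height_mm + 4.0
    blood = (radial <= r + 2.0) & (Z >= z_lo) & (Z <= z_hi)
    values[blood] = config.hu_blood

    calc = np.zeros(shape, dtype=bool)
    for _ in range(config.n_calc_blobs):
        t = np.deg2rad(rng.uniform(0.0, 360.0))
        rr = r + rng.uniform(-2.0, 2.0)
        bc = center + np.array([rr * np.cos(t), rr * np.sin(t), rng.uniform(-2.0, 2.0)])
        br = rng.uniform(*config.calc_radius_range_mm)
        blob = (X - bc[0]) ** 2 + (Y - bc[1]) ** 2 + (Z - bc[2]) ** 2 <= br**2
        calc |= blob
    values[calc] = config.hu_calc

    heart = (radial <= r + 8.0) & (Z >= z_lo - 6.0) & (Z <= z_hi + 6.0)
    heart |= calc  # heart mask must cover every foreground structure
    heart |= blood

    if config.noise_sd_hu > 0:
        values = values + rng.normal(0.0, config.noise_sd_hu, size=shape)

    origin = np.zeros(3)
    return Sample(
        sample_id=sample_id,
        client_id=client_id,
        volume=Volume(values, spacing, origin),
        heart_mask=Volume(heart.astype(np.float32), spacing, origin),
        points_true=points,
        calc_true=Volume(calc.astype(np.float32), spacing, origin),
        aux={"blood": Volume(blood.astype(np.float32), spacing, origin)},
    )


# ---------------------------------------------------------------------------
# Annotator model


@dataclass
class AnnotatorModel:
    """Systematic bias + isotropic scatter + occasional MS1/MS2 id swap."""

    annotator_id: str = "annotator"
    bias_mm: object = (0.0, 0.0, 0.0)  # 3-vector or mapping landmark -> 3-vector
    noise_sd_mm: float = 0.0
    swap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if not 0.0 <= self.swap_prob <= 1.0:
            raise ValueError("swap_prob must lie in [0, 1]")

    def bias_for(self, name: str) -> np.ndarray:
        if isinstance(self.bias_mm, Mapping):
            return np.asarray(self.bias_mm.get(name, (0.0, 0.0, 0.0)), dtype=float)
        return np.asarray(self.bias_mm, dtype=float)


def perturb_annotation(points: PointSet, model: AnnotatorModel, seed: int = 0) -> PointSet:
    """Emulate one human annotation of ``points``.

    Each present landmark is displaced by the annotator's bias plus isotropic
    Gaussian scatter; with probability ``swap_prob`` the MS1/MS2 names are
    exchanged.  Absent landmarks pass through absent.  Deterministic given
    (model.seed, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([model.seed & 0x7FFFFFFF, seed & 0x7FFFFFFF]))
    out = PointSet()
    # canonical order so the draw sequence is independent of dict ordering
    for name in ALL_LANDMARKS:
        if name not in points:
            continue
        noise = rng.normal(0.0, 1.0, size=3) * model.noise_sd_mm
        out[name] = points[name] + model.bias_for(name) + noise
    for name in points:
        if name not in out:  # non-canonical extra names
            out[name] = points[name] + model.bias_for(name) + rng.normal(0.0, model.noise_sd_mm, 3)
    if "MS1" in out and "MS2" in out and rng.uniform() < model.swap_prob:
        out["MS1"], out["MS2"] = out["MS2"].copy(), out["MS1"].copy()
    return out


# ---------------------------------------------------------------------------
# Federation specification and generation


@dataclass
class ClientSpec:
    client_id: str
    n_total: int
    labeled: dict[str, int] = field(default_factory=dict)  # task -> count

    def __post_init__(self) -> None:
        for task, k in self.labeled.items():
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
            if k > self.n_total:
                raise ValueError(
                    f"client {self.client_id}: labeled count {k} for {task} exceeds total {self.n_total}"
                )


@dataclass
class FederationSpec:
    clients: list[ClientSpec]
    test_fraction: float = 0.2
    held_out_clients: dict[str, tuple[str, ...]] = field(default_factory=dict)
    expected_totals: dict[str, int] | None = None  # {"volumes": N, task: N, ...}

    def __post_init__(self) -> None:
        ids = [c.client_id for c in self.clients]
        if len(set(ids)) != len(ids):
            raise ValueError("client ids must be unique")
        by_id = {c.client_id: c for c in self.clients}
        for task in TASKS:
            held = self.held_out_clients.get(task, ())
            for cid in held:
                if cid not in by_id:
                    raise ValueError(f"held-out client {cid!r} for {task} is not in the federation")
                if by_id[cid].labeled.get(task, 0) == 0:
                    raise ValueError(
                        f"held-out client {cid!r} has zero labeled samples for {task} "
                        "and cannot serve as a test client"
                    )
            train = [c.client_id for c in self.clients if c.labeled.get(task, 0) > 0 and c.client_id not in held]
            if not train:
                raise ValueError(f"task {task} has no training client")
            if not held:
                raise ValueError(f"task {task} has no held-out client")
        if self.expected_totals is not None:
            actual = self.count_table()
            for key, expected in self.expected_totals.items():
                if actual[key] != expected:
                    raise ValueError(
                        f"declared federation total for {key!r} is {expected} "
                        f"but client counts sum to {actual[key]}"
                    )

    def count_table(self) -> dict[str, int]:
        table = {"volumes": sum(c.n_total for c in self.clients)}
        for task in TASKS:
            table[task] = sum(c.labeled.get(task, 0) for c in self.clients)
        return table


def plan_federation(spec: FederationSpec, rounds: int = 20, epochs: int = 10,
                    weighting: str = "sample-count") -> FederationPlan:
    """Derive the per-task training/held-out topology from a spec.

    Pure bookkeeping — no volumes are generated, so this also works for the
    full-scale (8104-volume) federation shape.
    """
    train: dict[str, tuple[str, ...]] = {}
    held: dict[str, tuple[str, ...]] = {}
    for task in TASKS:
        h = tuple(spec.held_out_clients.get(task, ()))
        held[task] = h
        train[task] = tuple(
            c.client_id for c in spec.clients if c.labeled.get(task, 0) > 0 and c.client_id not in h
        )
    return FederationPlan(
        train_clients=train,
        held_out_clients=held,
        rounds=rounds,
        epochs=epochs,
        weighting=weighting,
    )


def _client_entropy(client_id: str) -> int:
    return zlib.crc32(client_id.encode()) & 0x7FFFFFFF


def make_federation(
    spec: FederationSpec,
    phantom_config: PhantomConfig,
    annotators: Mapping[str, AnnotatorModel],
    seed: int,
    rounds: int = 20,
    epochs: int = 10,
) -> tuple[list[ClientShard], FederationPlan]:
    """Materialise a phantom federation: per-client samples, human labels on
    exactly the declared counts, a fixed local train/test split, and the
    per-task training topology."""
    plan = plan_federation(spec, rounds=rounds, epochs=epochs)
    shards = []
    for client in spec.clients:
        crng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, _client_entropy(client.client_id)])
        )
        annot = annotators.get(client.client_id, AnnotatorModel(annotator_id=f"ann-{client.client_id}"))
        n = client.n_total
        sample_seeds = crng.integers(0, 2**31 - 1, size=n)
        samples = [
            make_phantom(
                phantom_config,
                int(sample_seeds[i]),
                sample_id=f"{client.client_id}-{i:04d}",
                client_id=client.client_id,
            )
            for i in range(n)
        ]
        labeled_idx: dict[str, tuple[int, ...]] = {}
        for task in TASKS:
            k = client.labeled.get(task, 0)
            idx = tuple(sorted(map(int, crng.choice(n, size=k, replace=False)))) if k else ()
            labeled_idx[task] = idx
            for i in idx:
                s = samples[i]
                if task == TASK_CALC:
                    payload: object = s.calc_true.copy()
                else:
                    names = HCO_LANDMARKS if task == TASK_HCO else MS_LANDMARKS
                    truth = s.points_true.subset(names)
                    task_tag = zlib.crc32(task.encode()) % (2**20)
                    payload = perturb_annotation(truth, annot, seed=int(sample_seeds[i]) ^ task_tag)
                s.labels[task] = Label(task=task, payload=payload, source="human", annotator=annot.annotator_id)
        perm = crng.permutation(n)
        n_test = int(round(spec.test_fraction * n))
        test_idx = tuple(sorted(map(int, perm[:n_test])))
        train_idx = tuple(sorted(map(int, perm[n_test:])))
        shards.append(
            ClientShard(
                client_id=client.client_id,
                samples=samples,
                train_idx=train_idx,
                test_idx=test_idx,
                labeled_idx=labeled_idx,
            )
        )
    return shards, plan


# ---------------------------------------------------------------------------
# Presets


def consortium_spec() -> FederationSpec:
    """Eight-location federation with the consortium label-count structure:
    8104 volumes, 251 HCO labels over 7 locations, 116 MS over 3, 118 CALC
    over 3; held-out locations 6+7 (HCO), 7 (MS), 6 (CALC)."""
    volumes = [1200, 900, 3001, 700, 20, 800, 733, 750]
    hco = [78, 40, 35, 28, 0, 25, 20, 25]
    ms = [0, 73, 0, 23, 0, 0, 20, 0]
    calc = [78, 0, 20, 0, 0, 20, 0, 0]
    clients = []
    for i in range(8):
        labeled = {}
        if hco[i]:
            labeled[TASK_HCO] = hco[i]
        if ms[i]:
            labeled[TASK_MS] = ms[i]
        if calc[i]:
            labeled[TASK_CALC] = calc[i]
        clients.append(ClientSpec(client_id=f"L{i + 1}", n_total=volumes[i], labeled=labeled))
    return FederationSpec(
        clients=clients,
        test_fraction=0.2,
        held_out_clients={TASK_HCO: ("L6", "L7"), TASK_MS: ("L7",), TASK_CALC: ("L6",)},
        expected_totals={"volumes": 8104, TASK_HCO: 251, TASK_MS: 116, TASK_CALC: 118},
    )


def tiny_spec() -> FederationSpec:
    """Desk-scale federation: 4 clients x 12 volumes, skewed labels, client D
    held out for every task."""
    clients = [
        ClientSpec("A", 12, {TASK_HCO: 5, TASK_MS: 4}),
        ClientSpec("B", 12, {TASK_HCO: 5, TASK_CALC: 5}),
        ClientSpec("C", 12, {TASK_HCO: 4, TASK_MS: 4, TASK_CALC: 4}),
        ClientSpec("D", 12, {TASK_HCO: 4, TASK_MS: 3, TASK_CALC: 4}),
    ]
    return FederationSpec(
        clients=clients,
        test_fraction=0.25,
        held_out_clients={TASK_HCO: ("D",), TASK_MS: ("D",), TASK_CALC: ("D",)},
    )


def default_annotators(spec: FederationSpec, noise_sd_mm: float = 1.5,
                       bias_scale_mm: float = 1.0, swap_prob: float = 0.0,
                       seed: int = 17) -> dict[str, AnnotatorModel]:
    """One annotator per client with a small client-specific systematic bias."""
    rng = np.random.default_rng(seed)
    out = {}
    for c in spec.clients:
        out[c.client_id] = AnnotatorModel(
            annotator_id=f"ann-{c.client_id}",
            bias_mm=tuple(rng.normal(0.0, bias_scale_mm, 3)),
            noise_sd_mm=noise_sd_mm,
            swap_prob=swap_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return out


__all__ = [
    "PhantomConfig", "AnnotatorModel", "ClientSpec", "FederationSpec",
    "make_phantom", "perturb_annotation", "make_federation", "plan_federation",
    "consortium_spec", "tiny_spec", "default_annotators",
]
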