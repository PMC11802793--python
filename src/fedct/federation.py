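"""In-process simulation of the hub-and-spoke federation.

Clients train sequentially with isolated random streams (simulating the
parallel hub-and-spoke topology while staying bit-reproducible on one
machine).  Each federated round broadcasts the server state, runs local
training on every participating client, and averages the returned states.
Aggregation weights default to each client's labeled training-sample count;
uniform weighting is available.  Before averaging, the (state, weight) pairs
are put into a canonical order (by weight, then state checksum), which makes
the aggregate exactly invariant to client permutation despite floating-point
non-associativity.

No networking, TLS, or authentication: trust is simulated, matching an
honest-environment assumption.
"""

from __future__ import annotations

import zlib
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from .core import Sample
from .labelcodec import DEFAULT_ENCODING, HeatmapEncoding
from .models import (
    AdamW,
    ModelState,
    TeacherConfig,
    TeacherNet,
    ds_loss,
    sample_targets,
)
from .preprocess import DEFAULT_NORMALIZATION, normalize_ct


@dataclass
class FederationPlan:
    train_clients: dict[str, tuple[str, ...]]
    held_out_clients: dict[str, tuple[str, ...]]
    rounds: int = 20
    epochs: int = 10
    weighting: str = "sample-count"  # "sample-count" | "uniform"

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.epochs < 1:
            raise ValueError("rounds and epochs must be >= 1")
        for task in self.train_clients:
            overlap = set(self.train_clients[task]) & set(self.held_out_clients.get(task, ()))
            if overlap:
                raise ValueError(f"task {task}: clients {overlap} are both training and held-out")


@dataclass
class ClientShard:
    client_id: str
    samples: list[Sample]
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    labeled_idx: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.samples)
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train/test split must be disjoint")
        if sorted(self.train_idx + self.test_idx) != list(range(n)):
            raise ValueError("train/test split must be exhaustive")
        for task, idx in self.labeled_idx.items():
            for i in idx:
                if task not in self.samples[i].labels:
                    raise ValueError(f"sample {i} listed as labeled for {task} but carries no label")

    def labeled_train(self, task: str) -> list[int]:
        train = set(self.train_idx)
        return [i for i in self.labeled_idx.get(task, ()) if i in train]

    def labeled_test(self, task: str) -> list[int]:
        test = set(self.test_idx)
        return [i for i in self.labeled_idx.get(task, ()) if i in test]


def model_input(sample: Sample) -> np.ndarray:
    """Normalized CT + heart mask as the 2-channel network input (cached)."""
    if sample._net_input is None:
        norm = normalize_ct(sample.volume, DEFAULT_NORMALIZATION)
        sample._net_input = np.stack(
            [norm.values, np.asarray(sample.heart_mask.values, dtype=float)]
        )
    return sample._net_input


# ---------------------------------------------------------------------------
# FedAvg


def _state_key(state: ModelState) -> str:
    return state.checksum()


def fedavg(states: list[ModelState], weights: list[float]) -> ModelState:
    """Weighted parameter mean: theta = sum_i w_i theta_i / sum_i w_i."""
    if not states:
        raise ValueError("fedavg needs at least one state")
    if len(weights) != len(states):
        raise ValueError("one weight per state required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    ref = states[0]
    for s in states[1:]:
        if list(s.params.keys()) != list(ref.params.keys()):
            extra = set(s.params) ^ set(ref.params)
            name = sorted(extra)[0] if extra else "<ordering>"
            raise ValueError(f"state signature mismatch at parameter {name!r}")
        for name in ref.params:
            if s.params[name].shape != ref.params[name].shape:
                raise ValueError(f"state signature mismatch at parameter {name!r}")
    if len(states) == 1:
        return states[0].copy()
    # canonical order -> exact permutation invariance of the fp sum
    order = sorted(range(len(states)), key=lambda i: (w[i], _state_key(states[i])))
    total = float(w.sum())
    params: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for name in ref.params:
        acc = np.zeros_like(ref.params[name], dtype=float)
        for i in order:
            acc += w[i] * states[i].params[name]
        params[name] = acc / total
    return ModelState(params, dict(ref.partitions), ref.config_hash)


# ---------------------------------------------------------------------------
# local training (Stage 1: one task-specific teacher per client)


def local_train(
    config: TeacherConfig,
    state: ModelState,
    shard: ClientShard,
    task: str,
    epochs: int,
    seed: int,
    enc: HeatmapEncoding = DEFAULT_ENCODING,
    audit: list[str] | None = None,
) -> tuple[ModelState, list[float]]:
    """Train a teacher on the shard's human-labeled training samples.

    Pure function of (config, state, shard, task, epochs, seed).  Returns the
    updated state and the per-epoch mean loss trace.
    """
    if task != config.task:
        raise ValueError(f"teacher config is for task {config.task}, not {task}")
    idx = shard.labeled_train(task)
    if not idx:
        raise ValueError(f"client {shard.client_id} has no labeled training samples for {task}")
    net = TeacherNet(config, seed=0)
    net.load_state(state)
    if epochs == 0:
        return net.state(), []
    opt = AdamW(net.params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(idx))
        losses = []
        for j in order:
            sample = shard.samples[idx[j]]
            if audit is not None:
                audit.append(sample.sample_id)
            targets = sample_targets(sample, enc, include_pseudo=False)
            if task not in targets:
                continue
            preds = net.forward(model_input(sample))
            tgt, soft = targets[task]
            loss = ds_loss(preds, tgt, soft=soft)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if not losses:
            raise ValueError(f"client {shard.client_id}: no usable {task} targets")
        trace.append(float(np.mean(losses)))
    return net.state(), trace


# ---------------------------------------------------------------------------
# Stage 1 orchestration


def stage1_init_seed(seed: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA11CE]).generate_state(1)[0] % (2**31))


def stage1_client_seed(seed: int, round_idx: int, client_id: str) -> int:
    ent = zlib.crc32(client_id.encode()) & 0x7FFFFFFF
    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, round_idx, ent]).generate_state(1)[0] % (2**31)
    )


def run_stage1(
    plan: FederationPlan,
    shards: list[ClientShard],
    task: str,
    config: TeacherConfig,
    seed: int,
    enc: HeatmapEncoding = DEFAULT_ENCODING,
) -> tuple[ModelState, dict]:
    """Federated teacher training for one task.

    Each round: broadcast the server state, run ``plan.epochs`` local epochs
    on every training client, average with the plan's weighting.  Held-out
    clients are never read.
    """
    by_id = {s.client_id: s for s in shards}
    train_clients = plan.train_clients[task]
    if not train_clients:
        raise ValueError(f"no training clients for task {task}")
    for cid in train_clients:
        if cid not in by_id:
            raise ValueError(f"training client {cid!r} has no shard")
    _, state = _build(config, stage1_init_seed(seed))
    audit: list[str] = []
    log: dict = {"task": task, "rounds": [], "clients": list(train_clients)}
    for r in range(plan.rounds):
        states, weights, traces = [], [], {}
        for cid in train_clients:
            shard = by_id[cid]
            s2, trace = local_train(
                config, state, shard, task, plan.epochs,
                stage1_client_seed(seed, r, cid), enc, audit=audit,
            )
            states.append(s2)
            weights.append(len(shard.labeled_train(task)) if plan.weighting == "sample-count" else 1.0)
            traces[cid] = trace
        state = fedavg(states, weights)
        log["rounds"].append({"round": r, "weights": list(map(float, weights)), "loss": traces})
    log["samples_read"] = sorted(set(audit))
    return state, log


def _build(config: TeacherConfig, seed: int):
    from .models import build_teacher
    return build_teacher(config, seed=seed)


__all__ = [
    "FederationPlan", "ClientShard", "model_input", "fedavg", "local_train",
    "run_stage1", "stage1_init_seed", "stage1_client_seed",
]
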