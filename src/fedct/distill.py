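"""Stages 1B, 2A, 2B and the downstream transfer.

1B  Every trained per-task teacher predicts on every sample that lacks a
    human label for its task; the decoded hard prediction (point set or
    binary mask) is attached as a pseudo-label.  Human labels are never
    overwritten; provenance is recorded; degenerate teacher outputs are
    flagged and excluded from distillation rather than imputed.
2A  The three-head student is trained federated over **all** clients on the
    pseudo-labeled (and, by default, also the human-labeled) training
    samples with task-routed loss.
2B  Each prediction head is finetuned federated per task on human labels
    only, with every backbone parameter frozen bitwise.
Transfer  A fresh 1x1x1 output convolution is trained on a new single-target
    segmentation task over frozen backbone features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import TASK_CALC, TASKS, Label, Sample, Volume
from .federation import ClientShard, FederationPlan, fedavg, model_input, stage1_client_seed, stage1_init_seed
from .labelcodec import DEFAULT_ENCODING, HeatmapEncoding, binarize_mask, decode_points, task_landmarks
from .models import (
    AdamW,
    ModelState,
    StudentConfig,
    StudentNet,
    TeacherConfig,
    TeacherNet,
    routed_loss,
    sample_targets,
)


# ---------------------------------------------------------------------------
# inference helpers


def _prob(logits: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-logits))


def teacher_predict(net: TeacherNet, sample: Sample, enc: HeatmapEncoding = DEFAULT_ENCODING,
                    min_peak: float = 0.25):
    """Hard prediction of a teacher on one sample.

    Returns (payload, degenerate, warnings): a PointSet for point tasks or a
    binary mask Volume for segmentation.
    """
    task = net.config.task
    prob = _prob(net.forward(model_input(sample))[0].data)
    if task == TASK_CALC:
        return binarize_mask(prob, sample.volume, threshold=0.5), False, []
    peaks = prob.reshape(prob.shape[0], -1).max(axis=1)
    points, warns = decode_points(prob, sample.volume, enc, task)
    degenerate = bool((peaks < min_peak).any()) or len(points) < len(task_landmarks(task))
    return points, degenerate, warns


def student_predict(net: StudentNet, sample: Sample, enc: HeatmapEncoding = DEFAULT_ENCODING):
    """Hard predictions of the multi-head student for all three tasks."""
    outputs = net.forward(model_input(sample))
    result = {}
    for task, tensor in outputs.items():
        prob = _prob(tensor.data)
        if task == TASK_CALC:
            result[task] = binarize_mask(prob, sample.volume, threshold=0.5)
        else:
            points, _ = decode_points(prob, sample.volume, enc, task)
            result[task] = points
    return result


# ---------------------------------------------------------------------------
# Stage 1B: pseudo-labels


def generate_pseudo_labels(
    teachers: dict[str, tuple[TeacherConfig, ModelState]],
    shards: list[ClientShard],
    enc: HeatmapEncoding = DEFAULT_ENCODING,
    min_peak: float = 0.25,
) -> dict[str, int]:
    """Attach teacher predictions as pseudo-labels to unlabeled samples.

    ``min_peak``: a point channel whose peak probability stays below this is
    considered degenerate (no confident landmark) and the pseudo-label is
    flagged and excluded from Stage 2A for that task.  Returns per-task
    counts of generated pseudo-labels.
    """
    for task, (config, _) in teachers.items():
        if config.task != task:
            raise ValueError(f"teacher for {task} is configured for {config.task}")
    nets = {}
    for task, (config, state) in teachers.items():
        net = TeacherNet(config, seed=0)
        net.load_state(state)
        nets[task] = (net, state.checksum()[:12])
    counts = {t: 0 for t in teachers}
    for shard in shards:
        for sample in shard.samples:
            for task, (net, tid) in nets.items():
                if task in sample.labels and not sample.labels[task].is_pseudo:
                    continue  # never overwrite a human label
                payload, degenerate, warns = teacher_predict(net, sample, enc, min_peak)
                sample.labels[task] = Label(
                    task=task,
                    payload=payload,
                    source="pseudo",
                    teacher_id=tid,
                    degenerate=degenerate,
                    warnings=tuple(warns),
                )
                counts[task] += 1
    return counts


# ---------------------------------------------------------------------------
# student local training


def _student_local(
    config: StudentConfig,
    state: ModelState,
    shard: ClientShard,
    sample_idx: list[int],
    tasks: tuple[str, ...],
    epochs: int,
    seed: int,
    enc: HeatmapEncoding,
    include_pseudo: bool,
    trainable: set[str] | None = None,
) -> tuple[ModelState, list[float]]:
    net = StudentNet(config, seed=0)
    net.load_state(state)
    if epochs == 0:
        return net.state(), []
    opt = AdamW(net.params, lr=config.lr, weight_decay=config.weight_decay, trainable=trainable)
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(sample_idx))
        losses = []
        for j in order:
            sample = shard.samples[sample_idx[j]]
            targets = sample_targets(sample, enc, include_pseudo=include_pseudo)
            targets = {t: v for t, v in targets.items() if t in tasks}
            if not targets:
                continue
            outputs = net.forward(model_input(sample))
            loss = routed_loss(outputs, targets)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return net.state(), trace


def _usable_train_idx(shard: ClientShard, tasks, include_pseudo: bool) -> list[int]:
    return [
        i for i in shard.train_idx
        if any(shard.samples[i].has_label(t, include_pseudo=include_pseudo) for t in tasks)
    ]


# ---------------------------------------------------------------------------
# Stage 2A: federated distillation into the multi-head student


def run_stage2_distill(
    config: StudentConfig,
    shards: list[ClientShard],
    plan: FederationPlan,
    seed: int,
    enc: HeatmapEncoding = DEFAULT_ENCODING,
    include_human: bool = True,
    init_state: ModelState | None = None,
) -> tuple[ModelState, dict]:
    """Federated training of the three-head student on every client's
    (pseudo-)labeled training samples with routed loss."""
    if init_state is None:
        net = StudentNet(config, seed=stage1_init_seed(seed))
        state = net.state()
    else:
        state = init_state.copy()
    log: dict = {"rounds": [], "include_human": include_human}
    client_ids = [s.client_id for s in shards]
    for r in range(plan.rounds):
        states, weights, traces = [], [], {}
        for shard in shards:
            idx = _usable_train_idx(shard, TASKS, include_pseudo=True)
            if not include_human:
                idx = [
                    i for i in idx
                    if any(
                        shard.samples[i].labels.get(t) is not None
                        and shard.samples[i].labels[t].is_pseudo
                        and not shard.samples[i].labels[t].degenerate
                        for t in TASKS
                    )
                ]
            if not idx:
                continue
            s2, trace = _student_local(
                config, state, shard, idx, TASKS, plan.epochs,
                stage1_client_seed(seed, r, shard.client_id), enc,
                include_pseudo=True,
            )
            states.append(s2)
            weights.append(len(idx) if plan.weighting == "sample-count" else 1.0)
            traces[shard.client_id] = trace
        if not states:
            raise ValueError("no client produced usable distillation data")
        state = fedavg(states, weights)
        log["rounds"].append({"round": r, "weights": list(map(float, weights)), "loss": traces})
    log["clients"] = client_ids
    return state, log


# ---------------------------------------------------------------------------
# Stage 2B: head-only finetuning on human labels


def finetune_heads(
    config: StudentConfig,
    state: ModelState,
    shards: list[ClientShard],
    plan: FederationPlan,
    seed: int,
    enc: HeatmapEncoding = DEFAULT_ENCODING,
    rounds: int | None = None,
    epochs: int | None = None,
) -> tuple[ModelState, dict]:
    """Finetune each task head federated on human labels; backbone frozen.

    A task with no human-labeled training client is skipped with a warning
    entry in the log.  The backbone partition is asserted bitwise unchanged.
    """
    rounds = plan.rounds if rounds is None else rounds
    epochs = plan.epochs if epochs is None else epochs
    by_id = {s.client_id: s for s in shards}
    ref = StudentNet(config, seed=0)
    before = state.checksum(partition_prefix="backbone")
    out = state.copy()
    log: dict = {"tasks": {}}
    for task in TASKS:
        head = ref.head_param_names(task)
        clients = [
            cid for cid in plan.train_clients.get(task, ())
            if cid in by_id and by_id[cid].labeled_train(task)
        ]
        if not clients:
            log["tasks"][task] = {"skipped": True, "warning": "no human-labeled training client"}
            continue
        rlog = []
        for r in range(rounds):
            states, weights = [], []
            for cid in clients:
                shard = by_id[cid]
                idx = shard.labeled_train(task)
                s2, trace = _student_local(
                    config, out, shard, idx, (task,), epochs,
                    stage1_client_seed(seed, r, f"{task}:{cid}"), enc,
                    include_pseudo=False,
                    trainable=head,
                )
                states.append(s2)
                weights.append(len(idx) if plan.weighting == "sample-count" else 1.0)
            agg = fedavg(states, weights)
            # only this task's head is trainable: restore every other
            # parameter bitwise from the broadcast state (the fp mean of
            # identical values is not bitwise identical)
            for name in agg.params:
                if name not in head:
                    agg.params[name] = out.params[name].copy()
            out = agg
            rlog.append({"round": r, "clients": clients, "weights": list(map(float, weights))})
        log["tasks"][task] = {"skipped": False, "rounds": rlog}
    after = out.checksum(partition_prefix="backbone")
    if after != before:
        raise AssertionError("backbone parameters changed during head finetuning")
    return out, log


# ---------------------------------------------------------------------------
# downstream transfer: last-layer-only finetuning on a new task


@dataclass
class TransferHead:
    """A fresh 1x1x1 output convolution over frozen backbone features."""

    w: np.ndarray
    b: np.ndarray


def init_transfer_head(config: StudentConfig, seed: int) -> TransferHead:
    rng = np.random.default_rng(seed)
    df = config.decoder_filters
    return TransferHead(
        w=rng.normal(0.0, np.sqrt(2.0 / df), size=(1, df, 1, 1, 1)),
        b=np.zeros(1),
    )


def _frozen_features(net: StudentNet, sample: Sample) -> np.ndarray:
    net.forward(model_input(sample))
    return net.last_features.data


def finetune_last_layer(
    config: StudentConfig,
    state: ModelState,
    train_data: list[tuple[Sample, Volume]],
    seed: int,
    epochs: int = 5,
    lr: float = 1e-2,
) -> tuple[TransferHead, ModelState, list[float]]:
    """Train only a fresh last layer on (sample, target-mask) pairs.

    All backbone parameters are frozen and returned bitwise unchanged; the
    teacher-quality of the frozen features is exactly what this probes.
    """
    net = StudentNet(config, seed=0)
    net.load_state(state)
    frozen_before = state.checksum()
    head = init_transfer_head(config, seed)
    wt = Tensor(head.w, requires_grad=True, name="transfer.w")
    bt = Tensor(head.b, requires_grad=True, name="transfer.b")
    from collections import OrderedDict
    opt = AdamW(OrderedDict([("transfer.w", wt), ("transfer.b", bt)]), lr=lr)
    feats = [(_frozen_features(net, s), np.asarray(t.values, dtype=float)[None]) for s, t in train_data]
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(feats))
        losses = []
        for j in order:
            f, tgt = feats[j]
            logits = ad.conv3d(Tensor(f), wt, bt)
            loss = ad.add(ad.bce_with_logits(logits, tgt), ad.soft_dice_loss(logits, tgt))
            wt.grad = bt.grad = None
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    after_state = net.state()
    if after_state.checksum() != frozen_before:
        raise AssertionError("frozen parameters changed during transfer finetuning")
    return TransferHead(w=wt.data.copy(), b=bt.data.copy()), after_state, trace


def predict_transfer(config: StudentConfig, state: ModelState, head: TransferHead,
                     sample: Sample, threshold: float = 0.5) -> Volume:
    net = StudentNet(config, seed=0)
    net.load_state(state)
    f = _frozen_features(net, sample)
    logits = np.einsum("ocijl,cdhw->odhw", head.w, f) + head.b[:, None, None, None]
    prob = 1.0 / (1.0 + np.exp(-logits))
    return binarize_mask(prob, sample.volume, threshold=threshold)


__all__ = [
    "generate_pseudo_labels", "run_stage2_distill", "finetune_heads",
    "finetune_last_layer", "predict_transfer", "TransferHead", "init_transfer_head",
    "teacher_predict", "student_predict",
]
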