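"""End-to-end orchestration: configured, logged, resumable runs.

A single YAML/dict config drives the full chain

    simulate -> stage1 (x3 tasks) -> pseudolabel -> stage2
             -> finetune-heads [-> transfer] -> evaluate -> qc

Every stage records its seed, wall clock and artifact paths in a
:class:`RunManifest` (written as ``manifest.json`` in the run directory).
The phantom federation is regenerated deterministically from the config, so
resuming a run only needs the stored checkpoints; a requested stage whose
checkpoint inputs are missing raises a dependency error naming the file.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import TASK_CALC, TASK_HCO, TASK_MS, TASKS, TASK_LANDMARKS
from .distill import (
    finetune_heads,
    finetune_last_layer,
    generate_pseudo_labels,
    predict_transfer,
    run_stage2_distill,
    student_predict,
    teacher_predict,
)
from .evaluation import MetricsRecord, aggregate_results, dice, point_error_mm
from .federation import run_stage1
from .geometry_qc import qc_records, qc_report
from .labelcodec import HeatmapEncoding
from .models import (
    ModelState,
    StudentConfig,
    StudentNet,
    TeacherConfig,
    TeacherNet,
    load_checkpoint,
    save_checkpoint,
)
from .phantom import (
    PhantomConfig,
    default_annotators,
    make_federation,
    make_phantom,
    consortium_spec,
    plan_federation,
    tiny_spec,
)

STAGE_ORDER = (
    "simulate", "stage1", "pseudolabel", "stage2",
    "finetune-heads", "transfer", "evaluate", "qc",
)
DEFAULT_STAGES = tuple(s for s in STAGE_ORDER if s != "transfer")


def tiny_config() -> dict:
    """Desk-scale preset: 4 clients x 12 volumes at 32^3, tiny models,
    5 federated rounds x 2 local epochs."""
    return {
        "preset": "tiny",
        "seed": 1,
        "out_dir": "runs/tiny",
        "phantom": {},
        "annotators": {"noise_sd_mm": 1.5, "bias_scale_mm": 1.0, "swap_prob": 0.0},
        "teacher": {"base_filters": 8, "depth": 2},
        # capacity matched per task: the point tasks need azimuthal context
        # (wider net), the bright-blob segmentation trains best small
        "teacher_overrides": {"CALC": {"base_filters": 4}},
        "student": {"embed_dim": 16, "n_blocks": 1, "n_heads": 2,
                    "decoder_filters": 6, "patch_size": 8, "lr": 0.01},
        "federation": {"rounds": 5, "epochs": 2, "weighting": "sample-count"},
        "finetune": {"rounds": 2, "epochs": 1},
        "transfer": {"n_train": 6, "n_test": 4, "epochs": 8, "lr": 0.05},
        "encoding": {"sigma_mm": 3.0, "threshold_frac": 0.5},
    }


def consortium_config() -> dict:
    """Structure-faithful preset: the eight-location label-count skew with
    the full-scale round/epoch schedule (20 x 10).  Constructible and plannable on any
    machine; materializing all 8104 volumes is a batch-scale run."""
    cfg = tiny_config()
    cfg.update({
        "preset": "consortium",
        "out_dir": "runs/consortium",
        "federation": {"rounds": 20, "epochs": 10, "weighting": "sample-count"},
    })
    return cfg


def load_config(source) -> dict:
    """Accept a dict, a preset name, or a YAML file path."""
    if isinstance(source, dict):
        cfg = copy.deepcopy(source)
    elif source in ("tiny", None):
        cfg = tiny_config()
    elif source == "consortium":
        cfg = consortium_config()
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    base = consortium_config() if cfg.get("preset") == "consortium" else tiny_config()
    for key, val in base.items():
        if key not in cfg:
            cfg[key] = val
        elif isinstance(val, dict):
            merged = dict(val)
            merged.update(cfg[key] or {})
            cfg[key] = merged
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    known = set(consortium_config()) | {"stages", "write_volumes"}
    for key in cfg:
        if key not in known:
            raise ValueError(f"unknown config field: {key}")
    for section, builder in (("phantom", PhantomConfig),):
        try:
            builder(**cfg.get(section, {}))
        except TypeError as exc:
            raise ValueError(f"config section '{section}': {exc}") from exc
    if not isinstance(cfg.get("seed", 1), int):
        raise ValueError("config field 'seed' must be an integer")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    stage_status: dict[str, dict] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "artifacts": self.artifacts,
            "stage_status": self.stage_status,
            "checksums": self.checksums,
            "results": self.results,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x57A6E, stage]).generate_state(1)[0] % (2**31))


def _objects_from_config(cfg: dict):
    phantom_cfg = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in cfg["phantom"].items()})
    spec = consortium_spec() if cfg["preset"] == "consortium" else tiny_spec()
    overrides = cfg.get("teacher_overrides") or {}
    teacher_cfgs = {
        t: TeacherConfig(task=t, **{**cfg["teacher"], **overrides.get(t, {})})
        for t in TASKS
    }
    student_kwargs = dict(cfg["student"])
    student_kwargs.setdefault("input_shape", tuple(phantom_cfg.grid_shape))
    student_kwargs["input_shape"] = tuple(student_kwargs["input_shape"])
    student_cfg = StudentConfig(**student_kwargs)
    enc = HeatmapEncoding(**cfg["encoding"])
    return phantom_cfg, spec, teacher_cfgs, student_cfg, enc


class Pipeline:
    """Holds the in-memory state shared between stages of one run."""

    def __init__(self, config, stages: list[str] | None = None):
        self.cfg = load_config(config)
        self.seed = int(self.cfg["seed"])
        self.out = Path(self.cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        (self.phantom_cfg, self.spec, self.teacher_cfgs,
         self.student_cfg, self.enc) = _objects_from_config(self.cfg)
        self.stages = list(stages) if stages else list(self.cfg.get("stages", DEFAULT_STAGES))
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.manifest = RunManifest(config=self.cfg, seed=self.seed)
        self.shards = None
        self.plan = None
        self.teacher_states: dict[str, ModelState] = {}
        self.student_distilled: ModelState | None = None
        self.student_finetuned: ModelState | None = None
        self.pseudo_done = False

    # -- dependency helpers -------------------------------------------------

    def _ckpt(self, name: str) -> Path:
        return self.out / f"{name}.npz"

    def _require_simulated(self) -> None:
        if self.shards is None:
            self._run_simulate()

    def _require_teachers(self) -> None:
        self._require_simulated()
        for task in TASKS:
            if task not in self.teacher_states:
                path = self._ckpt(f"teacher_{task}")
                if not path.exists():
                    raise FileNotFoundError(
                        f"stage dependency missing: {path} (run stage1 first)"
                    )
                self.teacher_states[task] = load_checkpoint(path, self.teacher_cfgs[task])

    def _require_pseudo(self) -> None:
        if not self.pseudo_done:
            self._run_pseudolabel()

    def _require_student(self, which: str) -> ModelState:
        attr = "student_distilled" if which == "distilled" else "student_finetuned"
        state = getattr(self, attr)
        if state is None:
            path = self._ckpt(f"student_{which}")
            if not path.exists():
                raise FileNotFoundError(
                    f"stage dependency missing: {path} (run "
                    f"{'stage2' if which == 'distilled' else 'finetune-heads'} first)"
                )
            state = load_checkpoint(path, self.student_cfg)
            setattr(self, attr, state)
        return state

    # -- stages -------------------------------------------------------------

    def _run_simulate(self) -> None:
        annot_cfg = self.cfg["annotators"]
        annotators = default_annotators(self.spec, seed=_stage_seed(self.seed, 0), **annot_cfg)
        fed_cfg = self.cfg["federation"]
        self.shards, self.plan = make_federation(
            self.spec, self.phantom_cfg, annotators,
            seed=_stage_seed(self.seed, 1),
            rounds=fed_cfg["rounds"], epochs=fed_cfg["epochs"],
        )
        self.plan.weighting = fed_cfg.get("weighting", "sample-count")
        manifest = {
            "clients": [
                {
                    "client_id": sh.client_id,
                    "n_samples": len(sh.samples),
                    "train_idx": list(sh.train_idx),
                    "test_idx": list(sh.test_idx),
                    "labeled_idx": {t: list(v) for t, v in sh.labeled_idx.items()},
                }
                for sh in self.shards
            ],
            "train_clients": {t: list(v) for t, v in self.plan.train_clients.items()},
            "held_out_clients": {t: list(v) for t, v in self.plan.held_out_clients.items()},
        }
        path = self.out / "federation_manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        self.manifest.artifacts["federation_manifest"] = str(path)
        if self.cfg.get("write_volumes"):
            from .preprocess import write_nifti, write_pointset
            vol_dir = self.out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for sh in self.shards:
                for s in sh.samples:
                    write_nifti(s.volume, vol_dir / f"{s.sample_id}_ct.nii.gz")
                    write_nifti(s.heart_mask, vol_dir / f"{s.sample_id}_heart.nii.gz")
                    write_nifti(s.calc_true, vol_dir / f"{s.sample_id}_calc.nii.gz")
                    write_pointset(s.points_true, vol_dir / f"{s.sample_id}.mps")

    def _run_stage1(self) -> None:
        self._require_simulated()
        for i, task in enumerate(TASKS):
            seed = _stage_seed(self.seed, 10 + i)
            self.manifest.stage_seeds[f"stage1:{task}"] = seed
            state, log = run_stage1(
                self.plan, self.shards, task, self.teacher_cfgs[task], seed, self.enc
            )
            self.teacher_states[task] = state
            path = self._ckpt(f"teacher_{task}")
            save_checkpoint(state, path)
            (self.out / f"stage1_{task}_log.json").write_text(json.dumps(log, indent=2))
            self.manifest.artifacts[f"teacher_{task}"] = str(path)
            self.manifest.checksums[f"teacher_{task}"] = state.checksum()

    def _run_pseudolabel(self) -> None:
        self._require_teachers()
        teachers = {t: (self.teacher_cfgs[t], self.teacher_states[t]) for t in TASKS}
        counts = generate_pseudo_labels(teachers, self.shards, self.enc)
        self.pseudo_done = True
        path = self.out / "pseudolabel_counts.json"
        path.write_text(json.dumps(counts, indent=2))
        self.manifest.artifacts["pseudolabel_counts"] = str(path)

    def _run_stage2(self) -> None:
        self._require_pseudo()
        seed = _stage_seed(self.seed, 20)
        self.manifest.stage_seeds["stage2"] = seed
        state, log = run_stage2_distill(self.student_cfg, self.shards, self.plan, seed, self.enc)
        self.student_distilled = state
        path = self._ckpt("student_distilled")
        save_checkpoint(state, path)
        (self.out / "stage2_log.json").write_text(json.dumps(log, indent=2))
        self.manifest.artifacts["student_distilled"] = str(path)
        self.manifest.checksums["student_distilled"] = state.checksum()

    def _run_finetune_heads(self) -> None:
        self._require_pseudo()
        state = self._require_student("distilled")
        seed = _stage_seed(self.seed, 30)
        self.manifest.stage_seeds["finetune-heads"] = seed
        ft_cfg = self.cfg["finetune"]
        out_state, log = finetune_heads(
            self.student_cfg, state, self.shards, self.plan, seed, self.enc,
            rounds=ft_cfg["rounds"], epochs=ft_cfg["epochs"],
        )
        self.student_finetuned = out_state
        path = self._ckpt("student_finetuned")
        save_checkpoint(out_state, path)
        (self.out / "finetune_heads_log.json").write_text(json.dumps(log, indent=2))
        self.manifest.artifacts["student_finetuned"] = str(path)
        self.manifest.checksums["student_finetuned"] = out_state.checksum()

    def _run_transfer(self) -> None:
        """Downstream transfer: last-layer-only tube segmentation, distilled
        backbone vs an untrained one."""
        distilled = self._require_student("distilled")
        tcfg = self.cfg["transfer"]
        seed = _stage_seed(self.seed, 40)
        self.manifest.stage_seeds["transfer"] = seed
        rng = np.random.default_rng(seed)
        n_train, n_test = tcfg["n_train"], tcfg["n_test"]
        samples = [
            make_phantom(self.phantom_cfg, int(rng.integers(0, 2**31 - 1)),
                         sample_id=f"transfer-{i:03d}")
            for i in range(n_train + n_test)
        ]
        data = [(s, s.aux["blood"]) for s in samples]
        untrained = StudentNet(self.student_cfg, seed=seed).state()
        scores = {}
        for tag, state in (("distilled", distilled), ("untrained", untrained)):
            head, _, trace = finetune_last_layer(
                self.student_cfg, state, data[:n_train], seed,
                epochs=tcfg["epochs"], lr=tcfg["lr"],
            )
            dices = [
                dice(predict_transfer(self.student_cfg, state, head, s), t)
                for s, t in data[n_train:]
            ]
            scores[tag] = {"dice_mean": float(np.mean(dices)),
                           "dice_per_sample": list(map(float, dices)),
                           "final_loss": trace[-1]}
        path = self.out / "transfer_results.json"
        path.write_text(json.dumps(scores, indent=2))
        self.manifest.artifacts["transfer_results"] = str(path)
        self.manifest.results["transfer"] = scores

    def _evaluate_model(self, tag: str, predict, records: list[MetricsRecord]) -> None:
        """Score `predict(sample) -> {task: payload}` on every eval sample."""
        for task in TASKS:
            train_clients = set(self.plan.train_clients[task])
            held = set(self.plan.held_out_clients[task])
            for sh in self.shards:
                if sh.client_id in train_clients:
                    idx, split = list(sh.test_idx), "training"
                elif sh.client_id in held:
                    idx, split = list(range(len(sh.samples))), "other"
                else:
                    continue
                for i in idx:
                    s = sh.samples[i]
                    pred = predict(s)
                    if task == TASK_CALC:
                        value, missing = dice(pred[task], s.calc_true), 0
                    else:
                        truth = s.points_true.subset(TASK_LANDMARKS[task])
                        try:
                            _, value, miss = point_error_mm(pred[task], truth)
                        except ValueError:
                            value, miss = float("nan"), list(TASK_LANDMARKS[task])
                        missing = len(miss)
                    if np.isfinite(value):
                        records.append(MetricsRecord(
                            task=task, model_tag=tag, client_id=sh.client_id,
                            split=split, sample_id=s.sample_id,
                            value=float(value), missing=missing,
                        ))

    def _run_evaluate(self) -> None:
        self._require_teachers()
        records: list[MetricsRecord] = []

        teacher_nets = {}
        for task in TASKS:
            net = TeacherNet(self.teacher_cfgs[task], seed=0)
            net.load_state(self.teacher_states[task])
            teacher_nets[task] = net

        def teacher_pred(sample):
            out = {}
            for task, net in teacher_nets.items():
                payload, _, _ = teacher_predict(net, sample, self.enc)
                out[task] = payload
            return out

        self._evaluate_model("teacher-fed", teacher_pred, records)

        for which, tag in (("distilled", "student-distilled"), ("finetuned", "student-finetuned")):
            try:
                state = self._require_student(which)
            except FileNotFoundError:
                continue
            net = StudentNet(self.student_cfg, seed=0)
            net.load_state(state)
            self._evaluate_model(tag, lambda s, n=net: student_predict(n, s, self.enc), records)

        table = aggregate_results(records)
        path = self.out / "results_table.csv"
        table.to_csv(path, index=False)
        (self.out / "results_records.json").write_text(json.dumps(
            [r.__dict__ for r in records], indent=2, default=str))
        self.manifest.artifacts["results_table"] = str(path)
        self.manifest.results["table"] = table.to_dict(orient="records")

    def _run_qc(self) -> None:
        self._require_simulated()
        records = []
        for sh in self.shards:
            pointsets, sids = [], []
            for i in sorted(set(sh.labeled_idx.get(TASK_HCO, ()))):
                s = sh.samples[i]
                merged = s.labels[TASK_HCO].payload.copy()
                if s.has_label(TASK_MS, include_pseudo=False):
                    for n, c in s.labels[TASK_MS].payload.items():
                        merged[n] = c
                pointsets.append(merged)
                sids.append(s.sample_id)
            if pointsets:
                records.extend(qc_records(sh.client_id, pointsets, "human", sids))
        qc_dir = self.out / "qc"
        df = qc_report(records, out_dir=qc_dir)
        self.manifest.artifacts["qc_dir"] = str(qc_dir)
        self.manifest.results["qc_flags"] = int((df["flags"] != "").sum())

    # -- driver -------------------------------------------------------------

    def run(self) -> RunManifest:
        runners = {
            "simulate": self._run_simulate,
            "stage1": self._run_stage1,
            "pseudolabel": self._run_pseudolabel,
            "stage2": self._run_stage2,
            "finetune-heads": self._run_finetune_heads,
            "transfer": self._run_transfer,
            "evaluate": self._run_evaluate,
            "qc": self._run_qc,
        }
        for stage in STAGE_ORDER:
            if stage not in self.stages:
                continue
            t0 = time.time()
            try:
                runners[stage]()
            except Exception:
                self.manifest.stage_status[stage] = {
                    "status": "failed", "wall_s": round(time.time() - t0, 2)}
                self.manifest.save(self.out / "manifest.json")
                raise
            self.manifest.stage_status[stage] = {
                "status": "ok", "wall_s": round(time.time() - t0, 2)}
            self.manifest.save(self.out / "manifest.json")
        return self.manifest


def run_pipeline(config, stages: list[str] | None = None) -> RunManifest:
    """Execute (a subset of) the pipeline described by ``config``."""
    return Pipeline(config, stages=stages).run()


__all__ = [
    "Pipeline", "RunManifest", "run_pipeline", "load_config",
    "tiny_config", "consortium_config", "plan_federation",
    "STAGE_ORDER", "DEFAULT_STAGES",
]
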