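"""Pseudo-labeling, distillation routing, head finetuning, transfer."""

import copy

import numpy as np
import pytest

from fedct.core import TASK_CALC, TASK_HCO, TASK_MS, TASKS
from fedct.distill import (
    finetune_heads,
    finetune_last_layer,
    generate_pseudo_labels,
    init_transfer_head,
    predict_transfer,
    run_stage2_distill,
    student_predict,
    teacher_predict,
)
from fedct.federation import FederationPlan
from fedct.models import (
    StudentConfig,
    StudentNet,
    TeacherConfig,
    TeacherNet,
    build_student,
    build_teacher,
)

TINY_S = StudentConfig(input_shape=(24, 24, 24), patch_size=8, embed_dim=12,
                       n_blocks=1, n_heads=2, decoder_filters=4)


def teacher_states(seed=0):
    out = {}
    for task in TASKS:
        cfg = TeacherConfig(task=task, base_filters=4, depth=2)
        _, state = build_teacher(cfg, seed=seed)
        out[task] = (cfg, state)
    return out


@pytest.fixture
def federation(small_federation):
    shards, plan = small_federation
    return copy.deepcopy(shards), copy.deepcopy(plan)


class TestPseudoLabels:
    def test_coverage_and_no_overwrite(self, federation):
        shards, _ = federation
        human_before = {
            (sh.client_id, i, t): sh.samples[i].labels[t].payload
            for sh in shards for i, s in enumerate(sh.samples)
            for t in TASKS if t in s.labels
        }
        counts = generate_pseudo_labels(teacher_states(), shards)
        for sh in shards:
            for i, s in enumerate(sh.samples):
                # every sample now carries all three tasks
                assert set(s.labels) == set(TASKS)
                for t in TASKS:
                    key = (sh.client_id, i, t)
                    if key in human_before:
                        assert s.labels[t].source == "human"
                        assert s.labels[t].payload is human_before[key]
                    else:
                        assert s.labels[t].source == "pseudo"
                        assert s.labels[t].teacher_id
        assert all(c > 0 for c in counts.values())

    def test_degenerate_outputs_flagged(self, federation):
        shards, _ = federation
        teachers = teacher_states()
        # force the HCO teacher to emit near-zero heatmaps everywhere
        cfg, state = teachers[TASK_HCO]
        for name in state.params:
            if name.startswith("out"):
                state.params[name][:] = 0.0
                if name.endswith(".b"):
                    state.params[name][:] = -30.0
        generate_pseudo_labels(teachers, shards)
        for sh in shards:
            for s in sh.samples:
                lab = s.labels[TASK_HCO]
                if lab.is_pseudo:
                    assert lab.degenerate
                    assert not s.has_label(TASK_HCO)  # excluded from training

    def test_pseudo_payload_schema_matches_human(self, federation):
        """Pseudo payloads are format-indistinguishable from human labels."""
        shards, _ = federation
        generate_pseudo_labels(teacher_states(), shards)
        for sh in shards:
            for s in sh.samples:
                hco = s.labels[TASK_HCO].payload
                assert hasattr(hco, "names")
                calc = s.labels[TASK_CALC].payload
                assert calc.shape == s.volume.shape
                assert set(np.unique(calc.values)) <= {0.0, 1.0}

    def test_teacher_task_mismatch(self, federation):
        shards, _ = federation
        t = teacher_states()
        bad = {TASK_HCO: t[TASK_MS]}
        with pytest.raises(ValueError, match="configured"):
            generate_pseudo_labels(bad, shards)


class TestStage2:
    def test_unused_head_stays_at_init(self, federation):
        """With pseudo labels present only for CALC, the HCO/MS heads never
        receive gradient during distillation."""
        shards, plan = federation
        generate_pseudo_labels(teacher_states(), shards)
        for sh in shards:
            for s in sh.samples:
                s.labels.pop(TASK_HCO, None)
                s.labels.pop(TASK_MS, None)
        state, _ = run_stage2_distill(TINY_S, shards, plan, seed=4, include_human=False)
        net = StudentNet(TINY_S, seed=0)
        from fedct.federation import stage1_init_seed
        init = StudentNet(TINY_S, seed=stage1_init_seed(4)).state()
        for task in (TASK_HCO, TASK_MS):
            for name in net.head_param_names(task):
                assert np.array_equal(state.params[name], init.params[name])
        changed = [n for n in net.head_param_names(TASK_CALC)
                   if not np.array_equal(state.params[n], init.params[n])]
        assert changed

    def test_reproducible(self, federation):
        shards, plan = federation
        generate_pseudo_labels(teacher_states(), shards)
        a, _ = run_stage2_distill(TINY_S, shards, plan, seed=9)
        b, _ = run_stage2_distill(TINY_S, shards, plan, seed=9)
        assert a.checksum() == b.checksum()


class TestFinetuneHeads:
    def test_backbone_bitwise_frozen(self, federation):
        shards, plan = federation
        generate_pseudo_labels(teacher_states(), shards)
        _, init = build_student(TINY_S, seed=2)
        out, log = finetune_heads(TINY_S, init, shards, plan, seed=5, rounds=1, epochs=1)
        assert out.checksum("backbone") == init.checksum("backbone")
        net = StudentNet(TINY_S, seed=0)
        for name, arr in out.params.items():
            if out.partitions[name] == "backbone":
                assert np.array_equal(arr, init.params[name])
        # at least one trained head moved
        head_names = net.head_param_names()
        assert any(not np.array_equal(out.params[n], init.params[n]) for n in head_names)

    def test_task_without_labels_skipped(self, federation):
        shards, plan = federation
        generate_pseudo_labels(teacher_states(), shards)
        for sh in shards:
            for s in sh.samples:
                if TASK_MS in s.labels and not s.labels[TASK_MS].is_pseudo:
                    s.labels[TASK_MS] = s.labels[TASK_MS]
            sh.labeled_idx[TASK_MS] = ()
        _, init = build_student(TINY_S, seed=2)
        out, log = finetune_heads(TINY_S, init, shards, plan, seed=5, rounds=1, epochs=1)
        assert log["tasks"][TASK_MS]["skipped"]
        net = StudentNet(TINY_S, seed=0)
        for name in net.head_param_names(TASK_MS):
            assert np.array_equal(out.params[name], init.params[name])

    def test_pseudo_labels_do_not_contribute(self, federation):
        """Human-only finetuning: stripping pseudo labels changes nothing."""
        shards, plan = federation
        generate_pseudo_labels(teacher_states(), shards)
        _, init = build_student(TINY_S, seed=2)
        a, _ = finetune_heads(TINY_S, init, shards, plan, seed=5, rounds=1, epochs=1)
        stripped = copy.deepcopy(shards)
        for sh in stripped:
            for s in sh.samples:
                for t in list(s.labels):
                    if s.labels[t].is_pseudo:
                        del s.labels[t]
        b, _ = finetune_heads(TINY_S, init, stripped, plan, seed=5, rounds=1, epochs=1)
        assert a.checksum() == b.checksum()


class TestTransfer:
    def _data(self, small_config, n=3):
        from fedct.phantom import make_phantom
        samples = [make_phantom(small_config, seed=500 + i) for i in range(n)]
        return [(s, s.aux["blood"]) for s in samples]

    def test_frozen_parameters_unchanged(self, small_config):
        _, state = build_student(TINY_S, seed=3)
        data = self._data(small_config)
        _, after, _ = finetune_last_layer(TINY_S, state, data, seed=1, epochs=2)
        assert after.checksum() == state.checksum()

    def test_zero_epochs_head_equals_init(self, small_config):
        _, state = build_student(TINY_S, seed=3)
        data = self._data(small_config, n=1)
        head, _, trace = finetune_last_layer(TINY_S, state, data, seed=7, epochs=0)
        ref = init_transfer_head(TINY_S, seed=7)
        assert np.array_equal(head.w, ref.w) and np.array_equal(head.b, ref.b)
        assert trace == []

    def test_predict_shape(self, small_config):
        _, state = build_student(TINY_S, seed=3)
        data = self._data(small_config, n=1)
        head, _, _ = finetune_last_layer(TINY_S, state, data, seed=1, epochs=1)
        mask = predict_transfer(TINY_S, state, head, data[0][0])
        assert mask.shape == data[0][0].volume.shape
        assert set(np.unique(mask.values)) <= {0.0, 1.0}


def test_teacher_and_student_predict_payloads(sample):
    cfg = TeacherConfig(task=TASK_MS, base_filters=4, depth=2)
    net, _ = build_teacher(cfg, seed=0)
    payload, degenerate, warns = teacher_predict(net, sample)
    assert hasattr(payload, "names")
    snet, _ = build_student(TINY_S, seed=0)
    preds = student_predict(snet, sample)
    assert set(preds) == set(TASKS)
    assert preds[TASK_CALC].shape == sample.volume.shape
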