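"""Network contracts, loss behaviour, routing, optimizer, checkpoints."""

import numpy as np
import pytest

from fedct.core import TASK_CHANNELS, TASKS
from fedct.federation import model_input
from fedct.labelcodec import DEFAULT_ENCODING, encode_points
from fedct.models import (
    AdamW,
    StudentConfig,
    StudentNet,
    TeacherConfig,
    TeacherNet,
    build_student,
    build_teacher,
    ds_loss,
    load_checkpoint,
    routed_loss,
    sample_targets,
    save_checkpoint,
)
from fedct.autodiff import Tensor

TINY_T = TeacherConfig(task="HCO", base_filters=4, depth=2)
TINY_S = StudentConfig(input_shape=(24, 24, 24), patch_size=8, embed_dim=12,
                       n_blocks=1, n_heads=2, decoder_filters=4)


class TestTeacher:
    def test_forward_shapes(self, sample):
        net, _ = build_teacher(TINY_T, seed=0)
        outs = net.forward(model_input(sample))
        assert outs[0].data.shape == (5, 24, 24, 24)
        assert outs[1].data.shape == (5, 12, 12, 12)  # deep supervision at 1/2 res

    def test_same_seed_bitwise_identical(self):
        _, s1 = build_teacher(TINY_T, seed=3)
        _, s2 = build_teacher(TINY_T, seed=3)
        assert list(s1.params) == list(s2.params)
        for k in s1.params:
            assert np.array_equal(s1.params[k], s2.params[k])

    def test_input_validation(self):
        net, _ = build_teacher(TINY_T, seed=0)
        with pytest.raises(ValueError, match="input channels"):
            net.forward(np.zeros((3, 24, 24, 24)))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((2, 23, 24, 24)))

    def test_full_scale_constructible(self):
        cfg = TeacherConfig(task="CALC", base_filters=32, depth=5)
        net, state = build_teacher(cfg, seed=0)
        assert any(v.shape[0] == 32 for v in state.params.values())


class TestStudent:
    def test_three_heads_with_fixed_channels(self, sample):
        net, _ = build_student(TINY_S, seed=0)
        outs = net.forward(model_input(sample))
        assert set(outs) == set(TASKS)
        for task in TASKS:
            assert outs[task].data.shape == (TASK_CHANNELS[task], 24, 24, 24)

    def test_head_partition_disjoint_and_complement(self):
        net, state = build_student(TINY_S, seed=0)
        heads = {t: net.head_param_names(t) for t in TASKS}
        for a in TASKS:
            for b in TASKS:
                if a != b:
                    assert not heads[a] & heads[b]
        backbone = {n for n, p in state.partitions.items() if p == "backbone"}
        assert backbone | heads["HCO"] | heads["MS"] | heads["CALC"] == set(state.params)

    def test_variants(self, sample):
        x = model_input(sample)
        for variant in ("windowed", "plain"):
            cfg = StudentConfig(variant=variant, input_shape=(24, 24, 24),
                                patch_size=8, embed_dim=12, n_blocks=1,
                                n_heads=2, decoder_filters=4)
            net, _ = build_student(cfg, seed=0)
            outs = net.forward(x)
            assert outs["HCO"].data.shape == (5, 24, 24, 24)


class TestDsLoss:
    def _preds_targets(self):
        rng = np.random.default_rng(0)
        tgt = (rng.uniform(size=(2, 8, 8, 8)) > 0.8).astype(float)
        p0 = Tensor(rng.normal(size=(2, 8, 8, 8)), requires_grad=True)
        p1 = Tensor(rng.normal(size=(2, 4, 4, 4)), requires_grad=True)
        return [p0, p1], tgt

    def test_perfect_prediction_near_zero_dice(self):
        tgt = np.zeros((1, 8, 8, 8))
        tgt[0, 2:5, 2:5, 2:5] = 1.0
        logits = Tensor(np.where(tgt > 0, 40.0, -40.0), requires_grad=True)
        loss = ds_loss([logits], tgt, soft=False)
        assert float(loss.data) < 1e-4  # CE ~ 0 and Dice deficit ~ eps only

    def test_single_level_weight_is_one(self):
        preds, tgt = self._preds_targets()
        single = ds_loss([preds[0]], tgt, soft=False)
        from fedct.autodiff import add, bce_with_logits, soft_dice_loss
        direct = add(bce_with_logits(preds[0], tgt), soft_dice_loss(preds[0], tgt))
        assert float(single.data) == pytest.approx(float(direct.data), rel=1e-12)

    def test_weight_scale_invariance(self):
        preds, tgt = self._preds_targets()
        a = ds_loss(preds, tgt, soft=False, weights=[1.0, 0.5])
        b = ds_loss(preds, tgt, soft=False, weights=[2.0, 1.0])
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-12)

    def test_level_shape_mismatch(self):
        preds, tgt = self._preds_targets()
        with pytest.raises(ValueError, match="level 1"):
            ds_loss([preds[0], preds[0]], tgt, soft=False)


class TestRouting:
    def _student_with_targets(self, sample, tasks):
        net, _ = build_student(TINY_S, seed=1)
        targets = {}
        if "HCO" in tasks:
            hm = encode_points(sample.points_true.subset(("RCC", "LCC", "NCC", "RCO", "LCO")),
                               sample.volume, DEFAULT_ENCODING, "HCO")
            targets["HCO"] = (hm, True)
        if "MS" in tasks:
            hm = encode_points(sample.points_true.subset(("MS1", "MS2")),
                               sample.volume, DEFAULT_ENCODING, "MS")
            targets["MS"] = (hm, True)
        if "CALC" in tasks:
            targets["CALC"] = (np.asarray(sample.calc_true.values)[None], False)
        return net, targets

    def test_absent_task_heads_get_exactly_zero_gradient(self, sample):
        net, targets = self._student_with_targets(sample, ("CALC",))
        loss = routed_loss(net.forward(model_input(sample)), targets)
        net.zero_grad()
        loss.backward()
        for task in ("HCO", "MS"):
            for name in net.head_param_names(task):
                g = net.params[name].grad
                assert g is None or not np.any(g)
        assert any(np.any(net.params[n].grad) for n in net.head_param_names("CALC"))

    def test_full_labels_is_mean_of_tasks(self, sample):
        net, targets = self._student_with_targets(sample, TASKS)
        outputs = net.forward(model_input(sample))
        total = routed_loss(outputs, targets)
        parts = [routed_loss(outputs, {t: targets[t]}) for t in TASKS]
        assert float(total.data) == pytest.approx(np.mean([float(p.data) for p in parts]), rel=1e-12)

    def test_disjoint_samples_gradients_add(self, sample, small_config):
        from fedct.phantom import make_phantom
        other = make_phantom(small_config, seed=99)
        net, t1 = self._student_with_targets(sample, ("HCO",))
        _, t2 = self._student_with_targets(other, ("CALC",))
        t2 = {"CALC": (np.asarray(other.calc_true.values)[None], False)}

        def grads_for(batches):
            net.zero_grad()
            for s, t in batches:
                routed_loss(net.forward(model_input(s)), t).backward()
            return {n: (p.grad.copy() if p.grad is not None else None)
                    for n, p in net.params.items()}

        g_both = grads_for([(sample, t1), (other, t2)])
        g_a = grads_for([(sample, t1)])
        g_b = grads_for([(other, t2)])
        for n in g_both:
            ga = 0 if g_a[n] is None else g_a[n]
            gb = 0 if g_b[n] is None else g_b[n]
            if g_both[n] is None:
                assert np.all(ga == 0) and np.all(gb == 0)
            else:
                assert np.allclose(g_both[n], ga + gb, atol=1e-12)

    def test_no_labels_is_error(self, sample):
        net, _ = build_student(TINY_S, seed=1)
        with pytest.raises(ValueError, match="no usable task labels"):
            routed_loss(net.forward(model_input(sample)), {})


class TestOptimizer:
    def test_lr_zero_leaves_params_bitwise(self, sample):
        net, before = build_teacher(TINY_T, seed=0)
        opt = AdamW(net.params, lr=0.0, weight_decay=0.1)
        hm = encode_points(sample.points_true.subset(("RCC", "LCC", "NCC", "RCO", "LCO")),
                           sample.volume, DEFAULT_ENCODING, "HCO")
        loss = ds_loss(net.forward(model_input(sample)), hm, soft=True)
        net.zero_grad()
        loss.backward()
        opt.step()
        after = net.state()
        for k in before.params:
            assert np.array_equal(before.params[k], after.params[k])

    def test_training_loss_decreases(self, small_federation):
        """On a separable tiny task the epoch-mean teacher loss trends down
        over the first 5 epochs."""
        from fedct.federation import local_train
        shards, _ = small_federation
        cfg = TeacherConfig(task="CALC", base_filters=4, depth=2)
        _, state = build_teacher(cfg, seed=0)
        _, trace = local_train(cfg, state, shards[0], "CALC", epochs=5, seed=7)
        assert trace[-1] < trace[0]
        assert np.mean(trace[2:]) < np.mean(trace[:2])


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        _, state = build_teacher(TINY_T, seed=5)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path, TINY_T)
        assert list(back.params) == list(state.params)
        for k in state.params:
            assert np.array_equal(back.params[k], state.params[k])
        assert back.partitions == state.partitions

    def test_mismatched_config_refused(self, tmp_path):
        _, state = build_teacher(TINY_T, seed=5)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(path, TeacherConfig(task="MS", base_filters=4, depth=2))

    def test_load_into_mismatched_model_refused(self):
        net, _ = build_teacher(TINY_T, seed=0)
        other = TeacherNet(TeacherConfig(task="HCO", base_filters=8, depth=2), seed=0)
        with pytest.raises(ValueError, match="mismatched config"):
            net.load_state(other.state())


def test_sample_targets_respects_provenance(sample):
    from fedct.core import Label, PointSet
    sample = __import__("copy").deepcopy(sample)
    sample.labels["MS"] = Label(task="MS", payload=sample.points_true.subset(("MS1", "MS2")),
                                source="pseudo")
    human_only = sample_targets(sample, DEFAULT_ENCODING, include_pseudo=False)
    with_pseudo = sample_targets(sample, DEFAULT_ENCODING, include_pseudo=True)
    assert "MS" not in human_only and "MS" in with_pseudo
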