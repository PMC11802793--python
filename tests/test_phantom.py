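"""Phantom generation, annotator simulation, federation bookkeeping."""

import dataclasses

import numpy as np
import pytest

from fedct.core import MS_LANDMARKS, TASK_CALC, TASK_HCO, TASK_MS, TASKS
from fedct.phantom import (
    AnnotatorModel,
    ClientSpec,
    FederationSpec,
    PhantomConfig,
    default_annotators,
    make_federation,
    make_phantom,
    consortium_spec,
    perturb_annotation,
    plan_federation,
    tiny_spec,
)


class TestMakePhantom:
    def test_deterministic(self, small_config):
        a = make_phantom(small_config, seed=42)
        b = make_phantom(small_config, seed=42)
        assert np.array_equal(a.volume.values, b.volume.values)
        for n in a.points_true:
            assert np.array_equal(a.points_true[n], b.points_true[n])

    def test_zero_jitter_exact_angles(self, small_config):
        cfg = dataclasses.replace(small_config, jitter_deg=0.0, center_jitter_mm=0.0)
        s = make_phantom(cfg, seed=1)
        c = np.asarray(cfg.annulus_center_mm)
        vecs = {n: s.points_true[n] - c for n in ("RCC", "LCC", "NCC")}
        for a, b in (("RCC", "LCC"), ("LCC", "NCC"), ("NCC", "RCC")):
            cosang = np.dot(vecs[a], vecs[b]) / (
                np.linalg.norm(vecs[a]) * np.linalg.norm(vecs[b])
            )
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(120.0, abs=1e-9)
        # coplanar: all hinge points share the annulus z-plane exactly
        assert vecs["RCC"][2] == vecs["LCC"][2] == vecs["NCC"][2] == 0.0

    def test_heart_mask_covers_foreground(self, sample, small_config):
        fg = sample.calc_true.values > 0
        assert np.all(sample.heart_mask.values[fg] > 0)
        bg_mean = small_config.hu_background
        outside = sample.volume.values[sample.heart_mask.values == 0]
        assert abs(outside.mean() - bg_mean) < 5 * small_config.noise_sd_hu

    def test_landmark_geometry(self, small_config):
        s = make_phantom(small_config, seed=2)
        c_z = s.points_true["RCC"][2]  # annulus plane height for this draw
        for o in ("RCO", "LCO"):
            assert s.points_true[o][2] == pytest.approx(c_z + small_config.ostia_height_mm)
        assert s.points_true["MS1"][2] - s.points_true["MS2"][2] == pytest.approx(
            small_config.ms_gap_mm
        )

    def test_calc_brightness_monte_carlo(self, small_config):
        """Calcification voxels stay above hu_calc - 3*noise_sd in >= 99% of
        draws (Gaussian tail bound, checked by simulation)."""
        total = bright = 0
        for seed in range(1000):
            s = make_phantom(small_config, seed=seed)
            m = s.calc_true.values > 0
            if not m.any():
                continue
            vals = s.volume.values[m]
            total += vals.size
            bright += int((vals >= small_config.hu_calc - 3 * small_config.noise_sd_hu).sum())
        assert total > 0
        assert bright / total >= 0.99

    def test_grid_too_small(self, small_config):
        cfg = dataclasses.replace(small_config, grid_shape=(8, 24, 24))
        with pytest.raises(ValueError, match="along x"):
            make_phantom(cfg, seed=0)

    def test_invalid_intensities(self):
        with pytest.raises(ValueError, match="hu_calc > hu_blood"):
            PhantomConfig(hu_calc=100.0, hu_blood=300.0)


class TestAnnotator:
    def test_identity(self, sample, clean_annotator):
        out = perturb_annotation(sample.points_true, clean_annotator, seed=1)
        assert out == sample.points_true

    def test_pure_bias_is_pythagorean(self, sample):
        m = AnnotatorModel(bias_mm=(3.0, 4.0, 0.0), noise_sd_mm=0.0, seed=1)
        out = perturb_annotation(sample.points_true, m, seed=9)
        for n in sample.points_true:
            assert np.linalg.norm(out[n] - sample.points_true[n]) == pytest.approx(5.0)

    def test_forced_swap(self, sample):
        m = AnnotatorModel(swap_prob=1.0, seed=2)
        out = perturb_annotation(sample.points_true, m, seed=3)
        assert np.array_equal(out["MS1"], sample.points_true["MS2"])
        assert np.array_equal(out["MS2"], sample.points_true["MS1"])

    def test_absent_landmarks_pass_through(self, sample):
        partial = sample.points_true.subset(["RCC", "LCC", "NCC"])
        out = perturb_annotation(partial, AnnotatorModel(noise_sd_mm=1.0, seed=4), seed=5)
        assert out.names == ("RCC", "LCC", "NCC")

    def test_maxwell_mean_distance(self, sample):
        """Mean displacement of isotropic 3D Gaussian scatter converges to
        the Maxwell mean sigma*2*sqrt(2/pi) (within 5% at n = 10,000)."""
        sigma = 1.7
        m = AnnotatorModel(noise_sd_mm=sigma, seed=6)
        one = sample.points_true.subset(["RCC"])
        d = [
            np.linalg.norm(perturb_annotation(one, m, seed=i)["RCC"] - one["RCC"])
            for i in range(10_000)
        ]
        expected = sigma * 2.0 * np.sqrt(2.0 / np.pi)
        assert abs(np.mean(d) - expected) / expected < 0.05

    def test_invalid_models(self):
        with pytest.raises(ValueError):
            AnnotatorModel(noise_sd_mm=-1.0)
        with pytest.raises(ValueError):
            AnnotatorModel(swap_prob=1.5)


class TestFederation:
    def test_label_count_conservation(self, small_federation, small_spec):
        shards, _ = small_federation
        for task in TASKS:
            total = sum(len(sh.labeled_idx[task]) for sh in shards)
            assert total == sum(c.labeled.get(task, 0) for c in small_spec.clients)

    def test_labeled_vs_unlabeled_bookkeeping(self, small_federation):
        shards, _ = small_federation
        for sh in shards:
            for task in TASKS:
                labeled = set(sh.labeled_idx[task])
                for i, s in enumerate(sh.samples):
                    if i in labeled:
                        assert task in s.labels and s.labels[task].source == "human"
                    else:
                        assert task not in s.labels

    def test_adding_client_preserves_other_shards(self, small_spec, small_config):
        ann = default_annotators(small_spec, seed=5)
        shards_a, _ = make_federation(small_spec, small_config, ann, seed=11)
        bigger = FederationSpec(
            clients=small_spec.clients + [ClientSpec("z", 2, {TASK_HCO: 1})],
            test_fraction=small_spec.test_fraction,
            held_out_clients=small_spec.held_out_clients,
        )
        ann_b = default_annotators(bigger, seed=5)
        # annotator draws are positional, so pin the shared clients' models
        for cid in ("a", "b", "h"):
            ann_b[cid] = ann[cid]
        shards_b, _ = make_federation(bigger, small_config, ann_b, seed=11)
        for sa, sb in zip(shards_a, shards_b):
            assert sa.client_id == sb.client_id
            for x, y in zip(sa.samples, sb.samples):
                assert np.array_equal(x.volume.values, y.volume.values)

    def test_plan_topology(self, small_federation):
        _, plan = small_federation
        assert plan.train_clients[TASK_HCO] == ("a", "b")
        assert plan.train_clients[TASK_MS] == ("a",)
        assert plan.held_out_clients[TASK_MS] == ("h",)

    def test_heldout_needs_labels(self):
        with pytest.raises(ValueError, match="zero labeled"):
            FederationSpec(
                clients=[
                    ClientSpec("t", 4, {TASK_HCO: 2, TASK_MS: 2, TASK_CALC: 2}),
                    ClientSpec("u", 4, {TASK_MS: 2, TASK_CALC: 2}),
                ],
                held_out_clients={TASK_HCO: ("u",), TASK_MS: ("u",), TASK_CALC: ("u",)},
            )

    def test_labeled_exceeds_total(self):
        with pytest.raises(ValueError, match="exceeds total"):
            ClientSpec("x", 3, {TASK_HCO: 5})


class TestPresets:
    def test_consortium_counts(self):
        spec = consortium_spec()
        table = spec.count_table()
        assert table["volumes"] == 8104
        assert table[TASK_HCO] == 251
        assert table[TASK_MS] == 116
        assert table[TASK_CALC] == 118
        assert len(spec.clients) == 8
        by_id = {c.client_id: c for c in spec.clients}
        assert by_id["L3"].n_total == 3001 and by_id["L5"].n_total == 20
        assert sum(1 for c in spec.clients if c.labeled.get(TASK_HCO)) == 7
        assert sum(1 for c in spec.clients if c.labeled.get(TASK_MS)) == 3
        assert sum(1 for c in spec.clients if c.labeled.get(TASK_CALC)) == 3

    def test_consortium_heldout(self):
        spec = consortium_spec()
        assert spec.held_out_clients[TASK_HCO] == ("L6", "L7")
        assert spec.held_out_clients[TASK_MS] == ("L7",)
        assert spec.held_out_clients[TASK_CALC] == ("L6",)
        plan = plan_federation(spec)
        assert plan.rounds == 20 and plan.epochs == 10
        assert "L6" not in plan.train_clients[TASK_HCO]
        assert "L7" not in plan.train_clients[TASK_HCO]

    def test_tiny_spec_valid(self):
        spec = tiny_spec()
        assert len(spec.clients) == 4
        assert all(c.n_total == 12 for c in spec.clients)
        plan = plan_federation(spec, rounds=5, epochs=2)
        for task in TASKS:
            assert plan.train_clients[task] and plan.held_out_clients[task]
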