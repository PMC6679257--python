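"""Detector building blocks: pooling, OHEM, losses, training mechanics."""

from __future__ import annotations

import numpy as np
import pytest

from paniclecount.annotations_io import AnnotatedImage, BoundingBox, boxes_to_array
from paniclecount.detector import (
    STRIDE,
    HyperParams,
    ProposalSet,
    RegionLoss,
    TrainState,
    _Net,
    compute_losses,
    generate_proposals,
    load_checkpoint,
    make_anchors,
    position_sensitive_score,
    predict,
    save_checkpoint,
    select_hard_examples,
    train,
)
from paniclecount.nms import NmsConfig
from paniclecount.synthetic_field import SceneConfig, preset, render_scenes


def _blank_image(h=96, w=96, value=80):
    return AnnotatedImage("blank", np.full((h, w, 3), value, dtype=np.uint8))


def _untrained_state(seed=0, **hp_kwargs):
    hp = HyperParams(seed=seed, **hp_kwargs)
    return TrainState(net=_Net(hp, np.random.default_rng(seed)), hp=hp)


def _tiny_scenes(n=10, seed=300, **cfg_kwargs):
    cfg = preset("easy").with_(
        image_size=(96, 96), panicle_count_range=(4, 8), rng_seed=seed, **cfg_kwargs
    )
    return render_scenes(cfg, n)


class TestPositionSensitiveScore:
    def test_k1_is_plain_average_pooling(self):
        maps = np.arange(16.0).reshape(4, 4, 1)
        score = position_sensitive_score(maps, (0, 0, 4, 4), k=1)
        assert score[0] == pytest.approx(maps.mean())

    def test_constant_maps_give_constant_score(self):
        maps = np.concatenate(
            [np.full((6, 6, 9), 2.5), np.full((6, 6, 9), -1.25)], axis=2
        )
        for region in [(0, 0, 6, 6), (1.3, 0.7, 3.9, 5.2), (2, 2, 2.4, 2.4)]:
            score = position_sensitive_score(maps, region, k=3)
            assert score == pytest.approx([2.5, -1.25])

    def test_two_by_two_toy_votes_mean_of_designated_cells(self):
        """Each bin reads only its own map: the vote is the mean of the
        four designated constants."""
        toy = np.zeros((2, 2, 4))
        constants = [10.0, 11.0, 12.0, 13.0]
        for b, c in enumerate(constants):
            toy[:, :, b] = c
        score = position_sensitive_score(toy, (0, 0, 2, 2), k=2)
        assert score[0] == pytest.approx(np.mean(constants))

    def test_position_sensitivity(self):
        """A misplaced region reads other cells than a centered one."""
        maps = np.zeros((8, 8, 9))
        maps[3:5, 3:5, :] = 1.0  # object signature in the center cells
        centered = position_sensitive_score(maps, (3, 3, 5, 5), k=3)
        shifted = position_sensitive_score(maps, (5, 5, 7, 7), k=3)
        assert centered[0] > shifted[0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            position_sensitive_score(np.zeros((4, 4, 5)), (0, 0, 2, 2), k=2)
        with pytest.raises(ValueError):
            position_sensitive_score(np.zeros((4, 4, 4)), (0, 0, 2, 2), k=0)


class TestSelectHardExamples:
    def _losses(self, values):
        return [
            RegionLoss(BoundingBox(i, 0, i + 1, 1), v, "background")
            for i, v in enumerate(values)
        ]

    def test_top_k_by_loss(self):
        out = select_hard_examples(self._losses([1.0, 0.5, 2.0, 0.1]), k=2)
        assert [r.loss for r in out] == [2.0, 1.0]

    def test_k_larger_than_list_returns_all(self):
        losses = self._losses([0.3, 0.1])
        assert select_hard_examples(losses, k=10) == losses

    def test_ties_keep_input_order(self):
        losses = self._losses([0.5, 0.5, 0.5, 0.5])
        out = select_hard_examples(losses, k=2)
        assert out == losses[:2]

    def test_equals_full_sort_oracle(self, rng):
        for _ in range(50):
            losses = self._losses(rng.uniform(0, 3, size=rng.integers(1, 60)).round(2))
            k = int(rng.integers(1, 70))
            got = select_hard_examples(losses, k)
            oracle = sorted(losses, key=lambda r: -r.loss)[:k]
            assert sorted(r.loss for r in got) == sorted(r.loss for r in oracle)
            assert [r.loss for r in got] == sorted((r.loss for r in got), reverse=True)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_hard_examples(self._losses([1.0]), 0)


class TestProposals:
    def test_blank_image_returns_full_count(self):
        state = _untrained_state()
        ps = generate_proposals(_blank_image(), state)
        assert len(ps) == state.hp.proposal_count

    def test_proposals_clipped_to_image(self):
        state = _untrained_state()
        img = _blank_image(64, 96)
        ps = generate_proposals(img, state)
        assert (ps.boxes[:, 0] >= 0).all() and (ps.boxes[:, 1] >= 0).all()
        assert (ps.boxes[:, 2] <= 96).all() and (ps.boxes[:, 3] <= 64).all()

    def test_anchor_grid_geometry(self):
        anchors = make_anchors(4, 4, scales=(16.0,), ratios=(1.0,))
        assert anchors.shape == (16, 4)
        # first anchor centered on the first stride-8 cell center
        assert anchors[0] == pytest.approx([-4.0, -4.0, 12.0, 12.0])

    def test_incompatible_anchor_spec_rejected(self):
        state = _untrained_state()
        with pytest.raises(ValueError):
            generate_proposals(_blank_image(), state, anchor_spec=((12.0,), (1.0,)))


class TestComputeLosses:
    def test_one_loss_per_proposal_with_iou_labels(self):
        scenes = _tiny_scenes(1)
        img = scenes[0].image
        state = _untrained_state()
        gt = boxes_to_array(img.boxes)
        proposals = ProposalSet(
            boxes=np.concatenate([gt, np.array([[0.0, 0.0, 12.0, 12.0]])]),
            scores=np.ones(len(gt) + 1),
            image_id=img.image_id,
        )
        losses = compute_losses(state, img, proposals, img.boxes)
        assert len(losses) == len(proposals)
        assert [r.label for r in losses[: len(gt)]] == ["panicle"] * len(gt)
        assert all(r.loss >= 0 and np.isfinite(r.loss) for r in losses)
        assert all(r.loc_loss == 0.0 for r in losses if r.label == "background")

    def test_scalar_oracle_recomputation(self):
        """Region losses agree with an independent scalar recomputation
        through the public pooling op to 1e-6."""
        scenes = _tiny_scenes(1, seed=77)
        img = scenes[0].image
        state = _untrained_state(seed=5)
        rng = np.random.default_rng(0)
        boxes = []
        for _ in range(10):
            x0, y0 = rng.uniform(0, 70, 2)
            boxes.append([x0, y0, x0 + rng.uniform(4, 25), y0 + rng.uniform(4, 25)])
        proposals = ProposalSet(np.array(boxes), np.ones(10), img.image_id)
        losses = compute_losses(state, img, proposals, img.boxes)

        maps = state.net.forward(img.pixels, train=False, rng=None)
        gt = boxes_to_array(img.boxes)
        from paniclecount.nms import iou_matrix

        k = state.hp.ps_grid
        for region, rl in zip(boxes, losses):
            feat_region = tuple(np.asarray(region) / STRIDE)
            cls = position_sensitive_score(maps["ps_cls"], feat_region, k)
            regd = position_sensitive_score(maps["ps_reg"], feat_region, k)
            ious = iou_matrix(np.array([region]), gt)[0]
            label = 1 if ious.max() >= 0.5 else 0
            z = cls - cls.max()
            ce = -(z[label] - np.log(np.exp(z).sum()))
            loc = 0.0
            if label:
                j = int(ious.argmax())
                g, r = gt[j], np.asarray(region, dtype=float)
                rw, rh = r[2] - r[0], r[3] - r[1]
                t = np.array([
                    ((g[0] + g[2]) / 2 - (r[0] + r[2]) / 2) / rw,
                    ((g[1] + g[3]) / 2 - (r[1] + r[3]) / 2) / rh,
                    np.log((g[2] - g[0]) / rw),
                    np.log((g[3] - g[1]) / rh),
                ])
                d = regd - t
                loc = float(np.where(np.abs(d) < 1, 0.5 * d * d, np.abs(d) - 0.5).sum())
            assert rl.cls_loss == pytest.approx(ce, abs=1e-6)
            assert rl.loc_loss == pytest.approx(loc, abs=1e-6)
            assert rl.loss == pytest.approx(ce + state.hp.loc_weight * loc, abs=1e-6)


class TestTraining:
    def test_identical_seed_identical_initial_loss(self):
        scenes = _tiny_scenes(4)
        imgs = [s.image for s in scenes]
        hp = HyperParams(seed=9, iteration_budget=3, epochs=1, channels=(6, 8, 12))
        a = train(imgs, hp)
        b = train(imgs, hp)
        assert a.loss_curve[0] == b.loss_curve[0]

    def test_smoke_run_loss_decreases(self):
        scenes = _tiny_scenes(10)
        imgs = [s.image for s in scenes]
        hp = HyperParams(seed=2, iteration_budget=80, verification_period=40)
        state = train(imgs, hp)
        assert state.iteration == 80
        assert len(state.history) == 2
        first = np.mean(state.loss_curve[:15])
        last = np.mean(state.loss_curve[-15:])
        assert last < first

    def test_epoch_schedule_caps_iterations(self):
        scenes = _tiny_scenes(3)
        hp = HyperParams(seed=1, iteration_budget=1000, epochs=2)
        state = train([s.image for s in scenes], hp)
        assert state.iteration == 6  # 2 epochs x 3 images

    def test_warm_start_continues_from_pretrained(self):
        scenes = _tiny_scenes(6)
        imgs = [s.image for s in scenes]
        hp = HyperParams(seed=3, iteration_budget=60, verification_period=30)
        pretrained = train(imgs, hp)
        probe = hp.with_(iteration_budget=1, epochs=1)
        resumed = train(imgs, probe, init_state=pretrained)
        fresh = train(imgs, probe)
        # transferring weights starts from a better operating point
        assert resumed.loss_curve[0] < fresh.loss_curve[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], HyperParams())


class TestPredict:
    def test_threshold_above_all_scores_gives_empty(self):
        state = _untrained_state()
        assert predict(_blank_image(), state, confidence_threshold=1.01) == []

    def test_without_nms_is_superset(self):
        scenes = _tiny_scenes(1)
        state = _untrained_state()
        img = scenes[0].image
        with_nms = predict(img, state, 0.0, NmsConfig(0.3))
        without = predict(img, state, 0.0, nms_config=None)
        raw = {(d.box.as_tuple(), d.score) for d in without}
        assert {(d.box.as_tuple(), d.score) for d in with_nms} <= raw
        assert len(with_nms) <= len(without)

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        scenes = _tiny_scenes(4)
        hp = HyperParams(seed=4, iteration_budget=30, channels=(6, 8, 12))
        state = train([s.image for s in scenes], hp)
        save_checkpoint(state, tmp_path / "model.npz")
        loaded = load_checkpoint(tmp_path / "model.npz")
        img = scenes[0].image
        a = predict(img, state, 0.2)
        b = predict(img, loaded, 0.2)
        assert [(d.box.as_tuple(), d.score) for d in a] == [
            (d.box.as_tuple(), d.score) for d in b
        ]
        assert loaded.hp == state.hp


def test_hyperparams_defaults_follow_study_configuration():
    hp = HyperParams()
    assert hp.base_learning_rate == 0.01
    assert hp.momentum == 0.9
    assert hp.dropout == 0.5
    assert hp.batch_size == 100
    assert hp.iteration_budget == 5000
    assert hp.epochs == 300
    assert hp.verification_period == 1000
    with pytest.raises(ValueError):
        HyperParams(epochs=0)
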