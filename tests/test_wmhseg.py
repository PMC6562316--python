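"""Spatial-prior segmentation: training contracts, gating, volume bookkeeping."""

import numpy as np
import pytest

from flairwmh.core import BinaryMask, VoxelVolume
from flairwmh.intnorm import WM_TARGET
from flairwmh.metrics import dice
from flairwmh.nn.layers import sigmoid
from flairwmh.spatialnorm import Template
from flairwmh.wmhseg import (
    adaptive_gate,
    default_gate,
    evaluate_validation,
    segment_wmh,
    train_inference,
    train_prior,
)


def _atlas_masks(rng, n=12, shape=(32, 32, 8)):
    """Small atlas-space lesion maps: one random blob per map."""
    out = []
    for _ in range(n):
        m = np.zeros(shape, dtype=bool)
        cx, cy = rng.integers(8, 24, 2)
        cz = rng.integers(2, 6)
        xx, yy, zz = np.ogrid[:shape[0], :shape[1], :shape[2]]
        m[(xx - cx) ** 2 + (yy - cy) ** 2 + ((zz - cz) * 2) ** 2 <= 16] = True
        out.append(BinaryMask(m, (1, 1, 1)))
    return out


@pytest.fixture(scope="module")
def prior_and_masks():
    rng = np.random.default_rng(0)
    masks = _atlas_masks(rng)
    prior = train_prior(masks, features=8, code=16, epochs=40, seed=0)
    return prior, masks


class TestPrior:
    def test_validation_loss_improves_over_untrained(self, prior_and_masks):
        prior, _ = prior_and_masks
        assert prior.history["val_loss"][-1] < prior.history["untrained_val_loss"]

    def test_split_proportions_preserved(self, prior_and_masks):
        prior, masks = prior_and_masks
        assert prior.n_train + prior.n_val + prior.n_test == len(masks)
        assert prior.n_train >= prior.n_val >= 1

    def test_heldout_reconstruction_overlaps_truth(self, prior_and_masks):
        prior, masks = prior_and_masks
        held = masks[-1]  # last map lands in the held-out tail of the split
        x = held.data.transpose(2, 0, 1)[:, None].astype(np.float32)
        prob = sigmoid(prior.net.forward(x))[:, 0].transpose(1, 2, 0)
        assert dice(prob > 0.5, held.data) >= 0.3

    def test_all_empty_maps_give_near_zero_decoder(self):
        empty = [BinaryMask(np.zeros((32, 32, 4), dtype=bool), (1, 1, 1)) for _ in range(10)]
        prior = train_prior(empty, features=4, code=8, epochs=30, pos_weight=1.0, seed=1)
        x = np.zeros((4, 1, 32, 32), dtype=np.float32)
        prob = sigmoid(prior.net.forward(x))
        assert prob.max() < 0.2

    def test_mismatched_grids_rejected(self, rng):
        a = BinaryMask(np.zeros((32, 32, 4), dtype=bool), (1, 1, 1))
        b = BinaryMask(np.zeros((16, 16, 4), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError, match="common grid"):
            train_prior([a] * 9 + [b], features=4, code=8, epochs=1)

    def test_too_few_maps_rejected(self):
        a = BinaryMask(np.zeros((32, 32, 2), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError):
            train_prior([a] * 5)


class TestInference:
    @pytest.fixture(scope="class")
    def trained(self, prior_and_masks):
        prior, masks = prior_and_masks
        rng = np.random.default_rng(2)
        vols = []
        for m in masks:
            data = np.full(m.shape, WM_TARGET)
            data[m.data] = 1.3  # hyperintense lesions
            data[:3, :3, :] = 0.1  # suppressed-CSF corner, as on real FLAIR
            data += rng.normal(0, 0.03, m.shape)
            vols.append(VoxelVolume(data, (1, 1, 1)))
        model = train_inference(list(zip(vols, masks)), prior, epochs=3, seed=0)
        return model, vols, masks

    def test_decoder_bitwise_frozen(self, trained, prior_and_masks):
        model, _, _ = trained
        model.check_frozen()  # would raise on any modification
        prior, _ = prior_and_masks
        for ref, p in zip(model._frozen, prior.decoder.params):
            assert np.array_equal(ref, p.value)

    def test_training_loss_decreases(self, trained):
        model, _, _ = trained
        assert model.history["loss"][-1] < model.history["loss"][0]

    def test_tampered_decoder_detected(self, trained):
        model, _, _ = trained
        p = model.prior.decoder.params[0]
        p.value[0] += 1.0
        with pytest.raises(RuntimeError, match="decoder"):
            model.check_frozen()
        p.value[0] -= 1.0


def _template_for(shape):
    brain = np.ones(shape, dtype=bool)
    prior_vol = np.ones(shape)  # uninformative prior support
    return Template(
        volume=VoxelVolume(np.full(shape, WM_TARGET), (1, 1, 1)),
        brain_mask=BinaryMask(brain, (1, 1, 1)),
        wmh_prior=prior_vol,
    )


class TestSegment:
    @pytest.fixture(scope="class")
    def model(self, prior_and_masks):
        prior, masks = prior_and_masks
        rng = np.random.default_rng(2)
        vols = []
        for m in masks:
            data = np.full(m.shape, WM_TARGET)
            data[m.data] = 1.3
            data[:3, :3, :] = 0.1
            data += rng.normal(0, 0.03, m.shape)
            vols.append(VoxelVolume(data, (1, 1, 1)))
        return train_inference(list(zip(vols, masks)), prior, epochs=3, seed=0)

    def test_zero_volume_gives_zero_wmhv(self, model):
        tpl = _template_for((32, 32, 8))
        res = segment_wmh(model, VoxelVolume(np.zeros((32, 32, 8)), (1, 1, 1)), tpl)
        assert res.wmhv_cc == 0.0

    def test_unnormalized_input_rejected(self, model):
        tpl = _template_for((32, 32, 8))
        bad = VoxelVolume(np.full((32, 32, 8), 140.0), (1, 1, 1))
        with pytest.raises(ValueError, match="normalized"):
            segment_wmh(model, bad, tpl)

    def test_hemispheric_split_partitions_total(self, model, prior_and_masks):
        _, masks = prior_and_masks
        tpl = _template_for((32, 32, 8))
        rng = np.random.default_rng(3)
        data = np.full((32, 32, 8), WM_TARGET) + rng.normal(0, 0.02, (32, 32, 8))
        data[:3, :3, :] = 0.1
        data[masks[0].data] = 1.3
        res = segment_wmh(model, VoxelVolume(data, (1, 1, 1)), tpl)
        assert res.left_cc + res.right_cc == pytest.approx(res.wmhv_cc, abs=1e-12)

    def test_lesion_entirely_left_gives_zero_right(self, model):
        tpl = _template_for((32, 32, 8))
        rng = np.random.default_rng(4)
        data = np.full((32, 32, 8), WM_TARGET) + rng.normal(0, 0.02, (32, 32, 8))
        data[:3, 29:, :] = 0.1
        data[4:10, 10:20, 2:6] = 1.3  # x < 16: left half only
        res = segment_wmh(model, VoxelVolume(data, (1, 1, 1)), tpl)
        assert res.right_cc == 0.0

    def test_raising_gate_never_increases_wmhv(self, model, prior_and_masks):
        _, masks = prior_and_masks
        tpl = _template_for((32, 32, 8))
        rng = np.random.default_rng(5)
        data = np.full((32, 32, 8), WM_TARGET) + rng.normal(0, 0.02, (32, 32, 8))
        data[:3, :3, :] = 0.1
        data[masks[1].data] = 1.3
        vol = VoxelVolume(data, (1, 1, 1))
        vols = [segment_wmh(model, vol, tpl, gate=g).wmhv_cc for g in (0.8, 0.95, 1.1, 1.4)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_stroke_lesion_mask_excluded(self, model, prior_and_masks):
        _, masks = prior_and_masks
        tpl = _template_for((32, 32, 8))
        rng = np.random.default_rng(6)
        data = np.full((32, 32, 8), WM_TARGET) + rng.normal(0, 0.02, (32, 32, 8))
        data[:3, :3, :] = 0.1
        data[masks[2].data] = 1.3
        vol = VoxelVolume(data, (1, 1, 1))
        with_stroke = segment_wmh(model, vol, tpl, lesion_mask=masks[2])
        without = segment_wmh(model, vol, tpl)
        assert with_stroke.wmhv_cc <= without.wmhv_cc
        assert not np.any(with_stroke.mask.data & masks[2].data)


class TestGate:
    def test_default_gate_is_mode_plus_half_fwhm(self):
        assert default_gate((0.65, 0.85)) == pytest.approx(WM_TARGET + 0.10)
        assert default_gate(None) == pytest.approx(0.85)

    def test_adaptive_gate_splits_two_intensity_classes(self, rng):
        region = np.ones((40, 40, 10), dtype=bool)
        data = np.full((40, 40, 10), WM_TARGET) + rng.normal(0, 0.03, (40, 40, 10))
        data[5:15, 5:15, :] = 1.3 + rng.normal(0, 0.03, (10, 10, 10))
        gate = adaptive_gate(data, region, fwhm=(0.68, 0.82))
        assert 0.85 < gate < 1.25  # between the WM tail and the lesion plateau

    def test_adaptive_gate_falls_back_to_floor_without_candidates(self, rng):
        region = np.ones((10, 10, 2), dtype=bool)
        data = np.full((10, 10, 2), 0.5)
        assert adaptive_gate(data, region, fwhm=(0.68, 0.82)) == default_gate((0.68, 0.82))


class TestEvaluate:
    def test_perfect_agreement(self):
        v = np.array([0.6, 2.0, 8.0, 25.0, 3.0])
        rep = evaluate_validation(v, v)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.mse == pytest.approx(0.0, abs=1e-20)
        assert rep.icc == pytest.approx(1.0)

    def test_power_relation_slope(self):
        v = np.array([0.7, 2.0, 9.0, 30.0])
        rep = evaluate_validation(v, v**0.9)
        assert rep.slope == pytest.approx(0.9)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            evaluate_validation([1.0, 0.0, 2.0], [1.0, 1.0, 2.0])
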