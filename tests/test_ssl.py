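"""Cutout corruption, contrastive/reconstruction losses, pretext training."""

import numpy as np
import pytest

from smallseg.nn import tensor as T
from smallseg.ssl import (ContrastivePretrainer, CutoutSpec, combined_loss,
                          contrastive_loss, downstream_train,
                          inner_cutout_spec, make_cutout_view,
                          make_pretext_pair, outer_cutout_spec,
                          reconstruction_l1)

RNG = np.random.default_rng(0)


def _vol(shape=(64, 64, 12)):
    return np.random.default_rng(5).random(shape).astype(np.float32)


class TestCutouts:
    def test_zero_crops_is_identity(self):
        v = _vol()
        out = make_cutout_view(v, CutoutSpec("inner", 5, 20, n_crops=0))
        np.testing.assert_array_equal(out, v)

    def test_inner_changes_confined_to_interior(self):
        v = _vol()
        spec = CutoutSpec("inner", 5, 20, n_crops=6, seed=3)
        out, regions = make_cutout_view(v, spec, return_regions=True)
        assert len(regions) == 6
        diff = out != v
        assert diff.any()
        rows, cols, _ = np.nonzero(diff)
        H, W = v.shape[:2]
        assert rows.min() >= H // 4 and rows.max() < 3 * H // 4
        assert cols.min() >= W // 4 and cols.max() < 3 * W // 4

    def test_outer_touches_border_band(self):
        v = _vol()
        out = make_cutout_view(v, CutoutSpec("outer", 20, 40, n_crops=6, seed=4))
        diff = out != v
        H, W = v.shape[:2]
        band = np.ones_like(diff)
        band[H // 4:3 * H // 4, W // 4:3 * W // 4, :] = False
        assert (diff & band).any()

    def test_locality_voxels_outside_regions_bit_identical(self):
        v = _vol()
        out, regions = make_cutout_view(
            v, CutoutSpec("inner", 5, 20, n_crops=6, seed=9),
            return_regions=True)
        inside = np.zeros(v.shape, dtype=bool)
        for r0, r1, c0, c1, z0, z1 in regions:
            inside[r0:r1, c0:c1, z0:z1] = True
        np.testing.assert_array_equal(out[~inside], v[~inside])

    def test_region_sizes_within_spec(self):
        v = _vol((128, 128, 8))
        spec = CutoutSpec("outer", 20, 64, n_crops=6, seed=1)
        _, regions = make_cutout_view(v, spec, return_regions=True)
        for r0, r1, c0, c1, _, _ in regions:
            assert spec.min_size <= r1 - r0 <= spec.max_size
            assert spec.min_size <= c1 - c0 <= spec.max_size

    def test_small_volume_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            make_cutout_view(_vol((16, 16, 4)), CutoutSpec("inner", 5, 32))

    def test_pair_shares_shape_and_original_untouched(self):
        v = _vol()
        pair = make_pretext_pair(v, seed=2,
                                 inner=inner_cutout_spec(2, max_size=20),
                                 outer=outer_cutout_spec(3, min_size=10,
                                                         max_size=20))
        assert pair.aug1.shape == pair.aug2.shape == pair.original.shape
        np.testing.assert_array_equal(pair.original, v)


class TestContrastiveLoss:
    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_identical_embeddings_closed_form(self, n):
        z = np.ones((n, 16), dtype=np.float32)
        loss = contrastive_loss(z, z, temperature=0.5).item()
        assert loss == pytest.approx(np.log(2 * n - 1), abs=1e-6)

    def test_matched_orthogonal_low_temperature_limit(self):
        z1 = np.eye(4, 16, dtype=np.float32)
        loss = contrastive_loss(z1, z1, temperature=0.05).item()
        assert loss < 1e-3

    def test_matches_explicit_double_loop_oracle(self):
        n, d, tau = 5, 7, 0.5
        z1 = RNG.normal(size=(n, d)).astype(np.float32)
        z2 = RNG.normal(size=(n, d)).astype(np.float32)
        z = np.concatenate([z1, z2])
        z = z / np.linalg.norm(z, axis=1, keepdims=True)
        total = 0.0
        for i in range(2 * n):
            pos = i + n if i < n else i - n
            num = np.exp(z[i] @ z[pos] / tau)
            den = sum(np.exp(z[i] @ z[j] / tau) for j in range(2 * n) if j != i)
            total += -np.log(num / den)
        oracle = total / (2 * n)
        assert contrastive_loss(z1, z2, tau).item() == pytest.approx(
            oracle, abs=1e-6)

    def test_invariant_to_common_permutation(self):
        z1 = RNG.normal(size=(6, 8)).astype(np.float32)
        z2 = RNG.normal(size=(6, 8)).astype(np.float32)
        perm = np.random.default_rng(1).permutation(6)
        a = contrastive_loss(z1, z2).item()
        b = contrastive_loss(z1[perm], z2[perm]).item()
        assert a == pytest.approx(b, abs=1e-6)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            contrastive_loss(np.ones((1, 4)), np.ones((1, 4)))


class TestReconstructionL1:
    def test_identity_and_constant_offset(self):
        v = _vol((8, 8, 4))
        assert reconstruction_l1(v, v).item() == 0.0
        assert reconstruction_l1(v + 1.0, v).item() == pytest.approx(1.0, abs=1e-6)

    def test_matches_element_loop(self):
        a = RNG.normal(size=(4, 5)).astype(np.float32)
        b = RNG.normal(size=(4, 5)).astype(np.float32)
        oracle = float(np.mean([abs(float(a[i, j]) - float(b[i, j]))
                                for i in range(4) for j in range(5)]))
        assert reconstruction_l1(a, b).item() == pytest.approx(oracle, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_l1(np.zeros((2, 2)), np.zeros((3, 3)))


class TestCombinedLoss:
    def test_arithmetic(self):
        assert combined_loss(0.0, 0.0, 1.0).item() == 0.0
        assert combined_loss(1.5, 2.25, 1.0).item() == pytest.approx(3.75)
        assert combined_loss(1.0, 2.0, 0.5).item() == pytest.approx(2.0)

    def test_gradient_flows_to_both_terms(self):
        a = T.Tensor(np.array(2.0), requires_grad=True)
        b = T.Tensor(np.array(3.0), requires_grad=True)
        combined_loss(a, b, 0.7).backward()
        assert a.grad == pytest.approx(1.0)
        assert b.grad == pytest.approx(0.7)


@pytest.fixture(scope="module")
def tiny_volumes():
    rng = np.random.default_rng(2)
    X = []
    for i in range(8):
        v = rng.random((32, 32, 32)).astype(np.float32) * 0.2
        v[8 + i:20, 8:20, 10:22] += 0.6
        X.append(v)
    return np.stack(X)


PRETRAIN_KW = dict(feature_size=4, epochs=4, batch_size=2, lr=2e-3,
                   inner_min=3, inner_max=10, outer_min=8, outer_max=16,
                   random_state=0)


class TestPretraining:
    def test_loss_decreases_over_epochs(self, tiny_volumes):
        pt = ContrastivePretrainer(**PRETRAIN_KW).fit(tiny_volumes)
        assert pt.loss_history_[-1] < pt.loss_history_[0]

    def test_single_volume_rejected(self, tiny_volumes):
        with pytest.raises(ValueError, match=">= 2"):
            ContrastivePretrainer(**PRETRAIN_KW).fit(tiny_volumes[:1])

    def test_deterministic_per_seed(self, tiny_volumes):
        a = ContrastivePretrainer(**{**PRETRAIN_KW, "epochs": 2}).fit(tiny_volumes[:4])
        b = ContrastivePretrainer(**{**PRETRAIN_KW, "epochs": 2}).fit(tiny_volumes[:4])
        assert a.loss_history_ == b.loss_history_
        for k in a.encoder_state_:
            np.testing.assert_array_equal(a.encoder_state_[k],
                                          b.encoder_state_[k])

    def test_image_space_contrast_also_trains(self, tiny_volumes):
        pt = ContrastivePretrainer(**{**PRETRAIN_KW, "epochs": 1,
                                      "contrast_on": "image"}).fit(tiny_volumes[:4])
        assert len(pt.loss_history_) == 1


class TestDownstream:
    def test_encoder_frozen_during_downstream_training(self, tiny_volumes,
                                                       toy_cases):
        pt = ContrastivePretrainer(**{**PRETRAIN_KW, "epochs": 1}).fit(
            tiny_volumes[:4])
        snapshot = {k: v.copy() for k, v in pt.encoder_state_.items()}
        X = np.stack([c.image for c in toy_cases[:3]])
        y = np.stack([c.label for c in toy_cases[:3]])
        est = downstream_train(pt, X, y, epochs=2, lr=1e-2, random_state=0)
        enc_after = est.model_.encoder.state_dict()
        for k, v in snapshot.items():
            np.testing.assert_array_equal(enc_after[k], v)
        assert len(est.loss_history_) == 2

    def test_empty_dataset_rejected(self, tiny_volumes):
        pt = ContrastivePretrainer(**{**PRETRAIN_KW, "epochs": 1}).fit(
            tiny_volumes[:4])
        with pytest.raises(ValueError, match="nonempty"):
            downstream_train(pt, np.zeros((0, 32, 32, 32)),
                             np.zeros((0, 32, 32, 32)))
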