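"""Loss identities and the optimization loop (stub-network oracles)."""

import numpy as np
import pytest

from conftest import ConstantFieldNet, shift_with_clamp
from mindcycle import autodiff as ad
from mindcycle.deformation import regularization_loss
from mindcycle.mind import MindConfig, content_loss
from mindcycle.network import NetworkConfig, build_network
from mindcycle.phantom import PhantomConfig, generate_case
from mindcycle.training import (LossWeights, TrainState, cycle_loss,
                                total_loss, train)
from mindcycle.volume_io import Volume

SHAPE = (16, 16, 4)
NET_CFG = NetworkConfig(in_size=SHAPE, base_channels=4, n_resnet_blocks=1,
                        n_scales=2)


@pytest.fixture
def pair(rng):
    a = Volume(np.tanh(rng.normal(size=SHAPE)))
    b = Volume(np.tanh(rng.normal(size=SHAPE)))
    return a, b


def zero_state(seed=0):
    return TrainState(net_a2b=build_network(NET_CFG, seed),
                      net_b2a=build_network(NET_CFG, seed + 1))


class TestCycleLoss:
    def test_zero_init_nets_reconstruct_exactly(self, pair):
        a, b = pair
        state = zero_state()
        loss = cycle_loss(a, b, state.net_b2a, state.net_a2b)
        assert float(loss.value if isinstance(loss, ad.Tensor) else loss) == 0.0

    def test_inverse_translation_stubs_small_loss(self, smooth_volume):
        fwd = ConstantFieldNet((1.0, 0, 0), smooth_volume.data.shape)
        bwd = ConstantFieldNet((-1.0, 0, 0), smooth_volume.data.shape)
        loss = cycle_loss(smooth_volume, smooth_volume, fwd, bwd)
        assert float(loss) < 0.05  # interior cancels; only edges clamp

    def test_same_direction_translations_on_ramp(self):
        # both nets translate by +1 along the ramp: the reconstruction is
        # the ramp advanced twice, so |recon - orig| = 2 * slope except at
        # the two clamped end planes; oracle computed by index shifting
        x = np.arange(16, dtype=float)
        ramp = np.broadcast_to(x[:, None, None], (16, 4, 4)).copy()
        v = Volume(ramp)
        stub = ConstantFieldNet((1.0, 0, 0), ramp.shape)
        loss = cycle_loss(v, v, stub, stub)
        expected = np.abs(shift_with_clamp(shift_with_clamp(ramp, (1, 0, 0)),
                                           (1, 0, 0)) - ramp).mean()
        assert float(loss) == pytest.approx(expected, abs=1e-9)

    def test_size_mismatch_rejected(self, pair):
        a, _ = pair
        small = Volume(np.zeros((8, 8, 4)))
        with pytest.raises(ValueError):
            cycle_loss(a, small, ConstantFieldNet((0, 0, 0), SHAPE),
                       ConstantFieldNet((0, 0, 0), SHAPE))


class TestTotalLoss:
    def test_identical_images_zero_nets(self, pair):
        a, _ = pair
        state = zero_state()
        total, breakdown = total_loss(a, a, state)
        assert float(total.value if isinstance(total, ad.Tensor) else total) \
            == pytest.approx(0.0)
        for term, val in breakdown.items():
            assert val == pytest.approx(0.0), term

    def test_zero_weights_zero_total(self, pair):
        a, b = pair
        state = zero_state(seed=4)
        total, _ = total_loss(a, b, state, LossWeights(0, 0, 0))
        assert float(total.value if isinstance(total, ad.Tensor) else total) \
            == 0.0

    @pytest.mark.parametrize("penalty", ["magnitude", "gradient"])
    def test_stub_nets_match_hand_composed_sum(self, penalty):
        """Six term oracles composed with the lambda weights by hand."""
        case = generate_case(PhantomConfig(seed=3, size=(16, 16, 4),
                                           spacing=(1, 1, 1)))
        a, b = case.vol_a, case.vol_b
        shape = a.data.shape
        fwd = ConstantFieldNet((1.0, 0, 0), shape)   # acts as net_b2a
        bwd = ConstantFieldNet((0, -1.0, 0), shape)  # acts as net_a2b
        state = TrainState(net_a2b=bwd, net_b2a=fwd)
        w = LossWeights(5.0, 1.0, 1.0)
        mind_cfg = MindConfig(patch_size=3, region_size=3)
        total, breakdown = total_loss(a, b, state, w, mind_cfg,
                                      reg_penalty=penalty)

        from mindcycle.deformation import DeformationField, warp
        f_fwd = DeformationField(fwd.disp)
        f_bwd = DeformationField(bwd.disp)
        warped_b = warp(b, f_fwd)
        warped_a = warp(a, f_bwd)
        oracle = {
            "cont_b2a": content_loss(warped_b, a, mind_cfg),
            "reg_b2a": regularization_loss(f_fwd, penalty=penalty),
            "cyc_b": float(np.abs(
                warp(warped_b, f_bwd).data - b.data).mean()),
            "cont_a2b": content_loss(warped_a, b, mind_cfg),
            "reg_a2b": regularization_loss(f_bwd, penalty=penalty),
            "cyc_a": float(np.abs(
                warp(warped_a, f_fwd).data - a.data).mean()),
        }
        hand_total = (w.lambda_cont * (oracle["cont_b2a"] + oracle["cont_a2b"])
                      + w.lambda_reg * (oracle["reg_b2a"] + oracle["reg_a2b"])
                      + w.lambda_cyc * (oracle["cyc_b"] + oracle["cyc_a"]))
        for k, v in oracle.items():
            assert breakdown[k] == pytest.approx(v, abs=1e-6), k
        got = float(total.value if isinstance(total, ad.Tensor) else total)
        assert got == pytest.approx(hand_total, abs=1e-6)

    def test_cycle_weight_ablation_identity(self):
        """With lambda_cyc = 0 and inverse-translation stubs, the total is
        exactly the weighted content + regularization sum."""
        case = generate_case(PhantomConfig(seed=4, size=(16, 16, 4),
                                           spacing=(1, 1, 1)))
        a, b = case.vol_a, case.vol_b
        fwd = ConstantFieldNet((1.0, 0, 0), a.data.shape)
        bwd = ConstantFieldNet((-1.0, 0, 0), a.data.shape)
        state = TrainState(net_a2b=bwd, net_b2a=fwd)
        mind_cfg = MindConfig(patch_size=3, region_size=3)
        total, bd = total_loss(a, b, state, LossWeights(5, 1, 0), mind_cfg)
        want = 5 * (bd["cont_b2a"] + bd["cont_a2b"]) \
            + (bd["reg_b2a"] + bd["reg_a2b"])
        got = float(total.value if isinstance(total, ad.Tensor) else total)
        assert got == pytest.approx(want, abs=1e-12)


class TestTrainLoop:
    def make_pairs(self, n=1):
        cases = [generate_case(PhantomConfig(seed=50 + i, size=SHAPE,
                                             spacing=(1, 1, 1),
                                             deformation_smoothness=5.0))
                 for i in range(n)]
        return [(c.vol_a, c.vol_b) for c in cases]

    def test_zero_epochs_returns_initial_state(self):
        pairs = self.make_pairs()
        state = train(pairs, {"epochs": 0, "network": NET_CFG}, seed=5)
        assert state.epoch == 0
        assert state.loss_history == []
        # zero-init head: the initial transform is the identity
        f = state.net_b2a.predict_field(*pairs[0])
        np.testing.assert_array_equal(f.displacements, 0.0)

    def test_seeded_determinism(self):
        pairs = self.make_pairs()
        cfg = {"epochs": 2, "lr": 1e-3, "network": NET_CFG}
        h1 = train(pairs, cfg, seed=9).loss_history
        h2 = train(pairs, cfg, seed=9).loss_history
        assert h1 == h2

    def test_loss_terms_finite_nonnegative_and_decreasing(self):
        pairs = self.make_pairs()
        cfg = {"epochs": 10, "lr": 5e-3, "network": NET_CFG}
        state = train(pairs, cfg, seed=2)
        for row in state.loss_history:
            for key, val in row.items():
                if key != "epoch":
                    assert np.isfinite(val) and val >= 0, key
        assert state.loss_history[-1]["total"] < state.loss_history[0]["total"]

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            train([], {"epochs": 1}, seed=0)

    def test_log_csv_written(self, tmp_path):
        pairs = self.make_pairs()
        log = tmp_path / "loss.csv"
        train(pairs, {"epochs": 2, "network": NET_CFG, "log_csv": log}, seed=1)
        lines = log.read_text().strip().splitlines()
        assert lines[0].startswith("epoch,")
        assert len(lines) == 3
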