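import numpy as np
import pytest

from toothseg.mesh import GINGIVA, ToothClass
from toothseg.nn.convlstm import BiConvLSTM
from toothseg.nn.layers import (
    BatchNorm2d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2,
    MaxPool2,
)
from toothseg.nn.model import (
    AdamW,
    NetworkConfig,
    SegmentationModel,
    binarize,
    tooth_type_signal,
)


class TestToothTypeSignal:
    def test_values_and_injectivity(self):
        values = [tooth_type_signal(ToothClass(i)) for i in range(16)]
        assert len(set(values)) == 16
        assert all(0 < v <= 1 for v in values)
        assert tooth_type_signal(ToothClass.from_code("L8")) == pytest.approx(1 / 16)

    def test_gingiva_rejected(self):
        with pytest.raises(ValueError):
            tooth_type_signal(GINGIVA)


class TestBinarize:
    def test_rules(self):
        probs = np.array([[0.0, 0.5, 0.50001, 1.0]])
        np.testing.assert_array_equal(binarize(probs, 0.5), [[0, 0, 1, 1]])

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        probs = rng.random((4, 8, 8))
        lo = binarize(probs, 0.3)
        hi = binarize(probs, 0.7)
        assert (hi <= lo).all()


@pytest.fixture(scope="module")
def tiny_model():
    return SegmentationModel(
        NetworkConfig(stage_widths=[4, 8], recurrent_hidden=3, resolution=16, seed=1)
    )


class TestModelContracts:
    def test_output_shape_and_range(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(2, 3, 5, 16, 16)).astype(np.float32)
        probs, _ = tiny_model.forward(x, train=False)
        assert probs.shape == (2, 3, 16, 16)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_eval_deterministic(self, tiny_model):
        x = np.random.default_rng(1).normal(size=(1, 3, 5, 16, 16)).astype(np.float32)
        a, _ = tiny_model.forward(x, train=False)
        b, _ = tiny_model.forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_invariant_to_sequence_length(self, tiny_model):
        """Weights are shared across views: n does not enter the parameter count."""
        n_params = tiny_model.n_parameters()
        for n in (1, 3, 7):
            x = np.zeros((1, n, 5, 16, 16), dtype=np.float32)
            tiny_model.forward(x, train=False)
            assert tiny_model.n_parameters() == n_params

    def test_deep_supervision_heads_exist(self):
        cfg = NetworkConfig(
            stage_widths=[4, 8, 16], recurrent_hidden=2, resolution=16, seed=0
        )
        model = SegmentationModel(cfg)
        x = np.zeros((1, 2, 5, 16, 16), dtype=np.float32)
        probs, aux = model.forward(x, train=True)
        # S-1 auxiliary heads (one per decoder stage), deep -> shallow
        assert len(aux) == len(cfg.stage_widths) - 1
        assert aux[0].shape[-1] == 8 and aux[-1].shape[-1] == 16
        model.backward(np.zeros_like(probs), [np.zeros_like(a) for a in aux])

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        back = SegmentationModel.load(path)
        x = np.random.default_rng(2).normal(size=(1, 2, 5, 16, 16)).astype(np.float32)
        a, _ = tiny_model.forward(x, train=False)
        b, _ = back.forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(stage_widths=[4, 8, 16], resolution=18)


def layer_gradient_check(layer, x_shape, rng, atol=2e-5, rtol=5e-3):
    """Directional finite-difference check of one layer under a random linear
    functional of its output."""
    x = rng.normal(size=x_shape).astype(np.float32)
    y = layer.forward(x, train=True)
    w = rng.normal(size=y.shape).astype(np.float32)

    def loss(xv):
        return float((layer.forward(xv, train=True).astype(np.float64) * w).sum())

    layer.forward(x, train=True)
    for p in layer.params():
        p.grad[...] = 0
    dx = layer.backward(w.copy())
    h = 1e-3
    d = rng.normal(size=x.shape).astype(np.float32)
    num = (loss((x + h * d).astype(np.float32)) - loss((x - h * d).astype(np.float32))) / (2 * h)
    ana = float((dx.astype(np.float64) * d).sum())
    assert num == pytest.approx(ana, rel=rtol, abs=atol * d.size ** 0.5)
    for p in layer.params():
        dp = rng.normal(size=p.value.shape).astype(np.float32)
        orig = p.value.copy()
        p.value = orig + h * dp
        lp = loss(x)
        p.value = orig - h * dp
        lm = loss(x)
        p.value = orig
        num = (lp - lm) / (2 * h)
        layer.forward(x, train=True)
        for q in layer.params():
            q.grad[...] = 0
        layer.backward(w.copy())
        ana = float((p.grad.astype(np.float64) * dp).sum())
        assert num == pytest.approx(ana, rel=rtol, abs=atol * dp.size ** 0.5)


class TestLayerGradients:
    @pytest.mark.parametrize(
        "factory,shape",
        [
            (lambda rng: Conv3x3(3, 4, rng), (2, 3, 6, 6)),
            (lambda rng: Conv1x1(3, 4, rng), (2, 3, 6, 6)),
            (lambda rng: BatchNorm2d(3), (2, 3, 6, 6)),
            (lambda rng: ConvTranspose2(3, 4, rng), (2, 3, 6, 6)),
            (lambda rng: MaxPool2(), (2, 3, 6, 6)),
        ],
        ids=["conv3x3", "conv1x1", "batchnorm", "convtranspose", "maxpool"],
    )
    def test_layer_backward_matches_finite_differences(self, factory, shape):
        rng = np.random.default_rng(0)
        layer_gradient_check(factory(rng), shape, rng)

    def test_bidirectional_convlstm_backward(self):
        rng = np.random.default_rng(0)
        cell = BiConvLSTM(3, 2, rng)

        class SeqAdapter:
            def forward(self, x, train=True):
                return cell.forward(x, train)

            def backward(self, dy):
                return cell.backward(dy)

            def params(self):
                return cell.params()

        layer_gradient_check(SeqAdapter(), (2, 4, 3, 6, 6), rng)


class TestOverfitSanity:
    def test_reduced_model_overfits_one_sequence(self, default_case):
        """A [8,16,32] model trained 200 iterations on one rendered tooth
        sequence drives its Dice loss below 0.1."""
        from toothseg.train import TrainConfig, _render_pair, dice_loss, dice_loss_grad

        ncfg = NetworkConfig(
            stage_widths=[8, 16, 32], recurrent_hidden=4, resolution=32, seed=0
        )
        tcfg = TrainConfig(seq_len=5, resolution=32, iterations=1, seed=0)
        x, y = _render_pair(default_case, 9, ncfg, tcfg)
        model = SegmentationModel(ncfg)
        opt = AdamW(model.params(), lr=3e-3)
        xs, ys = x[None], y[None]
        loss = None
        for _ in range(200):
            opt.zero_grad()
            probs, aux = model.forward(xs, train=True)
            loss = dice_loss(probs[0], ys[0])
            dprobs = dice_loss_grad(probs[0], ys[0])[None]
            daux = []
            from toothseg.train import _downsample_nn, dice_loss_grad as dg

            for a in aux:
                r = _downsample_nn(ys[0], a.shape[-2], a.shape[-1])
                daux.append(dg(a[0], r)[None])
            model.backward(dprobs, daux)
            opt.step()
        probs, _ = model.forward(xs, train=True)
        assert dice_loss(probs[0], ys[0]) < 0.1

    def test_conditioning_signal_changes_output_after_training(self, default_case):
        """Changing only the i_tt channel alters a trained model's masks."""
        from toothseg.train import TrainConfig, _render_pair, dice_loss_grad

        ncfg = NetworkConfig(
            stage_widths=[4, 8], recurrent_hidden=2, resolution=32, seed=0
        )
        tcfg = TrainConfig(seq_len=3, resolution=32, iterations=1, seed=0)
        xa, ya = _render_pair(default_case, 6, ncfg, tcfg)
        xb, yb = _render_pair(default_case, 9, ncfg, tcfg)
        model = SegmentationModel(ncfg)
        opt = AdamW(model.params(), lr=3e-3)
        for _ in range(60):
            for x, y in ((xa, ya), (xb, yb)):
                opt.zero_grad()
                probs, aux = model.forward(x[None], train=True)
                dprobs = dice_loss_grad(probs[0], y)[None]
                model.backward(dprobs, [np.zeros_like(a) for a in aux])
                opt.step()
        x_mod = xa.copy()
        x_mod[:, 4] = xb[0, 4, 0, 0]  # swap in the other tooth's signal
        pa, _ = model.forward(xa[None], train=False)
        pb, _ = model.forward(x_mod[None], train=False)
        assert (binarize(pa) != binarize(pb)).sum() > 0
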