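"""The per-tooth 2D segmentation network.

A shared-weight U-Net (batch normalization between every convolution and its
ReLU, transposed-convolution upsampling) encodes each rendered view of the
5-channel input (depth, 3 normal components, constant tooth-type scalar).
A bi-directional convolutional LSTM then correlates the per-view feature
maps along the view axis; a 1x1 convolution and a sigmoid produce per-view
foreground probabilities.  Auxiliary 1x1 heads on every decoder stage
provide deep supervision.

The tooth-type scalar i_tt conditions the shared network: the 16 tooth types
(L8..L1, R1..R8) map injectively into (0, 1] so a single binary-segmentation
network serves all teeth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..mesh import ToothClass
from .convlstm import BiConvLSTM
from .layers import (
    BatchNorm2d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2,
    MaxPool2,
    Param,
    ReLU,
    sigmoid,
)


@dataclass
class NetworkConfig:
    stage_widths: list[int] = field(default_factory=lambda: [32, 64, 128, 256, 512])
    recurrent_hidden: int = 32
    input_channels: int = 5
    resolution: int = 256
    deep_supervision: bool = True
    threshold: float = 0.5
    stacked_recurrent: bool = False  # second stacked bi-directional layer
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_widths) < 2:
            raise ValueError("need at least 2 stages")
        if self.resolution % (2 ** (len(self.stage_widths) - 1)) != 0:
            raise ValueError("resolution must be divisible by 2^(stages-1)")


def tooth_type_signal(cls: ToothClass) -> float:
    """i_tt = (type_index + 1) / 16 over L8..L1, R1..R8 — injective, in (0,1]."""
    if cls.is_gingiva:
        raise ValueError("gingiva has no tooth-type signal")
    return (cls.index + 1) / 16.0


class _DoubleConv:
    def __init__(self, c_in: int, c_out: int, rng):
        self.conv1 = Conv3x3(c_in, c_out, rng, bias=False)
        self.bn1 = BatchNorm2d(c_out)
        self.act1 = ReLU()
        self.conv2 = Conv3x3(c_out, c_out, rng, bias=False)
        self.bn2 = BatchNorm2d(c_out)
        self.act2 = ReLU()
        self._layers = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act2]

    def forward(self, x, train=True):
        for layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self._layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for l in self._layers for p in l.params()]


class UNet:
    """Encoder-decoder producing full-resolution feature maps of width
    ``stage_widths[0]`` plus per-decoder-stage outputs for deep supervision."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        w = cfg.stage_widths
        self.enc = []
        c_in = cfg.input_channels
        for width in w[:-1]:
            self.enc.append(_DoubleConv(c_in, width, rng))
            c_in = width
        self.pools = [MaxPool2() for _ in w[:-1]]
        self.bottleneck = _DoubleConv(w[-2], w[-1], rng)
        self.ups = []
        self.dec = []
        for i in range(len(w) - 2, -1, -1):
            self.ups.append(ConvTranspose2(w[i + 1], w[i], rng))
            self.dec.append(_DoubleConv(2 * w[i], w[i], rng))
        self._skips = None

    def forward(self, x, train=True):
        """Returns (features, dec_outs) with dec_outs ordered deep -> shallow;
        dec_outs[-1] is ``features`` (full resolution)."""
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        dec_outs = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, train)
            dec_outs.append(x)
        if train:
            self._n_skip_channels = [s.shape[1] for s in skips]
        return x, dec_outs

    def backward(self, d_dec_outs: list[np.ndarray]):
        """d_dec_outs: gradient for each decoder stage output (deep->shallow),
        the last entry including the feature-map gradient."""
        d_skips = []
        dx = None
        widths = self._n_skip_channels
        for i in range(len(self.dec) - 1, -1, -1):
            dy = d_dec_outs[i].copy() if dx is None else d_dec_outs[i] + dx
            dcat = self.dec[i].backward(dy)
            c_skip = widths[len(widths) - 1 - i]
            d_skips.append(np.ascontiguousarray(dcat[:, :c_skip]))
            dx = self.ups[i].backward(np.ascontiguousarray(dcat[:, c_skip:]))
        dx = self.bottleneck.backward(dx)
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(d_skips)
        ):
            dx = pool.backward(dx)
            dx = block.backward(dx + dskip)
        return dx

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottleneck.params()
        for up, block in zip(self.ups, self.dec):
            out += up.params() + block.params()
        return out


class SegmentationModel:
    """Shared-weight per-view U-Net + bi-directional ConvLSTM + sigmoid head."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.unet = UNet(cfg, rng)
        w0 = cfg.stage_widths[0]
        r = cfg.recurrent_hidden
        self.lstm = BiConvLSTM(w0, r, rng)
        self.lstm2 = BiConvLSTM(2 * r, r, rng) if cfg.stacked_recurrent else None
        self.head = Conv1x1(2 * r, 1, rng)
        self.aux_heads = [
            Conv1x1(w, 1, rng) for w in reversed(cfg.stage_widths[:-1])
        ]  # deep -> shallow, matching dec_outs order
        self._cache = None

    # ------------------------------------------------------------------
    def forward(
        self, x_seq: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """x_seq (B, n, C, H, W) float32 -> (probs (B,n,H,W), aux_probs).

        aux_probs (only when deep supervision is on and train=True) are the
        per-decoder-stage sigmoid outputs at their native resolutions,
        ordered deep -> shallow, each (B, n, h_s, w_s).
        """
        bsz, n, c, h, w = x_seq.shape
        flat = np.ascontiguousarray(x_seq.reshape(bsz * n, c, h, w), dtype=np.float32)
        feats, dec_outs = self.unet.forward(flat, train)
        f_seq = feats.reshape(bsz, n, -1, h, w)
        hidden = self.lstm.forward(f_seq, train)
        if self.lstm2 is not None:
            hidden = self.lstm2.forward(hidden, train)
        hid_flat = np.ascontiguousarray(
            hidden.reshape(bsz * n, -1, h, w)
        )
        logits = self.head.forward(hid_flat, train)
        probs = sigmoid(logits).reshape(bsz, n, h, w)
        aux_probs: list[np.ndarray] = []
        if train and self.cfg.deep_supervision:
            for head, out in zip(self.aux_heads, dec_outs):
                al = head.forward(out, train)
                hs, ws = al.shape[2], al.shape[3]
                aux_probs.append(sigmoid(al).reshape(bsz, n, hs, ws))
        if train:
            self._cache = (bsz, n, h, w, probs, aux_probs, len(dec_outs))
        return probs, aux_probs

    def backward(self, dprobs: np.ndarray, daux: list[np.ndarray] | None = None):
        bsz, n, h, w, probs, aux_probs, n_dec = self._cache
        self._cache = None
        dlogits = (dprobs * probs * (1 - probs)).reshape(bsz * n, 1, h, w)
        dhid = self.head.backward(dlogits.astype(np.float32))
        dhid = dhid.reshape(bsz, n, -1, h, w)
        if self.lstm2 is not None:
            dhid = self.lstm2.backward(dhid)
        df_seq = self.lstm.backward(dhid)
        dfeats = np.ascontiguousarray(df_seq.reshape(bsz * n, -1, h, w))
        d_dec = []
        for i in range(n_dec):
            if daux is not None and self.cfg.deep_supervision:
                ap = aux_probs[i]
                hs, ws = ap.shape[2], ap.shape[3]
                dal = (daux[i] * ap * (1 - ap)).reshape(bsz * n, 1, hs, ws)
                d_dec.append(self.aux_heads[i].backward(dal.astype(np.float32)))
            else:
                shape = self.aux_heads[i].w.value.shape[1]
                hs = h >> (n_dec - 1 - i)
                d_dec.append(
                    np.zeros((bsz * n, shape, hs, hs), dtype=np.float32)
                )
        d_dec[-1] = d_dec[-1] + dfeats
        return self.unet.backward(d_dec)

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        out = self.unet.params() + self.lstm.params()
        if self.lstm2 is not None:
            out += self.lstm2.params()
        out += self.head.params()
        for head in self.aux_heads:
            out += head.params()
        return out

    def bn_layers(self) -> list[BatchNorm2d]:
        out = []

        def collect(block):
            out.extend([block.bn1, block.bn2])

        for b in self.unet.enc:
            collect(b)
        collect(self.unet.bottleneck)
        for b in self.unet.dec:
            collect(b)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self.bn_layers()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        arrays["config"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        data = np.load(str(path))
        cfg = NetworkConfig(**json.loads(bytes(data["config"]).decode()))
        model = cls(cfg)
        for i, p in enumerate(model.params()):
            p.value = data[f"p{i}"].astype(np.float32)
        for i, bn in enumerate(model.bn_layers()):
            bn.running_mean = data[f"rm{i}"].astype(np.float32)
            bn.running_var = data[f"rv{i}"].astype(np.float32)
        return model


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary masks: pixel = 1 iff probability strictly exceeds the threshold."""
    return (np.asarray(probs) > threshold).astype(np.uint8)


class AdamW:
    """Decoupled-weight-decay Adam with cosine annealing warm restarts."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        weight_decay: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        restart_period: int = 10_000,
        lr_min: float = 1e-6,
    ):
        self.params = params
        self.lr0 = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.restart_period = restart_period
        self.lr_min = lr_min
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def current_lr(self) -> float:
        t_cur = self.t % self.restart_period
        cos = 0.5 * (1 + np.cos(np.pi * t_cur / self.restart_period))
        return self.lr_min + (self.lr0 - self.lr_min) * cos

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= lr * (
                (m / b1t) / (np.sqrt(v / b2t) + self.eps) + self.wd * p.value
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
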