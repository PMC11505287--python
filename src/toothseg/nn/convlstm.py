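"""Convolutional LSTM over a view sequence, with backprop through time.

Gate pre-activations are a single 3x3 convolution over the concatenation of
the input and the previous hidden state (no peephole connections).  The
bi-directional unit runs two independent cells over the sequence and its
reversal and concatenates their hidden states per view.
"""

from __future__ import annotations

import numpy as np

from .layers import Param, _im2col3, conv3x3_backward, conv3x3_forward, sigmoid


class ConvLSTMCell:
    def __init__(self, c_in: int, c_hidden: int, rng: np.random.Generator):
        self.c_in = c_in
        self.c_hidden = c_hidden
        std = np.sqrt(1.0 / ((c_in + c_hidden) * 9))
        self.w = Param(
            rng.normal(0, std, size=(4 * c_hidden, (c_in + c_hidden) * 9)).astype(
                np.float32
            )
        )
        b = np.zeros(4 * c_hidden, dtype=np.float32)
        b[c_hidden : 2 * c_hidden] = 1.0  # forget-gate bias
        self.b = Param(b)
        self._cache = None

    def forward(self, xs: np.ndarray, train: bool = True) -> np.ndarray:
        """xs (B, T, Cin, H, W) -> hidden states (B, T, Ch, H, W)."""
        bsz, t_len, _, h, w = xs.shape
        ch = self.c_hidden
        h_t = np.zeros((bsz, ch, h, w), dtype=np.float32)
        c_t = np.zeros((bsz, ch, h, w), dtype=np.float32)
        hs = np.empty((bsz, t_len, ch, h, w), dtype=np.float32)
        steps = []
        for t in range(t_len):
            cat = np.concatenate([xs[:, t], h_t], axis=1)
            cols = _im2col3(cat)
            gates = conv3x3_forward(cat, self.w.value, self.b.value, cols)
            i = sigmoid(gates[:, :ch])
            f = sigmoid(gates[:, ch : 2 * ch])
            o = sigmoid(gates[:, 2 * ch : 3 * ch])
            g = np.tanh(gates[:, 3 * ch :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, t] = h_t
            if train:
                steps.append((cat, cols, i, f, o, g, c_prev, tc))
        if train:
            self._cache = steps
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """dhs (B, T, Ch, H, W) -> input gradient (B, T, Cin, H, W)."""
        steps = self._cache
        self._cache = None
        bsz, t_len, ch, h, w = dhs.shape
        dxs = np.empty((bsz, t_len, self.c_in, h, w), dtype=np.float32)
        dh_next = np.zeros((bsz, ch, h, w), dtype=np.float32)
        dc_next = np.zeros((bsz, ch, h, w), dtype=np.float32)
        for t in range(t_len - 1, -1, -1):
            cat, cols, i, f, o, g, c_prev, tc = steps[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dgates = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g * g),
                ],
                axis=1,
            )
            dcat, dw, db = conv3x3_backward(cat, self.w.value, dgates, cols)
            self.w.grad += dw
            self.b.grad += db
            dxs[:, t] = dcat[:, : self.c_in]
            dh_next = dcat[:, self.c_in :]
        return dxs

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BiConvLSTM:
    """Bi-directional ConvLSTM: forward and backward cells, states concatenated."""

    def __init__(self, c_in: int, c_hidden: int, rng: np.random.Generator):
        self.fwd = ConvLSTMCell(c_in, c_hidden, rng)
        self.bwd = ConvLSTMCell(c_in, c_hidden, rng)
        self.c_hidden = c_hidden

    def forward(self, xs: np.ndarray, train: bool = True) -> np.ndarray:
        hf = self.fwd.forward(xs, train)
        hb = self.bwd.forward(xs[:, ::-1], train)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dh: np.ndarray) -> np.ndarray:
        ch = self.c_hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dh[:, :, :ch]))
        dxb = self.bwd.backward(np.ascontiguousarray(dh[:, ::-1, ch:]))[:, ::-1]
        return dxf + dxb

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()
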