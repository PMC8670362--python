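"""Network layers built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv3d", "Linear", "ConvLSTM3d", "BiConvLSTM3d"]

DTYPE = np.float32


class Module:
    """Base class: children registered as attributes, flat parameter list."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, rng):
        fan_in = in_ch * kernel**3
        self.weight = Tensor(
            _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.stride = stride

    def __call__(self, x):
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng):
        self.weight = Tensor(
            (rng.standard_normal((in_f, out_f)) * np.sqrt(1.0 / in_f)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_f, dtype=DTYPE), requires_grad=True)

    def __call__(self, x):
        return ad.linear(x, self.weight, self.bias)


class ConvLSTM3d(Module):
    """Convolutional LSTM over 3D feature maps (stride 1, 'same' padding).

    Gates are computed from one convolution over the channel-concatenated
    input and hidden state; the hidden-state channel count equals
    ``hidden_ch``.
    """

    def __init__(self, in_ch: int, hidden_ch: int, kernel: int, rng):
        fan_in = (in_ch + hidden_ch) * kernel**3
        self.weight = Tensor(
            _he_init(rng, (4 * hidden_ch, in_ch + hidden_ch, kernel, kernel, kernel), fan_in),
            requires_grad=True,
        )
        bias = np.zeros(4 * hidden_ch, dtype=DTYPE)
        bias[hidden_ch : 2 * hidden_ch] = 1.0  # forget-gate bias
        self.bias = Tensor(bias, requires_grad=True)
        self.hidden_ch = hidden_ch

    def step(self, x_t, h, c):
        z = ad.conv3d(ad.concat([x_t, h], axis=1), self.weight, self.bias, stride=1)
        hc = self.hidden_ch
        i = ad.sigmoid(ad.narrow(z, 1, 0, hc))
        f = ad.sigmoid(ad.narrow(z, 1, hc, hc))
        g = ad.tanh(ad.narrow(z, 1, 2 * hc, hc))
        o = ad.sigmoid(ad.narrow(z, 1, 3 * hc, hc))
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def forward_sequence(self, xs, reverse: bool = False):
        """Run over a list of (B, C, X, Y, Z) tensors; returns hidden states
        in the original temporal order."""
        b_sp = xs[0].data.shape
        shape = (b_sp[0], self.hidden_ch) + b_sp[2:]
        h = Tensor(np.zeros(shape, dtype=DTYPE))
        c = Tensor(np.zeros(shape, dtype=DTYPE))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out = [None] * len(xs)
        for t in order:
            h, c = self.step(xs[t], h, c)
            out[t] = h
        return out


class BiConvLSTM3d(Module):
    """Two ConvLSTM passes (forward and backward in time), features
    concatenated per frame -> 2 * hidden_ch channels."""

    def __init__(self, in_ch: int, hidden_ch: int, kernel: int, rng):
        self.fwd = ConvLSTM3d(in_ch, hidden_ch, kernel, rng)
        self.bwd = ConvLSTM3d(in_ch, hidden_ch, kernel, rng)

    def forward_sequence(self, xs):
        hs_f = self.fwd.forward_sequence(xs, reverse=False)
        hs_b = self.bwd.forward_sequence(xs, reverse=True)
        return [ad.concat([f, b], axis=1) for f, b in zip(hs_f, hs_b)]
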