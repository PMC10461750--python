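"""ConvLSTM-UNet: per-frame encoder, recurrent bottleneck, single decoder.

Each frame passes the input/encoder blocks independently; the per-frame
bottleneck features form a sequence consumed by a convolutional LSTM whose
final hidden state is decoded (with UNet skip connections taken as the
temporal mean of per-frame encoder features) into a 2-channel velocity map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smv.velocity_net.layers import (
    F32,
    BatchNorm2d,
    BilinearUp2,
    Conv2d,
    Layer,
    MaxPool2,
    ReLU,
    Sequential,
    conv3_forward,
    conv3_input_grad,
    conv3_param_grad,
)

__all__ = ["NetworkConfig", "ConvLSTMCell", "ConvLSTMUNet"]


@dataclass
class NetworkConfig:
    depth: int = 3
    base_width: int = 32
    lstm_hidden: int | None = None  # default: channels at the bottleneck
    kernel: int = 3
    skip_mode: str = "temporal_mean"  # temporal_mean | last_frame | none

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.kernel != 3:
            raise ValueError("kernel is fixed at 3")
        if self.skip_mode not in ("temporal_mean", "last_frame", "none"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * 2**self.depth

    @property
    def hidden(self) -> int:
        return self.lstm_hidden or self.bottleneck_channels


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvLSTMCell(Layer):
    """Convolutional LSTM cell.

    A single 3x3 convolution over the concatenated (input, hidden) tensor
    yields 4L channels split into forget/input/output gates (sigmoid) and the
    candidate (tanh): c' = f*c + i*g, h' = o*tanh(c').
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.hidden = c_in, hidden
        self.conv = Conv2d(c_in + hidden, 4 * hidden, k=3, rng=rng)
        self.params = self.conv.params
        self.grads = self.conv.grads
        self._caches: list = []

    def train(self, mode: bool = True):
        self.training = mode
        self.conv.train(mode)

    def zero_grad(self):
        self.conv.zero_grad()

    def init_state(self, batch: int, h: int, w: int):
        z = np.zeros((batch, self.hidden, h, w), dtype=F32)
        return z, z.copy()

    def step(self, x_t, h_prev, c_prev):
        """One timestep; caches intermediates for BPTT when training."""
        if x_t.shape[2:] != h_prev.shape[2:]:
            raise ValueError("input/state spatial shape mismatch")
        z = np.concatenate([x_t, h_prev], axis=1).astype(F32)
        gates, zp = conv3_forward(z, self.params["W"], self.params["b"])
        L = self.hidden
        f = _sigmoid(gates[:, :L])
        i = _sigmoid(gates[:, L : 2 * L])
        o = _sigmoid(gates[:, 2 * L : 3 * L])
        g = np.tanh(gates[:, 3 * L :])
        c_new = f * c_prev + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if self.training:
            self._caches.append((zp, z.shape, f, i, o, g, c_prev, tc))
        return h_new.astype(F32), c_new.astype(F32)

    def reset(self):
        self._caches = []

    def backward_sequence(self, dh_last, dc_last=None):
        """BPTT over all cached steps (last to first).

        Returns per-timestep input gradients (list aligned with step order).
        """
        L = self.hidden
        dh = dh_last.astype(F32)
        dc = np.zeros_like(dh) if dc_last is None else dc_last.astype(F32)
        dx_list = []
        for zp, zshape, f, i, o, g, c_prev, tc in reversed(self._caches):
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_prev = dc * f
            dgates = np.concatenate(
                [df * f * (1 - f), di * i * (1 - i), do * o * (1 - o), dg * (1 - g**2)],
                axis=1,
            ).astype(F32)
            conv3_param_grad(zp, dgates, self.grads["W"], self.grads["b"])
            dz = conv3_input_grad(dgates, self.params["W"])
            dx_list.append(dz[:, : self.c_in])
            dh = dz[:, self.c_in :]
            dc = dc_prev
        self._caches = []
        return dx_list[::-1], dh, dc


def _conv_block(c_in, c_out, rng):
    return Sequential(
        Conv2d(c_in, c_out, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
        Conv2d(c_out, c_out, rng=rng),
        BatchNorm2d(c_out),
        ReLU(),
    )


class ConvLSTMUNet:
    """Frame sequence (B, T, 1, H, W) -> velocity map (B, 2, H, W)."""

    def __init__(self, cfg: NetworkConfig | None = None, rng_seed: int = 0):
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(rng_seed)
        w = self.cfg.base_width
        self.input_block = _conv_block(1, w, rng)
        self.encoders = []
        ch = w
        for _ in range(self.cfg.depth):
            self.encoders.append(Sequential(MaxPool2(), *_conv_block(ch, ch * 2, rng).layers))
            ch *= 2
        self.lstm = ConvLSTMCell(ch, self.cfg.hidden, rng=rng)
        self.decoders = []
        dec_in = self.cfg.hidden
        for _ in range(self.cfg.depth):
            skip_ch = ch // 2 if self.cfg.skip_mode != "none" else 0
            self.decoders.append(
                {
                    "up": BilinearUp2(),
                    "conv": _conv_block(dec_in + skip_ch, ch // 2, rng),
                }
            )
            ch //= 2
            dec_in = ch
        self.out_conv = Conv2d(ch, 2, rng=rng)
        self._modules = (
            [self.input_block] + self.encoders + [self.lstm]
            + [d["conv"] for d in self.decoders]
            + [d["up"] for d in self.decoders]
            + [self.out_conv]
        )
        self.training = True

    # -- bookkeeping ---------------------------------------------------

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)

    def zero_grad(self):
        for m in self._modules:
            m.zero_grad()

    def named_params(self):
        out = []
        for mi, m in enumerate(self._modules):
            if isinstance(m, Sequential):
                out += [(f"m{mi}.{n}", lay, k) for n, lay, k in m.named_params()]
            else:
                out += [(f"m{mi}.{k}", m, k) for k in m.params]
        return out

    def state_dict(self):
        sd = {}
        for name, layer, key in self.named_params():
            sd[name] = layer.params[key].copy()
        for mi, m in enumerate(self._modules):
            for lay_i, lay in enumerate(_iter_layers(m)):
                if isinstance(lay, BatchNorm2d):
                    sd[f"bn{mi}.{lay_i}.mean"] = lay.running_mean.copy()
                    sd[f"bn{mi}.{lay_i}.var"] = lay.running_var.copy()
        return sd

    def load_state_dict(self, sd):
        for name, layer, key in self.named_params():
            layer.params[key][...] = sd[name]
        for mi, m in enumerate(self._modules):
            for lay_i, lay in enumerate(_iter_layers(m)):
                if isinstance(lay, BatchNorm2d):
                    lay.running_mean[...] = sd[f"bn{mi}.{lay_i}.mean"]
                    lay.running_var[...] = sd[f"bn{mi}.{lay_i}.var"]

    # -- forward / backward --------------------------------------------

    def forward(self, clip: np.ndarray) -> np.ndarray:
        """clip: (B, T, 1, H, W) or (T, 1, H, W); returns (B, 2, H, W)."""
        squeeze = clip.ndim == 4
        if squeeze:
            clip = clip[None]
        b, t, _, h, w = clip.shape
        if h % 2**self.cfg.depth or w % 2**self.cfg.depth:
            raise ValueError(f"H, W must be divisible by {2 ** self.cfg.depth}")
        x = clip.reshape(b * t, 1, h, w).astype(F32)
        feats = [self.input_block.forward(x)]
        for enc in self.encoders:
            feats.append(enc.forward(feats[-1]))
        self._bt = (b, t)
        # temporal reduction through the ConvLSTM
        bott = feats[-1]
        _, cb, hb, wb = bott.shape
        seq = bott.reshape(b, t, cb, hb, wb)
        self.lstm.reset()
        hs, cs = self.lstm.init_state(b, hb, wb)
        for ti in range(t):
            hs, cs = self.lstm.step(np.ascontiguousarray(seq[:, ti]), hs, cs)
        # skips
        self._skips = []
        y = hs
        for li, dec in enumerate(self.decoders):
            y = dec["up"].forward(y)
            level = self.cfg.depth - 1 - li
            if self.cfg.skip_mode != "none":
                f = feats[level].reshape(b, t, *feats[level].shape[1:])
                skip = f.mean(axis=1) if self.cfg.skip_mode == "temporal_mean" else f[:, -1]
                self._skips.append(skip.shape)
                y = np.concatenate([y, skip.astype(F32)], axis=1)
            y = dec["conv"].forward(y)
        out = self.out_conv.forward(y)
        if self.training:
            self._feats_shapes = [f.shape for f in feats]
        return out[0] if squeeze else out

    def backward(self, grad: np.ndarray) -> None:
        """Backprop from the output gradient; accumulates parameter grads."""
        if grad.ndim == 3:
            grad = grad[None]
        b, t = self._bt
        g = self.out_conv.backward(grad.astype(F32))
        skip_grads: dict[int, np.ndarray] = {}
        for li in range(len(self.decoders) - 1, -1, -1):
            dec = self.decoders[li]
            g = dec["conv"].backward(g)
            level = self.cfg.depth - 1 - li
            if self.cfg.skip_mode != "none":
                c_up = g.shape[1] - self._feats_shapes[level][1]
                g_skip = g[:, c_up:]
                g = g[:, :c_up]
                skip_grads[level] = g_skip
            g = dec["up"].backward(g)
        dx_list, _, _ = self.lstm.backward_sequence(g)
        dbott = np.stack(dx_list, axis=1)  # (B, T, Cb, hb, wb)
        g = dbott.reshape(b * t, *dbott.shape[2:])
        for level in range(self.cfg.depth, 0, -1):
            g = self.encoders[level - 1].backward(self._add_skip_grad(g, skip_grads, level, b, t))
        g = self._add_skip_grad(g, skip_grads, 0, b, t)
        self.input_block.backward(g)

    def _add_skip_grad(self, g, skip_grads, level, b, t):
        if level not in skip_grads:
            return g
        gs = skip_grads[level]  # (B, C, H, W)
        shaped = g.reshape(b, t, *g.shape[1:])
        if self.cfg.skip_mode == "temporal_mean":
            shaped = shaped + gs[:, None] / t
        else:  # last_frame
            shaped[:, -1] += gs
        return shaped.reshape(g.shape)


def _iter_layers(m):
    if isinstance(m, Sequential):
        for lay in m.layers:
            yield from _iter_layers(lay)
    else:
        yield m
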