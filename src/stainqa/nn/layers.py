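"""Parameterized layers and network modules built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, upsample2


class Module:
    """Base class: tracks parameter tensors, supports freezing and state I/O."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        params.extend(v.parameters())
                    elif isinstance(v, Tensor):
                        params.append(v)
        return params

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.w = _he(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = _he(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class UNetSmall(Module):
    """Two-level encoder-decoder with a skip connection.

    Desk-scale generator for the staining transforms: base width ``ch``
    channels at full resolution, ``2*ch`` at half resolution, nearest-neighbour
    upsampling, linear output (images are standardized before the network and
    de-standardized after).
    """

    def __init__(self, c_in: int, c_out: int, ch: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.enc1 = Conv(rng, c_in, ch)
        self.enc2 = Conv(rng, ch, ch)
        self.down = Conv(rng, ch, 2 * ch, stride=2)
        self.mid = Conv(rng, 2 * ch, 2 * ch)
        self.up = Conv(rng, 2 * ch, ch)
        self.dec1 = Conv(rng, 2 * ch, ch)
        self.out = Conv(rng, ch, c_out, k=1, pad=0)

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc2(self.enc1(x).relu()).relu()
        m = self.mid(self.down(e1).relu()).relu()
        u = self.up(upsample2(m)).relu()
        d = self.dec1(concat([u, e1], axis=1)).relu()
        return self.out(d)


class Discriminator(Module):
    """Four strided conv layers, global average pool, scalar probability."""

    def __init__(self, c_in: int, ch: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.c1 = Conv(rng, c_in, ch, stride=2)
        self.c2 = Conv(rng, ch, 2 * ch, stride=2)
        self.c3 = Conv(rng, 2 * ch, 4 * ch, stride=2)
        self.c4 = Conv(rng, 4 * ch, 8 * ch, stride=2)
        self.fc = Dense(rng, 8 * ch, 1)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        h = self.c4(h).relu()
        pooled = h.mean(axis=(2, 3))
        return self.fc(pooled).sigmoid()  # (B, 1) probability of "real"


class ConvBackbone(Module):
    """Small frozen feature extractor: three strided convs, then per-channel
    mean *and* standard deviation over space.

    Stands in for a large pretrained classification trunk at desk scale; the
    weights are drawn once from a seeded He-normal initialization and then
    frozen, so features are a fixed random projection with local spatial
    structure.  The pooling keeps both first and second spatial moments per
    channel — a plain spatial average is nearly blind to localized content
    changes (e.g. one missing nucleus), which the channel variance retains.
    The feature length is ``2 * c_feat``.  Exposes the last convolutional
    activation map for class-activation mapping.
    """

    def __init__(self, c_in: int = 3, c_feat: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        mid = max(c_feat // 4, 4)
        self.c1 = Conv(rng, c_in, mid, stride=2)
        self.c2 = Conv(rng, mid, c_feat // 2, stride=2)
        self.c3 = Conv(rng, c_feat // 2, c_feat, stride=2)
        self.c_feat = c_feat
        self.feature_dim = 2 * c_feat
        self.in_channels = c_in
        self.seed = seed
        self.freeze()

    def forward(self, x: Tensor, return_activation: bool = False):
        h = self.c1(x).relu()
        h = self.c2(h).relu()
        act = self.c3(h).relu()                    # (B, c_feat, H/8, W/8)
        mean = act.mean(axis=(2, 3), keepdims=True)
        var = ((act - mean) ** 2).mean(axis=(2, 3))
        sd = (var + 1e-8) ** 0.5
        feat = concat([mean.reshape(act.shape[0], self.c_feat), sd], axis=1)
        if return_activation:
            return feat, act
        return feat


class TemporalHead(Module):
    """Temporal voting head over a (2T, C_f) feature sequence.

    Two temporal 1x1 convolutions (linear maps across the time axis, applied
    independently at each feature position) with ReLU collapse the 2T frames
    to a single spatio-temporal vector, followed by two dense layers emitting
    the positive/negative class logits.
    """

    def __init__(self, two_t: int, c_feat: int, hidden_t: int = 8,
                 hidden_d: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.two_t = two_t
        self.t1 = Dense(rng, two_t, hidden_t)
        self.t2 = Dense(rng, hidden_t, 1)
        self.d1 = Dense(rng, c_feat, hidden_d)
        self.d2 = Dense(rng, hidden_d, 2)

    def forward(self, f_s: Tensor) -> Tensor:
        """f_s: (B, 2T, C_f) -> logits (B, 2)."""
        x = f_s.transpose(0, 2, 1)            # (B, C_f, 2T)
        h = self.t1(x).relu()                 # (B, C_f, hidden_t)
        f_st = self.t2(h).relu()              # (B, C_f, 1)
        f_st = f_st.reshape(f_s.shape[0], -1)  # (B, C_f)
        return self.d2(self.d1(f_st).relu())
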