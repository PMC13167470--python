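"""Convolutional building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv_nd


class Module:
    """Base class; children are discovered via attribute scan."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()


class Conv(Module):
    """Stride-1 'same' convolution, fan-in scaled Gaussian init."""

    def __init__(self, cin, cout, kernel, dims, rng, gain=1.0):
        ksp = (kernel,) * dims if np.isscalar(kernel) else tuple(kernel)
        fan_in = cin * int(np.prod(ksp))
        std = gain * np.sqrt(2.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, std, size=(cout, cin) + ksp), requires_grad=True
        )
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return conv_nd(x, self.w, self.b)


class ConvBlock(Module):
    """`depth` conv layers with ELU activations."""

    def __init__(self, cin, cout, dims, rng, depth=1, kernel=3):
        self.layers = [
            Conv(cin if i == 0 else cout, cout, kernel, dims, rng)
            for i in range(depth)
        ]

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x).elu()
        return x
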