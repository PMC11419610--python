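"""Feature-pyramid fusion blocks: BiC and SlimCSPSPPF.

BiC (bi-directional concatenation) fuses three adjacent pyramid depths into
one map at the middle resolution: the same-depth map is reduced by a 1x1
convolution, the shallower (2x larger) map is reduced 1x1 then downsampled by
a stride-2 3x3 convolution, and the deeper (2x smaller) map is upsampled by a
2x2 stride-2 transposed convolution; the three are concatenated and reduced
1x1 to the configured output width.

SlimCSPSPPF splits the deepest map into two paths: one runs a compound
convolution (1x1 -> 3x3) followed by SPPF-style cascaded 5x5 stride-1 max
pooling (three times, all stages concatenated), the other is a 1x1 skip
convolution; the paths are concatenated and reduced 1x1.  Spatial size is
preserved.

Both blocks take ``norm``/``activation`` switches; with ``norm=False,
activation='identity'`` they are exactly linear in their inputs, which the
tests exploit for superposition checks.  Internal branch widths default to
half the output channels.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .nn import CBL, ConvTranspose2x2, Module, max_pool2d_s1

__all__ = ["BiC", "SlimCSPSPPF"]


class BiC(Module):
    """Bi-directional concatenation of shallow / same-depth / deep features."""

    def __init__(self, shallow_ch: int, same_ch: int, deep_ch: int,
                 out_ch: int, hidden_ch: int | None = None,
                 norm: bool = True, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = hidden_ch or max(out_ch // 2, 1)
        self.reduce_same = CBL(same_ch, c, kernel=1, norm=norm,
                               activation=activation, rng=rng)
        self.reduce_shallow = CBL(shallow_ch, c, kernel=1, norm=norm,
                                  activation=activation, rng=rng)
        self.down_shallow = CBL(c, c, kernel=3, stride=2, norm=norm,
                                activation=activation, rng=rng)
        self.up_deep = ConvTranspose2x2(deep_ch, c, rng=rng)
        self.reduce_out = CBL(3 * c, out_ch, kernel=1, norm=norm,
                              activation=activation, rng=rng)

    def forward(self, shallow: Tensor, same: Tensor, deep: Tensor) -> Tensor:
        n, _, h, w = same.shape
        if shallow.shape[-2:] != (2 * h, 2 * w) or deep.shape[-2:] != (h // 2, w // 2):
            raise ValueError(
                f"pyramid ladder mismatch: shallow {shallow.shape[-2:]}, "
                f"same {(h, w)}, deep {deep.shape[-2:]} (need 2x / 1x / 0.5x)")
        a = self.reduce_same(same)
        b = self.down_shallow(self.reduce_shallow(shallow))
        d = self.up_deep(deep)
        return self.reduce_out(concat([a, b, d], axis=1))


class SlimCSPSPPF(Module):
    """CSP-style split with cascaded max-pool spatial pyramid pooling."""

    def __init__(self, in_ch: int, out_ch: int, hidden_ch: int | None = None,
                 pool: int = 5, norm: bool = True, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = hidden_ch or max(out_ch // 2, 1)
        self.pool = pool
        # pyramid path: compound conv then SPPF cascade
        self.pre1 = CBL(in_ch, c, kernel=1, norm=norm, activation=activation, rng=rng)
        self.pre3 = CBL(c, c, kernel=3, norm=norm, activation=activation, rng=rng)
        self.post = CBL(4 * c, c, kernel=1, norm=norm, activation=activation, rng=rng)
        # skip path
        self.skip = CBL(in_ch, c, kernel=1, norm=norm, activation=activation, rng=rng)
        self.reduce_out = CBL(2 * c, out_ch, kernel=1, norm=norm,
                              activation=activation, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if min(x.shape[-2:]) < self.pool:
            raise ValueError(f"spatial size {x.shape[-2:]} smaller than pool {self.pool}")
        y0 = self.pre3(self.pre1(x))
        p1 = max_pool2d_s1(y0, self.pool)
        p2 = max_pool2d_s1(p1, self.pool)
        p3 = max_pool2d_s1(p2, self.pool)
        pyramid = self.post(concat([y0, p1, p2, p3], axis=1))
        return self.reduce_out(concat([pyramid, self.skip(x)], axis=1))
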