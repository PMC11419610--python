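"""IoU-family bounding-box regression losses: IoU, CIoU, WIoU v1 and v3.

Boxes are center-form ``(cx, cy, w, h)`` in continuous pixel units, given as
4-vectors, ``(..., 4)`` arrays, autodiff Tensors, or :class:`~flexdetect.io_formats.Box`
objects.  All functions broadcast over leading axes and are differentiable
when called with Tensors.

Wise-IoU v1 scales the plain IoU loss by an exponential center-distance
factor computed against the smallest enclosing box:

    R_WIoU = exp(((x - x_gt)^2 + (y - y_gt)^2) / (w_c^2 + h_c^2)*)
    L_WIoUv1 = R_WIoU * L_IoU

where the starred denominator is treated as a constant (excluded from
gradient propagation) so the factor does not create gradients that grow the
enclosing box.

Wise-IoU v3 adds a dynamic non-monotonic focusing gain.  The "outlier
degree" of a sample is its detached instantaneous IoU loss relative to the
momentum running mean of IoU losses seen so far,

    beta = L_IoU* / mean_L_IoU,    r = beta * alpha^(delta - beta),
    L_WIoUv3 = r * L_WIoUv1.

r vanishes at beta = 0, equals delta at beta = delta, and decays for large
beta, so both very easy and very hard (likely mislabeled) samples receive
small gradient gain while average-quality samples dominate — the mechanism
that makes training robust to low-quality box annotations.  The gain is
computed from detached quantities; gradients flow only through L_WIoUv1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, maximum, minimum
from .io_formats import Box

__all__ = [
    "LossState", "iou", "l_iou", "ciou", "r_wiou", "wiou_v1",
    "outlier_degree", "focusing_gain", "wiou_v3", "BOX_LOSSES", "box_loss",
]

_EPS = 1e-10


def _as_box_tensor(b) -> Tensor:
    if isinstance(b, Tensor):
        return b
    if isinstance(b, Box):
        return Tensor(np.array([b.cx, b.cy, b.w, b.h], dtype=float))
    return Tensor(np.asarray(b, dtype=float))


def _maybe_float(result: Tensor, *inputs):
    if result.data.size == 1 and not any(isinstance(i, Tensor) for i in inputs):
        return float(result.data)
    return result


def _corners(b: Tensor):
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5


def iou(a, b):
    """Intersection-over-union of two center-form boxes (symmetric, in [0,1])."""
    ta, tb = _as_box_tensor(a), _as_box_tensor(b)
    if np.any(ta.data[..., 2:] <= 0) or np.any(tb.data[..., 2:] <= 0):
        raise ValueError("degenerate box: width and height must be > 0")
    ax1, ay1, ax2, ay2 = _corners(ta)
    bx1, by1, bx2, by2 = _corners(tb)
    iw = maximum(minimum(ax2, bx2) - maximum(ax1, bx1), 0.0)
    ih = maximum(minimum(ay2, by2) - maximum(ay1, by1), 0.0)
    inter = iw * ih
    # union >= max(area_a, area_b) > 0 for valid boxes: no epsilon needed
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return _maybe_float(inter / union, a, b)


def l_iou(a, b):
    """IoU loss ``1 - IoU``."""
    return 1.0 - iou(a, b)


def ciou(a, b):
    """Complete-IoU loss: overlap + center distance + aspect-ratio terms.

    ``L = 1 - IoU + rho^2 / c^2 + alpha * v`` with v the squared arctan
    aspect difference and alpha = v / ((1 - IoU) + v) treated as a constant.
    Baseline loss the Wise-IoU variants are compared against.
    """
    ta, tb = _as_box_tensor(a), _as_box_tensor(b)
    li = 1.0 - iou(ta, tb)
    ax1, ay1, ax2, ay2 = _corners(ta)
    bx1, by1, bx2, by2 = _corners(tb)
    cw = maximum(ax2, bx2) - minimum(ax1, bx1)
    ch = maximum(ay2, by2) - minimum(ay1, by1)
    rho2 = ((ta[..., 0] - tb[..., 0]) ** 2 + (ta[..., 1] - tb[..., 1]) ** 2)
    c2 = cw ** 2 + ch ** 2 + _EPS
    v = (4.0 / np.pi ** 2) * ((tb[..., 2] / tb[..., 3]).arctan()
                              - (ta[..., 2] / ta[..., 3]).arctan()) ** 2
    alpha = v.data / (li.data + v.data + _EPS)  # constant weight, no grad
    return _maybe_float(li + rho2 / c2 + Tensor(alpha) * v, a, b)


def r_wiou(a, b):
    """Exponential center-distance factor of WIoU v1 (>= 1).

    The enclosing-box denominator ``w_c^2 + h_c^2`` is detached so this
    factor never shrinks/grows the enclosing box through its own gradient.
    """
    ta, tb = _as_box_tensor(a), _as_box_tensor(b)
    ax1, ay1, ax2, ay2 = _corners(ta)
    bx1, by1, bx2, by2 = _corners(tb)
    wc = maximum(ax2, bx2) - minimum(ax1, bx1)
    hc = maximum(ay2, by2) - minimum(ay1, by1)
    denom = (wc ** 2 + hc ** 2).detach() + _EPS
    if np.any(denom.data <= _EPS):
        raise ValueError("zero enclosing box")
    dist2 = ((ta[..., 0] - tb[..., 0]) ** 2 + (ta[..., 1] - tb[..., 1]) ** 2)
    return _maybe_float((dist2 / denom).exp(), a, b)


def wiou_v1(a, b):
    """WIoU v1 loss: ``R_WIoU * L_IoU``."""
    ta, tb = _as_box_tensor(a), _as_box_tensor(b)
    return _maybe_float(r_wiou(ta, tb) * (1.0 - iou(ta, tb)), a, b)


@dataclass
class LossState:
    """Running statistics driving WIoU v3's dynamic focusing.

    ``running_mean`` tracks the momentum-averaged IoU loss (outside the
    gradient flow); ``alpha``/``delta`` shape the focusing gain; ``momentum``
    is the update rate of the mean.
    """

    alpha: float = 1.9
    delta: float = 3.0
    momentum: float = 0.01
    eps: float = 1e-8
    running_mean: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha > 1 and self.delta > 0 and 0 < self.momentum <= 1):
            raise ValueError("require alpha > 1, delta > 0, momentum in (0, 1]")

    def update(self, liou_value: float | np.ndarray) -> None:
        val = float(np.mean(liou_value))
        if self.running_mean is None:
            self.running_mean = val
        else:
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * val)


def outlier_degree(a, b, state: LossState, update: bool = True):
    """beta = detached instantaneous L_IoU / running-mean L_IoU (>= 0).

    Reads the running mean first, then (by default) folds the current loss
    into it.  A fresh state seeds the mean with the current loss, so the
    first call returns beta = 1.
    """
    li = l_iou(_as_box_tensor(a), _as_box_tensor(b)).data
    if state.running_mean is None:  # self-normalized start: beta = 1
        state.running_mean = float(np.mean(li))
    beta = li / max(state.running_mean, state.eps)
    if update:
        state.update(li)
    return beta if beta.ndim else float(beta)


def focusing_gain(beta, alpha: float = 1.9, delta: float = 3.0):
    """Non-monotonic gain ``r = beta * alpha^(delta - beta)``.

    r(0) = 0, r(delta) = delta, r -> 0 as beta -> inf; maximal near
    beta = 1 / ln(alpha) + ... (located by the tests via grid search).
    """
    beta = np.asarray(beta, dtype=float)
    r = beta * alpha ** (delta - beta)
    return float(r) if r.ndim == 0 else r


def wiou_v3(a, b, state: LossState, literal_eq16: bool = False):
    """WIoU v3 loss: focusing gain times WIoU v1.

    ``literal_eq16`` evaluates the outlier degree with the instantaneous loss
    in both numerator and denominator (the printed form), which is
    identically 1; the default uses the running-mean denominator.
    """
    ta, tb = _as_box_tensor(a), _as_box_tensor(b)
    if literal_eq16:
        beta = np.ones(np.shape(l_iou(ta, tb).data))
        state.update(l_iou(ta, tb).data)
    else:
        beta = np.asarray(outlier_degree(ta, tb, state))
    r = focusing_gain(beta, state.alpha, state.delta)
    return _maybe_float(Tensor(np.asarray(r)) * wiou_v1(ta, tb), a, b)


def box_loss(name: str, a, b, state: LossState | None = None):
    """Dispatch by config string: ``iou | ciou | wiou1 | wiou3``."""
    if name == "iou":
        return l_iou(a, b)
    if name == "ciou":
        return ciou(a, b)
    if name == "wiou1":
        return wiou_v1(a, b)
    if name == "wiou3":
        if state is None:
            raise ValueError("wiou3 requires a LossState")
        return wiou_v3(a, b, state)
    raise ValueError(f"unknown box loss {name!r}")


BOX_LOSSES = ("iou", "ciou", "wiou1", "wiou3")
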