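"""The unsupervised training objective.

``L_total = L_sim + alpha * L_reg + beta * L_cons`` with

* ``L_sim``   — negative local normalised cross-correlation (LNCC) between
  the pre-compression frame and the displacement-warped post-compression
  frame;
* ``L_reg``   — mean absolute second-order finite differences of the axial
  displacement (the L1 norm of the strain spatial gradient);
* ``L_cons``  — negative LNCC between the previous strain field and the
  warped current strain field, enforcing temporal consistency of the
  elastogram sequence.

All three terms are means over valid windows/pixels rather than sums, so
the weights stay scale-free across image sizes; ``sum_reduction=True`` on
:func:`smoothness_loss` restores a summed penalty.

Every function accepts either plain NumPy arrays (returning floats) or
autodiff tensors (returning tensors), so the exact same code path is used
for metric evaluation and for gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .transforms import DisplacementField

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "lncc",
    "similarity_loss",
    "smoothness_loss",
    "consistency_loss",
    "total_loss",
]


@dataclass
class LossWeights:
    """Weights and window parameters of the training objective.

    ``alpha`` weighs the strain-smoothness regulariser and ``beta`` the
    temporal consistency term (``beta`` is forced to zero for the
    feed-forward variant and for the first pair of a sequence, where no
    previous strain exists).
    """

    alpha: float = 5.0
    beta: float = 0.2
    lncc_window: tuple[int, int] = (15, 15)
    epsilon: float = 1e-5
    regularize_lateral: bool = False

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        h, w = self.lncc_window
        if h % 2 == 0 or w % 2 == 0:
            raise ValueError("LNCC window dimensions must be odd")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LossBreakdown:
    sim: object
    reg: object
    cons: object
    total: object

    def as_floats(self) -> "LossBreakdown":
        def f(x):
            if x is None:
                return 0.0
            return x.item() if isinstance(x, Tensor) else float(x)

        return LossBreakdown(f(self.sim), f(self.reg), f(self.cons),
                             f(self.total))


def _is_numpy(*args) -> bool:
    return not any(isinstance(a, Tensor) for a in args)


def _maybe_float(x: Tensor, to_float: bool):
    return x.item() if to_float else x


def lncc(a, b, window: tuple[int, int] = (15, 15), mask=None,
         epsilon: float = 1e-5):
    """Mean windowed NCC between two images, in ``[-1, 1]``.

    Sliding windows (stride 1) are realised with box-filtered local
    moments; each window score is
    ``sum((W1-mu1)(W2-mu2)) / (N*sigma1*sigma2 + eps)``. Windows whose
    standard deviation falls below ``epsilon`` or that touch a pixel
    flagged invalid in ``mask`` are excluded from the average.
    """
    to_float = _is_numpy(a, b)
    at, bt = ad.as_tensor(a), ad.as_tensor(b)
    if at.shape != bt.shape:
        raise ValueError("images must share a shape")
    h, w = window
    if h > at.shape[0] or w > at.shape[1]:
        raise ValueError("LNCC window does not fit in the image")
    n = float(h * w)
    s1 = ad.boxsum(at, h, w)
    s2 = ad.boxsum(bt, h, w)
    s11 = ad.boxsum(at * at, h, w)
    s22 = ad.boxsum(bt * bt, h, w)
    s12 = ad.boxsum(at * bt, h, w)
    cov = s12 - s1 * s2 * (1.0 / n)
    var1 = ad.maximum(s11 - s1 * s1 * (1.0 / n), 0.0)
    var2 = ad.maximum(s22 - s2 * s2 * (1.0 / n), 0.0)
    ncc = cov / (ad.sqrt(var1 * var2) + epsilon)

    ok = (var1.data >= n * epsilon ** 2) & (var2.data >= n * epsilon ** 2)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != at.shape:
            raise ValueError("mask shape must match the images")
        bad = ad._boxsum_np((~mask).astype(np.float64), h, w)
        ok &= bad < 0.5
    count = int(ok.sum())
    if count == 0:
        raise ValueError("no usable LNCC window (all windows invalid)")
    weights = ok.astype(ncc.dtype)
    out = (ncc * Tensor(weights)).sum() * (1.0 / count)
    return _maybe_float(out, to_float)


def _field_tensors(displacement):
    if isinstance(displacement, DisplacementField):
        return Tensor(displacement.axial), Tensor(displacement.lateral)
    if isinstance(displacement, Tensor):
        if displacement.shape[0] != 2:
            raise ValueError("expected a (2, H, W) displacement tensor")
        return displacement[0], displacement[1]
    arr = np.asarray(displacement)
    return Tensor(arr[0]), Tensor(arr[1])


def similarity_loss(pre, post, displacement, weights: LossWeights):
    """``-LNCC(pre, post o T)``: the image-similarity data term."""
    to_float = _is_numpy(pre, post, displacement)
    d_ax, d_lat = _field_tensors(displacement)
    warped, valid = ad.warp_bilinear(ad.as_tensor(post), d_ax, d_lat)
    score = lncc(ad.as_tensor(pre), warped, weights.lncc_window, valid,
                 weights.epsilon)
    return _maybe_float(-score, to_float)


def _second_diff_terms(u: Tensor):
    """The four absolute second-order finite-difference maps of ``u``.

    Pure second differences use the central [1, -2, 1] stencil; the two
    mixed partials apply central first differences in either order.
    """
    d2x = u[:, 2:] - 2.0 * u[:, 1:-1] + u[:, :-2]
    d2y = u[2:, :] - 2.0 * u[1:-1, :] + u[:-2, :]
    dx = (u[:, 2:] - u[:, :-2]) * 0.5
    dy = (u[2:, :] - u[:-2, :]) * 0.5
    dxdy = (dx[2:, :] - dx[:-2, :]) * 0.5
    dydx = (dy[:, 2:] - dy[:, :-2]) * 0.5
    return d2x, d2y, dxdy, dydx


def smoothness_loss(displacement, weights: LossWeights,
                    sum_reduction: bool = False):
    """L1 norm of the strain spatial gradient (axial channel).

    Mean (default) or sum over interior pixels of the four absolute
    second-order derivatives of the predicted axial displacement. With
    ``weights.regularize_lateral`` the lateral channel is penalised too.
    """
    to_float = _is_numpy(displacement)
    d_ax, d_lat = _field_tensors(displacement)
    channels = [d_ax, d_lat] if weights.regularize_lateral else [d_ax]
    total = None
    for u in channels:
        for term in _second_diff_terms(u):
            red = ad.absolute(term).sum() if sum_reduction \
                else ad.absolute(term).mean()
            total = red if total is None else total + red
    if weights.regularize_lateral:
        total = total * 0.5
    return _maybe_float(total, to_float)


def consistency_loss(strain_prev, strain_curr, displacement,
                     weights: LossWeights):
    """``-LNCC(S_{t-1}, S_t o T)`` with T the current-step transformation.

    The current strain lives on the post-compression grid, so the same
    displacement that maps the post frame into the pre frame's space is
    used to map the current strain onto the previous one.
    """
    to_float = _is_numpy(strain_prev, strain_curr, displacement)
    d_ax, d_lat = _field_tensors(displacement)
    warped, valid = ad.warp_bilinear(ad.as_tensor(strain_curr), d_ax, d_lat)
    score = lncc(ad.as_tensor(strain_prev), warped, weights.lncc_window,
                 valid, weights.epsilon)
    return _maybe_float(-score, to_float)


def total_loss(sim, reg, cons, weights: LossWeights) -> LossBreakdown:
    """Exact weighted sum ``sim + alpha*reg + beta*cons``.

    ``cons=None`` states that no previous strain field exists (first pair
    of a sequence, or the feed-forward variant); it is an error to combine
    that with a non-zero ``beta``.
    """
    if cons is None:
        if weights.beta > 0:
            raise ValueError("beta > 0 but no previous strain is available")
        total = sim + weights.alpha * reg
        return LossBreakdown(sim, reg, None, total)
    total = sim + weights.alpha * reg + weights.beta * cons
    return LossBreakdown(sim, reg, cons, total)
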