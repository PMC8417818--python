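"""Dense displacement-field operations: warping, rescaling, composition.

Displacement semantics are backward-mapping throughout: a field ``d``
defined on the grid of a reference image maps each reference pixel ``p``
to the location ``p + d(p)`` in a moving image, so that
``warp(moving, d) ~ reference``. The axial component is array axis 0
(top row = transducer face, positive toward increasing depth index);
the lateral component is axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

__all__ = [
    "DisplacementField",
    "warp",
    "rescale_displacement",
    "compose_displacements",
]


@dataclass
class DisplacementField:
    """Dense two-channel displacement in sample units."""

    axial: np.ndarray
    lateral: np.ndarray

    def __post_init__(self):
        self.axial = np.asarray(self.axial, dtype=np.float64)
        self.lateral = np.asarray(self.lateral, dtype=np.float64)
        if self.axial.shape != self.lateral.shape:
            raise ValueError("axial and lateral channels must share a shape")
        if not (np.isfinite(self.axial).all() and
                np.isfinite(self.lateral).all()):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.axial.shape

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape))

    @classmethod
    def from_stack(cls, stack: np.ndarray) -> "DisplacementField":
        return cls(stack[0], stack[1])

    def stack(self) -> np.ndarray:
        return np.stack([self.axial, self.lateral])


def warp(image: np.ndarray, displacement: DisplacementField):
    """Resample ``image`` through ``displacement`` (bilinear, clamped).

    Returns ``(warped, valid)``: out-of-bounds samples take clamped border
    values and are flagged ``False`` in the boolean validity mask.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != displacement.shape:
        raise ValueError("image and displacement shapes differ")
    out, valid = ad.warp_bilinear(ad.Tensor(image),
                                  ad.Tensor(displacement.axial),
                                  ad.Tensor(displacement.lateral))
    return out.numpy(), valid


def rescale_displacement(displacement: DisplacementField,
                         target_shape) -> DisplacementField:
    """Bilinearly resize a field and scale its values to the new grid.

    A displacement is a length, so the axial values are multiplied by
    ``target_h / h`` and the lateral values by ``target_w / w``.
    """
    h2, w2 = target_shape
    if h2 <= 0 or w2 <= 0:
        raise ValueError("target shape must be positive")
    h, w = displacement.shape
    ax = ad.resize_bilinear(ad.Tensor(displacement.axial), (h2, w2)).numpy()
    la = ad.resize_bilinear(ad.Tensor(displacement.lateral), (h2, w2)).numpy()
    return DisplacementField(ax * (h2 / h), la * (w2 / w))


def compose_displacements(first: DisplacementField,
                          second: DisplacementField) -> DisplacementField:
    """Chain two backward-mapping fields: ``composed(p) = second(p) +
    first(p + second(p))`` with bilinear sampling of ``first``.

    If ``second`` maps grid-A coordinates into image-B space and ``first``
    maps the B grid into image-C space, the composition maps the A grid
    into image-C space (e.g. accumulating consecutive-pair fields of a
    compression sequence into a first-to-last field).
    """
    if first.shape != second.shape:
        raise ValueError("fields must share a shape")
    sec = DisplacementField(second.axial, second.lateral)
    fa, _ = warp(first.axial, sec)
    fl, _ = warp(first.lateral, sec)
    return DisplacementField(second.axial + fa, second.lateral + fl)
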