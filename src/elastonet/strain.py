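"""Axial strain estimation from displacement fields.

Strain is the axial derivative of the axial displacement. Direct finite
differencing amplifies displacement noise, so the standard estimator in
quasi-static elastography is the least-squares strain estimator (LSQSE):
for every pixel, the slope of an ordinary-least-squares line fitted to
displacement versus depth over a sliding axial window. The fit is a fixed
linear filter, so the whole estimator is one banded matrix applied to each
scan line.

Sign convention: tissue under compression has displacement decreasing with
depth in the backward-mapping convention used here, so the raw slope is
negated — compressive strain is reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["StrainField", "lsq_strain", "gradient_strain", "lsq_matrix"]

DEFAULT_WINDOW = 43


@dataclass
class StrainField:
    """Dimensionless axial strain map plus the estimator window used."""

    values: np.ndarray
    window_length: int = field(default=DEFAULT_WINDOW)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("strain field contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


def _ols_slope_weights(length: int) -> np.ndarray:
    idx = np.arange(length, dtype=np.float64)
    centred = idx - idx.mean()
    return centred / (centred ** 2).sum()


@lru_cache(maxsize=32)
def lsq_matrix(n_axial: int, window_length: int) -> np.ndarray:
    """(n, n) matrix mapping one axial displacement line to strain.

    Interior rows hold centred OLS slope weights over ``window_length``
    samples; border rows use the window shrunk to fit (one-sided), never
    smaller than 2 samples. Rows are negated so compression is positive.
    """
    if window_length % 2 == 0:
        raise ValueError("window_length must be odd")
    if window_length < 3 or window_length > n_axial:
        raise ValueError("window_length must be in [3, n_axial]")
    half = window_length // 2
    k = np.zeros((n_axial, n_axial))
    for row in range(n_axial):
        lo = max(0, row - half)
        hi = min(n_axial, row + half + 1)
        if hi - lo < 2:  # pragma: no cover - guarded by window checks
            raise ValueError("degenerate window")
        k[row, lo:hi] = -_ols_slope_weights(hi - lo)
    return k


def lsq_strain(axial_displacement: np.ndarray,
               window_length: int = DEFAULT_WINDOW) -> StrainField:
    """Least-squares strain of a 2D axial displacement grid (per column)."""
    u = np.asarray(axial_displacement, dtype=np.float64)
    if u.ndim != 2:
        raise ValueError("expected a 2D axial displacement grid")
    k = lsq_matrix(u.shape[0], window_length)
    return StrainField(k @ u, window_length)


def gradient_strain(axial_displacement: np.ndarray) -> StrainField:
    """Negated central-difference strain (one-sided at the borders)."""
    u = np.asarray(axial_displacement, dtype=np.float64)
    if u.ndim != 2 or u.shape[0] < 2:
        raise ValueError("need a 2D grid with at least 2 axial samples")
    return StrainField(-np.gradient(u, axis=0), 3)
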