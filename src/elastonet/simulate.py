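"""Synthetic quasi-static compression phantoms with exact ground truth.

The simulator emulates the data used to validate RF speckle tracking:
temporal sequences of speckle-bearing RF frames under monotonically
increasing axial compression, containing one or two stiff circular
inclusions. Instead of a finite-element solve, the local strain field is
an analytic Gaussian-bump model

    eps(y, x) = s * (1 - sum_k (1 - contrast_k) * exp(-d_k^2 / (2 r_k^2)))

with ``s`` the cumulative average strain, ``d_k`` the normalised distance
to inclusion k and ``contrast_k`` in (0, 1] the inclusion/background
strain ratio (a stiff inclusion strains less). The axial displacement is
the depth integral of ``eps`` (closed form via the error function), so
the ground truth is exact rather than numerically approximated.

RF frames are rendered with a convolution speckle model: point scatterers
with Gaussian reflectivity are bilinearly splatted onto the sample grid
and convolved with a separable cosine-modulated Gaussian point-spread
function. Scatterers are *moved* and each frame re-rendered — compression
therefore produces genuine speckle decorrelation, not image interpolation.

Coordinate conventions: axial = array axis 0, top row = transducer face,
displacement positive toward increasing depth. The per-step ground truth
is stored in three forms (all derived from the same closed form):

* ``displacement`` — the cumulative field on the step-t grid mapping
  step-t coordinates to step-0 coordinates (positive axial values);
* ``ref_displacement`` / ``ref_strain`` — the backward-warp field on the
  step-0 grid mapping into step-t space (what a tracker that registers
  frame t onto frame 0 should output; negative axial values);
* ``pair_displacement`` / ``pair_strain`` — the same for the consecutive
  pair (t-1, t), on the step-(t-1) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.special import erf

from .containers import RFSequence
from .strain import StrainField
from .transforms import DisplacementField

__all__ = [
    "PhantomSpec",
    "ScattererSet",
    "GroundTruth",
    "sample_scatterers",
    "analytic_displacement",
    "render_rf",
    "simulate_sequence",
]

#: ten-frame compression ramp: rest frame plus 0.5% .. 4.5% average strain
DEFAULT_SCHEDULE = tuple(np.round(np.arange(1, 10) * 0.005, 6))

MAX_STRAIN = 0.10


@dataclass
class PhantomSpec:
    """Configuration of one synthetic compression phantom.

    ``inclusions`` entries are ``(center_axial, center_lateral, radius,
    strain_contrast)`` with centre/radius in normalised [0, 1] grid
    coordinates and contrast in (0, 1].
    """

    grid_shape: tuple[int, int] = (1024, 128)
    scatterer_density: float = 0.5
    inclusions: tuple = ((0.5, 0.5, 0.15, 0.4),)
    strain_schedule: tuple = DEFAULT_SCHEDULE
    lateral_drift: float = 0.2
    noise_sigma: float = 0.02
    psf: tuple = (0.25, 2.0, 1.5)  # (cycles/sample, sigma_y, sigma_x)
    poisson_ratio: float = 0.495
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        h, w = self.grid_shape
        if h < 8 or w < 8:
            raise ValueError("grid too small")
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be non-negative")
        sched = np.asarray(self.strain_schedule, dtype=np.float64)
        if sched.size and (np.diff(sched) < 0).any():
            raise ValueError("strain_schedule must be non-decreasing")
        if sched.size and (sched.min() < 0 or sched.max() > MAX_STRAIN):
            raise ValueError(f"strains must lie in [0, {MAX_STRAIN}]")
        for cy, cx, r, c in self.inclusions:
            if r <= 0:
                raise ValueError("inclusion radius must be > 0")
            if not 0 < c <= 1:
                raise ValueError("strain_contrast must be in (0, 1]")
        if self.noise_sigma < 0 or self.psf[1] <= 0 or self.psf[2] <= 0:
            raise ValueError("invalid noise/psf parameters")
        return self


@dataclass
class ScattererSet:
    """Continuous scatterer coordinates (sample units) and reflectivities."""

    positions: np.ndarray  # (n, 2) = (axial, lateral)
    amplitudes: np.ndarray  # (n,)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if not np.isfinite(self.amplitudes).all():
            raise ValueError("amplitudes must be finite")


@dataclass
class GroundTruth:
    """Exact deformation imposed at one compression step."""

    displacement: DisplacementField       # step-t grid -> step-0 coords
    strain: StrainField                   # cumulative eps on the step-t grid
    ref_displacement: DisplacementField   # step-0 grid -> step-t coords
    ref_strain: StrainField
    pair_displacement: DisplacementField  # step-(t-1) grid -> step-t coords
    pair_strain: StrainField
    cumulative_strain: float = 0.0


def sample_scatterers(spec: PhantomSpec, seed: int) -> ScattererSet:
    """Uniform random scatterers; count = round(density * grid area)."""
    spec.validate()
    h, w = spec.grid_shape
    count = int(round(spec.scatterer_density * h * w))
    rng = np.random.default_rng(seed)
    pos = rng.uniform([0.0, 0.0], [h - 1.0, w - 1.0], size=(count, 2))
    amp = rng.standard_normal(count)
    return ScattererSet(pos.reshape(count, 2), amp)


# ------------------------------------------------------------ analytic field
def _local_strain(spec: PhantomSpec, s: float, y, x):
    h, w = spec.grid_shape
    yh = np.asarray(y, dtype=np.float64) / (h - 1)
    xh = np.asarray(x, dtype=np.float64) / (w - 1)
    reduction = np.zeros(np.broadcast_shapes(yh.shape, xh.shape))
    for cy, cx, r, c in spec.inclusions:
        d2 = (yh - cy) ** 2 + (xh - cx) ** 2
        reduction = reduction + (1.0 - c) * np.exp(-d2 / (2 * r ** 2))
    return s * (1.0 - reduction)


def _field_at(spec: PhantomSpec, s: float, y, x):
    """Cumulative t->0 displacement (axial, lateral) at continuous coords."""
    h, w = spec.grid_shape
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    yh = y / (h - 1)
    xh = x / (w - 1)
    d_ax = s * y
    for cy, cx, r, c in spec.inclusions:
        lat = np.exp(-((xh - cx) ** 2) / (2 * r ** 2))
        integral = (h - 1) * r * np.sqrt(np.pi / 2) * (
            erf((yh - cy) / (r * np.sqrt(2))) - erf(-cy / (r * np.sqrt(2))))
        d_ax = d_ax - s * (1.0 - c) * lat * integral
    n_steps = len(spec.strain_schedule)
    s_max = spec.strain_schedule[-1] if n_steps else 1.0
    drift = spec.lateral_drift * n_steps * (s / s_max if s_max else 0.0)
    x_c = (w - 1) / 2.0
    d_lat = drift + spec.poisson_ratio * s * (x - x_c) \
        + np.zeros_like(d_ax)
    return d_ax, d_lat


def analytic_displacement(spec: PhantomSpec, cumulative_strain: float):
    """Closed-form cumulative displacement and strain at one strain level.

    The returned field lives on the compressed grid and maps each pixel to
    its rest-state (step-0) coordinate; the strain field is the analytic
    axial derivative of the axial displacement.
    """
    if not 0.0 <= cumulative_strain <= MAX_STRAIN:
        raise ValueError(f"cumulative_strain must be in [0, {MAX_STRAIN}]")
    spec.validate()
    h, w = spec.grid_shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d_ax, d_lat = _field_at(spec, cumulative_strain, yy, xx)
    eps = _local_strain(spec, cumulative_strain, yy, xx)
    return DisplacementField(d_ax, d_lat), StrainField(eps, 0)


def _invert_axial(spec: PhantomSpec, s: float, rest_y, rest_x,
                  tol: float = 1e-9, max_iter: int = 60):
    """Solve p + D(p) = rest for the step-t coordinates of material points.

    The lateral equation is affine in x and solved in closed form; the
    axial equation is solved by fixed-point iteration (contraction factor
    <= max strain, so convergence is fast).
    """
    h, w = spec.grid_shape
    n_steps = len(spec.strain_schedule)
    s_max = spec.strain_schedule[-1] if n_steps else 1.0
    drift = spec.lateral_drift * n_steps * (s / s_max if s_max else 0.0)
    x_c = (w - 1) / 2.0
    nu = spec.poisson_ratio
    p_x = (np.asarray(rest_x, dtype=np.float64) - drift + nu * s * x_c) \
        / (1.0 + nu * s)
    p_y = np.asarray(rest_y, dtype=np.float64).copy()
    for _ in range(max_iter):
        d_ax, _ = _field_at(spec, s, p_y, p_x)
        new = rest_y - d_ax
        if np.max(np.abs(new - p_y)) < tol:
            p_y = new
            break
        p_y = new
    return p_y, p_x


# -------------------------------------------------------------- RF rendering
def _psf_kernels(spec: PhantomSpec):
    f_c, sig_y, sig_x = spec.psf
    ly = int(np.ceil(4 * sig_y))
    lx = int(np.ceil(4 * sig_x))
    y = np.arange(-ly, ly + 1, dtype=np.float64)
    x = np.arange(-lx, lx + 1, dtype=np.float64)
    ky = np.cos(2 * np.pi * f_c * y) * np.exp(-y ** 2 / (2 * sig_y ** 2))
    kx = np.exp(-x ** 2 / (2 * sig_x ** 2))
    return ky, kx


def render_rf(scatterers: ScattererSet, spec: PhantomSpec,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one RF frame from a scatterer set (bilinear splat + PSF)."""
    spec.validate()
    h, w = spec.grid_shape
    grid = np.zeros((h, w))
    if len(scatterers.amplitudes):
        y = np.clip(scatterers.positions[:, 0], 0, h - 1)
        x = np.clip(scatterers.positions[:, 1], 0, w - 1)
        y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
        x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
        ty, tx = y - y0, x - x0
        a = scatterers.amplitudes
        np.add.at(grid, (y0, x0), a * (1 - ty) * (1 - tx))
        np.add.at(grid, (y0, x0 + 1), a * (1 - ty) * tx)
        np.add.at(grid, (y0 + 1, x0), a * ty * (1 - tx))
        np.add.at(grid, (y0 + 1, x0 + 1), a * ty * tx)
    ky, kx = _psf_kernels(spec)
    rf = convolve1d(grid, ky, axis=0, mode="constant")
    rf = convolve1d(rf, kx, axis=1, mode="constant")
    if spec.noise_sigma > 0:
        rng = rng or np.random.default_rng(spec.seed)
        rf = rf + rng.normal(0.0, spec.noise_sigma * rf.std() + 1e-30,
                             size=rf.shape)
    return rf


# ----------------------------------------------------------------- sequences
def simulate_sequence(spec: PhantomSpec):
    """Simulate one compression sequence with exact per-step ground truth.

    Frame 0 is the rest state; frame t is re-rendered from the scatterers
    moved to their positions at ``strain_schedule[t-1]``. Returns
    ``(RFSequence, [GroundTruth, ...])`` with one ground-truth record per
    compressed frame.
    """
    spec.validate()
    h, w = spec.grid_shape
    scat = sample_scatterers(spec, spec.seed)
    schedule = list(spec.strain_schedule)
    frames = []
    noise_rng = np.random.default_rng([spec.seed, 7919])
    frames.append(render_rf(scat, spec, noise_rng))

    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    truths: list[GroundTruth] = []
    prev_s = 0.0
    for s in schedule:
        # move scatterers: step-t position solves p + D_t(p) = rest
        py, px = _invert_axial(spec, s, scat.positions[:, 0],
                               scat.positions[:, 1])
        moved = ScattererSet(np.stack([py, px], axis=1), scat.amplitudes)
        frames.append(render_rf(moved, spec, noise_rng))

        # spec-form cumulative field on the step-t grid (t -> 0)
        disp, strain = analytic_displacement(spec, s)

        # backward-warp field on the step-0 grid (0 -> t)
        qy, qx = _invert_axial(spec, s, yy, xx)
        eps_q = _local_strain(spec, s, qy, qx)
        ref_disp = DisplacementField(qy - yy, qx - xx)
        ref_strain = StrainField(eps_q / (1.0 + eps_q), 0)

        # consecutive-pair field on the step-(t-1) grid (t-1 -> t)
        d_prev_ax, d_prev_lat = _field_at(spec, prev_s, yy, xx)
        rest_y = yy + d_prev_ax
        rest_x = xx + d_prev_lat
        py2, px2 = _invert_axial(spec, s, rest_y, rest_x)
        eps_t = _local_strain(spec, s, py2, px2)
        eps_tm1 = _local_strain(spec, prev_s, yy, xx)
        pair_disp = DisplacementField(py2 - yy, px2 - xx)
        pair_strain = StrainField((eps_t - eps_tm1) / (1.0 + eps_t), 0)

        truths.append(GroundTruth(
            displacement=disp, strain=strain,
            ref_displacement=ref_disp, ref_strain=ref_strain,
            pair_displacement=pair_disp, pair_strain=pair_strain,
            cumulative_strain=float(s)))
        prev_s = s

    seq = RFSequence(np.stack(frames).astype(np.float32),
                     seq_id=f"phantom-{spec.seed}")
    return seq, truths
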