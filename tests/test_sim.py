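"""The synthetic compression phantom: scatterers, analytic deformation,
RF rendering and full sequences with exact ground truth."""

import numpy as np
import pytest

import elastonet as en
from elastonet.simulate import (PhantomSpec, _psf_kernels, render_rf,
                                sample_scatterers)


class TestScatterers:
    def test_density_zero_gives_empty_set(self):
        spec = PhantomSpec(grid_shape=(32, 32), scatterer_density=0.0)
        s = sample_scatterers(spec, 1)
        assert len(s.amplitudes) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            sample_scatterers(PhantomSpec(scatterer_density=-0.1), 1)

    def test_count_is_density_times_area(self):
        spec = PhantomSpec(grid_shape=(100, 50), scatterer_density=0.5)
        s = sample_scatterers(spec, 7)
        assert len(s.amplitudes) == 2500
        assert s.positions[:, 0].min() >= 0
        assert s.positions[:, 0].max() <= 99

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(grid_shape=(40, 40))
        a = sample_scatterers(spec, 42)
        b = sample_scatterers(spec, 42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestAnalyticDisplacement:
    def test_zero_strain_no_inclusions(self):
        spec = PhantomSpec(grid_shape=(32, 32), inclusions=(),
                           lateral_drift=0.0)
        d, s = en.analytic_displacement(spec, 0.0)
        assert np.allclose(d.axial, 0) and np.allclose(d.lateral, 0)
        assert np.allclose(s.values, 0)

    def test_homogeneous_compression_is_linear(self):
        spec = PhantomSpec(grid_shape=(64, 32), inclusions=(),
                           lateral_drift=0.0, poisson_ratio=0.0)
        d, s = en.analytic_displacement(spec, 0.02)
        assert np.allclose(s.values, 0.02)
        assert np.allclose(d.axial, 0.02 * np.arange(64)[:, None])

    def test_inclusion_halves_strain_at_center(self):
        spec = PhantomSpec(grid_shape=(128, 128),
                           inclusions=((0.5, 0.5, 0.05, 0.5),))
        _, s = en.analytic_displacement(spec, 0.02)
        h, w = spec.grid_shape
        center = s.values[(h - 1) // 2, (w - 1) // 2]
        corner = s.values[0, 0]
        assert abs(center - 0.01) < 2e-4  # contrast 0.5 at the bump centre
        assert abs(corner - 0.02) < 1e-4  # far field unaffected

    def test_out_of_range_strain_rejected(self):
        spec = PhantomSpec()
        for bad in (-0.01, 0.2):
            with pytest.raises(ValueError):
                en.analytic_displacement(spec, bad)


class TestRenderRF:
    def test_empty_scatterers_zero_frame(self):
        spec = PhantomSpec(grid_shape=(32, 32), scatterer_density=0.0,
                           noise_sigma=0.0)
        rf = render_rf(sample_scatterers(spec, 0), spec)
        assert np.allclose(rf, 0)

    def test_single_scatterer_reproduces_psf(self):
        spec = PhantomSpec(grid_shape=(64, 64), noise_sigma=0.0)
        scat = en.ScattererSet(np.array([[30.0, 30.0]]), np.array([1.0]))
        rf = render_rf(scat, spec)
        ky, kx = _psf_kernels(spec)
        ly, lx = len(ky) // 2, len(kx) // 2
        patch = rf[30 - ly:30 + ly + 1, 30 - lx:30 + lx + 1]
        assert np.allclose(patch, np.outer(ky, kx), atol=1e-12)
        rf[30 - ly:30 + ly + 1, 30 - lx:30 + lx + 1] = 0
        assert np.allclose(rf, 0)

    def test_envelope_follows_rayleigh_statistics(self):
        """Dense speckle: the analytic envelope of fully developed speckle
        is Rayleigh, whose std/mean = sqrt((4-pi)/pi) ~ 0.5227."""
        from scipy.signal import hilbert
        spec = PhantomSpec(grid_shape=(256, 128), scatterer_density=2.0,
                           noise_sigma=0.0, seed=5)
        rf = render_rf(sample_scatterers(spec, 5), spec)
        env = np.abs(hilbert(rf[20:-20, 10:-10], axis=0))
        ratio = env.std() / env.mean()
        assert abs(ratio - np.sqrt((4 - np.pi) / np.pi)) < 0.05


class TestSequences:
    def test_static_schedule_gives_identical_frames(self):
        spec = PhantomSpec(grid_shape=(32, 32), strain_schedule=(0.0, 0.0),
                           noise_sigma=0.0, lateral_drift=0.0)
        seq, _ = en.simulate_sequence(spec)
        assert np.array_equal(seq.frames[0], seq.frames[1])
        assert np.array_equal(seq.frames[0], seq.frames[2])

    def test_default_schedule_yields_ten_frames(self):
        spec = PhantomSpec(grid_shape=(32, 32))
        seq, gts = en.simulate_sequence(spec)
        assert len(spec.strain_schedule) == 9
        assert len(seq) == 10
        assert len(gts) == 9
        assert [round(g.cumulative_strain, 3) for g in gts] == \
            [0.005, 0.01, 0.015, 0.02, 0.025, 0.03, 0.035, 0.04, 0.045]

    def test_bit_identical_given_same_spec(self, small_spec):
        a, _ = en.simulate_sequence(small_spec)
        b, _ = en.simulate_sequence(small_spec)
        assert np.array_equal(a.frames, b.frames)

    def test_strain_is_derivative_of_displacement(self, small_sequence):
        _, gts = small_sequence
        for g in (gts[0], gts[-1]):
            num = np.gradient(g.displacement.axial, axis=0)
            assert np.abs(num - g.strain.values)[2:-2].max() < 1e-3

    def test_inclusion_strain_ratio_matches_contrast(self):
        spec = PhantomSpec(grid_shape=(128, 128),
                           inclusions=((0.5, 0.5, 0.08, 0.5),))
        _, gts = en.simulate_sequence(
            PhantomSpec(grid_shape=(128, 128),
                        inclusions=((0.5, 0.5, 0.08, 0.5),),
                        strain_schedule=(0.02,)))
        s = gts[0].strain.values
        yy, xx = np.meshgrid(np.linspace(0, 1, 128), np.linspace(0, 1, 128),
                             indexing="ij")
        r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
        inside = s[r2 < 0.04 ** 2].mean()
        background = s[r2 > 0.3 ** 2].mean()
        # bump centre strain ~ contrast * background strain, within 10%
        assert abs(inside / background - 0.5) < 0.1 * 0.5 + 0.05

    def test_pair_fields_compose_to_cumulative(self, small_sequence):
        _, gts = small_sequence
        comp = gts[0].pair_displacement
        for g in gts[1:]:
            comp = en.compose_displacements(g.pair_displacement, comp)
        err = comp.axial - gts[-1].ref_displacement.axial
        assert np.sqrt((err ** 2).mean()) < 0.1

    def test_block_matching_recovers_axial_shift(self):
        """Exhaustive integer NCC block search between frames 0 and 1 at
        1% strain finds the ground-truth axial shift within one sample on
        at least 90% of blocks (independent speckle-tracking oracle)."""
        spec = PhantomSpec(grid_shape=(128, 64), scatterer_density=1.0,
                           strain_schedule=(0.01,), noise_sigma=0.0,
                           lateral_drift=0.0, inclusions=(), seed=2)
        seq, gts = en.simulate_sequence(spec)
        pre = seq.frames[0].astype(np.float64)
        post = seq.frames[1].astype(np.float64)
        gt_ax = gts[0].pair_displacement.axial
        bh, bw, margin = 32, 16, 4
        hits = total = 0
        for by in range(0, 128 - bh + 1, bh):
            for bx in range(0, 64 - bw + 1, bw):
                block = pre[by:by + bh, bx:bx + bw]
                best, best_shift = -np.inf, 0
                for dy in range(-margin, margin + 1):
                    y0 = by + dy
                    if y0 < 0 or y0 + bh > 128:
                        continue
                    cand = post[y0:y0 + bh, bx:bx + bw]
                    ncc = np.corrcoef(block.ravel(), cand.ravel())[0, 1]
                    if ncc > best:
                        best, best_shift = ncc, dy
                expected = gt_ax[by:by + bh, bx:bx + bw].mean()
                hits += abs(best_shift - expected) <= 1.0
                total += 1
        assert hits / total >= 0.9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(strain_schedule=(0.04, 0.01)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(strain_schedule=(0.2,)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(inclusions=((0.5, 0.5, -0.1, 0.5),)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(inclusions=((0.5, 0.5, 0.1, 1.5),)).validate()
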