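"""The three-term unsupervised objective and its arithmetic contracts."""

import numpy as np
import pytest

from elastonet.losses import (LossBreakdown, LossWeights, consistency_loss,
                              lncc, similarity_loss, smoothness_loss,
                              total_loss)
from elastonet.transforms import DisplacementField


def brute_force_lncc(a, b, window, epsilon=1e-5):
    """Explicit per-window NCC loop (independent oracle)."""
    h, w = window
    scores = []
    for i in range(a.shape[0] - h + 1):
        for j in range(a.shape[1] - w + 1):
            w1 = a[i:i + h, j:j + w].astype(np.float64)
            w2 = b[i:i + h, j:j + w].astype(np.float64)
            v1 = ((w1 - w1.mean()) ** 2).sum()
            v2 = ((w2 - w2.mean()) ** 2).sum()
            n = h * w
            if v1 < n * epsilon ** 2 or v2 < n * epsilon ** 2:
                continue
            cov = ((w1 - w1.mean()) * (w2 - w2.mean())).sum()
            scores.append(cov / (np.sqrt(v1 * v2) + epsilon))
    return float(np.mean(scores))


class TestLncc:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=(20, 20))
        assert abs(lncc(a, a, (7, 7)) - 1.0) < 1e-4

    def test_anti_correlation_is_minus_one(self, rng):
        a = rng.normal(size=(20, 20))
        assert abs(lncc(a, -a, (7, 7)) + 1.0) < 1e-4

    def test_matches_brute_force_window_loop(self, rng):
        a = rng.integers(0, 10, size=(5, 5)).astype(np.float64)
        b = rng.integers(0, 10, size=(5, 5)).astype(np.float64)
        got = lncc(a, b, (3, 3))
        assert abs(got - brute_force_lncc(a, b, (3, 3))) < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_positive_affine_intensity(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(16, 16))
        b = r.normal(size=(16, 16))
        base = lncc(a, b, (5, 5))
        assert abs(lncc(3.2 * a + 1.7, b, (5, 5)) - base) < 1e-6
        assert abs(lncc(a, 0.4 * b - 2.0, (5, 5)) - base) < 1e-6

    def test_all_windows_invalid_raises(self):
        flat = np.ones((10, 10))
        with pytest.raises(ValueError):
            lncc(flat, flat, (5, 5))

    def test_masked_windows_are_skipped(self, rng):
        a = rng.normal(size=(12, 12))
        b = a.copy()
        b[:, 8:] = rng.normal(size=(12, 4))  # corrupt the right edge
        mask = np.ones((12, 12), bool)
        mask[:, 8:] = False
        assert lncc(a, b, (5, 5), mask=mask) > 0.999


class TestSimilarity:
    def test_identical_pair_zero_displacement(self, rng):
        a = rng.normal(size=(24, 24))
        zero = DisplacementField.zeros((24, 24))
        assert abs(similarity_loss(a, a, zero, LossWeights()) + 1.0) < 1e-4

    def test_exact_compensation_of_integer_shift(self, rng):
        post = rng.normal(size=(32, 32))
        pre = np.roll(post, 4, axis=0)  # pre(y) = post(y - 4)
        d = DisplacementField(np.full((32, 32), -4.0), np.zeros((32, 32)))
        w = LossWeights(lncc_window=(9, 9))
        assert similarity_loss(pre, post, d, w) < -0.999

    def test_independent_speckle_scores_near_zero(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pre = r.normal(size=(32, 32))
            post = r.normal(size=(32, 32))
            zero = DisplacementField.zeros((32, 32))
            vals.append(similarity_loss(pre, post, zero,
                                        LossWeights(lncc_window=(9, 9))))
        assert abs(np.mean(vals)) < 0.1


class TestSmoothness:
    def test_affine_field_is_exactly_zero(self):
        yy, xx = np.meshgrid(np.arange(20.0), np.arange(16.0), indexing="ij")
        u = 1.5 + 0.3 * xx - 0.2 * yy
        d = DisplacementField(u, np.zeros_like(u))
        assert abs(smoothness_loss(d, LossWeights())) < 1e-12

    def test_quadratic_matches_hand_finite_differences(self):
        yy = np.arange(16.0)[:, None] * np.ones((16, 12))
        u = yy ** 2
        d = DisplacementField(u, np.zeros_like(u))
        # |d2y u| = 2 at every interior pixel, the other three terms vanish
        assert abs(smoothness_loss(d, LossWeights()) - 2.0) < 1e-6

    def test_zero_field(self):
        d = DisplacementField.zeros((10, 10))
        assert smoothness_loss(d, LossWeights()) == 0.0

    def test_zero_iff_second_differences_vanish(self, rng):
        u = rng.normal(size=(12, 12))
        d = DisplacementField(u, np.zeros_like(u))
        assert smoothness_loss(d, LossWeights()) > 0


class TestConsistency:
    def test_identical_strains_zero_displacement(self, rng):
        s = rng.normal(size=(24, 24))
        zero = DisplacementField.zeros((24, 24))
        assert abs(consistency_loss(s, s, zero, LossWeights()) + 1.0) < 1e-4

    def test_shifted_copy_with_exact_shift(self, rng):
        curr = rng.normal(size=(32, 32))
        prev = np.roll(curr, 3, axis=0)
        d = DisplacementField(np.full((32, 32), -3.0), np.zeros((32, 32)))
        w = LossWeights(lncc_window=(9, 9))
        assert consistency_loss(prev, curr, d, w) < -0.999

    def test_noise_attenuates_but_correlation_remains(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = r.normal(size=(32, 32))
            curr = base + r.normal(size=(32, 32))
            zero = DisplacementField.zeros((32, 32))
            vals.append(consistency_loss(base, curr, zero,
                                         LossWeights(lncc_window=(9, 9))))
        # equal-power noise: NCC ~ 1/sqrt(2); assert well away from -1
        assert np.mean(vals) > -1 + 0.2
        assert np.mean(vals) < -0.4


class TestTotal:
    def test_weighted_sum_arithmetic(self):
        out = total_loss(-1.0, 0.0, -1.0, LossWeights(alpha=5.0, beta=0.2))
        assert out.total == pytest.approx(-1.2)
        assert isinstance(out, LossBreakdown)

    def test_beta_zero_ignores_consistency(self):
        w = LossWeights(alpha=5.0, beta=0.0)
        assert total_loss(-0.5, 0.1, -0.9, w).total == \
            total_loss(-0.5, 0.1, 123.0, w).total

    def test_missing_previous_strain_with_beta_raises(self):
        with pytest.raises(ValueError):
            total_loss(-1.0, 0.0, None, LossWeights(beta=0.2))

    def test_defaults_are_alpha_five_beta_fifth(self):
        w = LossWeights()
        assert w.alpha == 5.0
        assert w.beta == 0.2

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)
        with pytest.raises(ValueError):
            LossWeights(lncc_window=(4, 5))


def test_direct_descent_on_simulated_pair(clean_sequence):
    """Optimising a free-form displacement by gradient descent with a
    backtracking line search decreases the total loss over the first 50
    steps (sanity of the gradients and of the objective's landscape).

    The descent targets the smooth data term (alpha = 0): the L1 strain
    -gradient penalty is non-smooth at zero curvature, so raw per-pixel
    subgradient steps on it are not descent directions — the networks
    avoid this by construction because their output fields are smooth.
    """
    from elastonet._autodiff import Tensor
    from elastonet.losses import similarity_loss

    seq, _ = clean_sequence
    pre = seq.frames[0].astype(np.float64)
    post = seq.frames[3].astype(np.float64)
    pre = (pre - pre.mean()) / pre.std()
    post = (post - post.mean()) / post.std()
    w = LossWeights(alpha=0.0, beta=0.0, lncc_window=(9, 9))
    # start slightly off the integer grid: bilinear warping is only
    # one-sided differentiable exactly at integer sampling locations
    d = Tensor(np.full((2, 64, 64), 0.25), requires_grad=True)

    def objective(d):
        return similarity_loss(Tensor(pre), Tensor(post), d, w)

    losses = [objective(d).item()]
    step = 0.25
    for _ in range(50):
        d.zero_grad()
        loss = objective(d)
        loss.backward()
        # backtracking line search keeps the descent monotone
        accepted = False
        while step > 1e-8:
            trial = Tensor(d.data - step * d.grad, requires_grad=True)
            new = objective(trial).item()
            if new < losses[-1]:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            losses.append(losses[-1])
            continue
        d = trial
        losses.append(new)
        step *= 1.5
    diffs = np.diff(losses)
    assert losses[-1] < losses[0]
    assert (diffs <= 0).all()
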