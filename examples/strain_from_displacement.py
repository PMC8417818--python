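"""Least-squares strain estimation versus direct differentiation.

Builds a noisy linear axial displacement (2% compression), estimates
strain with the windowed least-squares estimator and with a plain
central difference, and prints the elastographic SNR of both. The
least-squares window averages displacement noise before differencing,
which is why clinical strain pipelines use it.
"""

import numpy as np

from elastonet import gradient_strain, lsq_strain, snre

rng = np.random.default_rng(0)
depth, lines = 400, 32
displacement = -0.02 * np.arange(depth)[:, None] * np.ones((depth, lines))
displacement += rng.normal(0, 0.05, size=displacement.shape)

lsq = lsq_strain(displacement, window_length=43)
grad = gradient_strain(displacement)

print(f"true strain: 0.0200 (2% compression)")
print(f"LSQSE  (window 43): mean {lsq.values.mean():+.4f}  "
      f"SNRe {snre(np.abs(lsq.values)):6.2f}")
print(f"gradient          : mean {grad.values.mean():+.4f}  "
      f"SNRe {snre(np.abs(grad.values)):6.2f}")
print("higher SNRe = cleaner elastogram at the same mean strain")
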