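# elastonet

Unsupervised deep displacement and strain estimation for quasi-static
ultrasound elastography, with an analytic speckle-phantom simulator.

In quasi-static elastography a handheld probe slowly compresses tissue
while radio-frequency (RF) frames are recorded; the axial strain
(depth derivative of the inter-frame displacement) maps relative tissue
stiffness. Because no ground-truth displacement exists for clinical
data, the networks here are trained **without labels** by minimising

```
L_total = L_sim + α·L_reg + β·L_cons,       α = 5, β = 0.2
```

where `L_sim = −LNCC(Pre, Post ∘ T)` is the windowed normalised
cross-correlation between the pre-compression frame and the
displacement-warped post-compression frame, `L_reg` is the L1 norm of
the strain spatial gradient (second derivatives of the axial
displacement), and `L_cons = −LNCC(S_{t−1}, S_t ∘ T)` makes successive
strain images consistent along a temporal sequence. Displacement is
converted to strain with the least-squares strain estimator (LSQSE):
per scan line, the slope of a sliding-window OLS fit of displacement
versus depth, reported positive under compression.

Two architectures are provided:

* **USENet** — a feed-forward encoder–decoder (four down-sampling
  ResNet blocks, bilinear-additive up-sampling with skip connections,
  multi-scale displacement heads; ~0.8 M parameters at the reference
  widths) operating on one frame pair;
* **ReUSENet** — the same encoder with a convolutional-LSTM decoder
  (~1.5 M parameters) whose state threads across the consecutive pairs
  of a frame sequence, integrating evidence along a compression ramp.

Everything — including the reverse-mode differentiation the training
needs — is implemented in NumPy inside the package; see
`docs/methods.md` for the model, the simulator and the numerical
choices.

This package is for researchers in ultrasound image analysis who want a
transparent, dependency-light reference implementation of unsupervised
strain estimation: the full pipeline runs on a laptop CPU with
simulated phantoms, and the same code path accepts real RF sequences
stored in the package's HDF5 layout.

## Worked example

```python
import numpy as np
import elastonet as en
from elastonet.losses import LossWeights
from elastonet.training import TrainConfig, train
from elastonet.evaluation import sequence_scores


def phantom(seed):
    """64x64 speckle phantom, one random stiff inclusion, ten-frame
    compression ramp (0.5% .. 4.5% average strain)."""
    rng = np.random.default_rng(seed)
    inclusion = (float(rng.uniform(0.3, 0.7)), float(rng.uniform(0.3, 0.7)),
                 float(rng.uniform(0.12, 0.2)), float(rng.uniform(0.4, 0.6)))
    return en.PhantomSpec(grid_shape=(64, 64), scatterer_density=1.0,
                          inclusions=(inclusion,), seed=seed)


train_seqs = [en.simulate_sequence(phantom(s))[0] for s in range(4)]
held_out, ground_truth = en.simulate_sequence(phantom(99))

model = en.build_network(en.tiny_config("reusenet"), seed=0)
config = TrainConfig(variant="reusenet", max_epochs=15, seed=0,
                     weights=LossWeights(lncc_window=(9, 9)))
model, history = train(model, train_seqs, config)

fields = model.predict_sequence(held_out.frames.astype(np.float64))
report = sequence_scores(held_out, fields, ground_truth=ground_truth,
                         strain_window=13)
```

This is `examples/train_and_evaluate.py`; after its 15 epochs (a few
minutes on one CPU) it prints:

```
held-out phantom after 15 epochs:
  similarity  0.986   (motion-compensated LNCC; 1 = perfect alignment)
  consistency 0.994   (agreement of successive strain maps)
  SNRe        1.47
  NRMSE       34.4%  (accumulated axial displacement vs ground truth)
```

`similarity` is the motion-compensated LNCC of the held-out frame pairs
(1 = perfect alignment — 0.99 means the predicted warp explains the
speckle motion almost completely); `consistency` is the agreement of
successive strain maps under that motion; `SNRe` is mean/std of the
strain image; `NRMSE` is the error of the accumulated axial
displacement against the simulator's exact ground truth, in percent of
its mean — it keeps improving with more training sequences and epochs
(see `docs/methods.md` for the precision this objective can and cannot
reach at this desk scale). Runnable variants of this workflow, including
the `simulate → train → infer → evaluate` command-line pipeline, are in
`examples/`.

## Command line

```sh
elastonet simulate --spec phantom.yaml --seed 7 --out data.h5
elastonet train    --config train.yaml --data data.h5 \
                   --variant reusenet --seed 0 --out model.npz
elastonet infer    --checkpoint model.npz --data data.h5
elastonet evaluate --data data.h5 --landmarks landmarks.csv \
                   --out report.json
```

Datasets are single HDF5 files (`/sequences/<id>/rf`, optional ground
truth under `gt/`, predictions under `pred/`); landmark files are plain
CSV (`case,pair,frame,axial,lateral`). Every run logs its configuration
and seed.

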