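#!/bin/sh
# The shell workflow: simulate -> train -> infer -> evaluate.
# Produces an HDF5 dataset of two phantoms, trains the small recurrent
# network for a few epochs, writes displacement + strain predictions
# back into the dataset, and prints a JSON metric report.
set -e

cat > /tmp/phantom.yaml <<'YAML'
grid_shape: [64, 64]
scatterer_density: 1.0
inclusions:
  - [0.5, 0.5, 0.2, 0.5]
count: 2
YAML

cat > /tmp/train.yaml <<'YAML'
max_epochs: 10
strain_window: 13
network:
  preset: tiny
loss:
  lncc_window: [9, 9]
YAML

elastonet simulate --spec /tmp/phantom.yaml --seed 7 --out /tmp/demo.h5
elastonet train --config /tmp/train.yaml --data /tmp/demo.h5 \
    --variant reusenet --seed 0 --out /tmp/model.npz --verbose
elastonet infer --checkpoint /tmp/model.npz --data /tmp/demo.h5 \
    --strain-window 13
elastonet evaluate --data /tmp/demo.h5 --out /tmp/report.json
cat /tmp/report.json
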