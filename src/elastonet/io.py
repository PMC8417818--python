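"""Dataset container I/O and B-mode conversion.

One HDF5 file holds any number of RF sequences::

    /sequences/<id>/rf                  (frames, axial, lateral) float32
    /sequences/<id>/gt/pair_displacement   (T-1, 2, H, W)   optional
    /sequences/<id>/gt/ref_displacement    (T-1, 2, H, W)
    /sequences/<id>/gt/cum_displacement    (T-1, 2, H, W)
    /sequences/<id>/gt/strain              (T-1, H, W)
    /sequences/<id>/gt/ref_strain          (T-1, H, W)
    /sequences/<id>/gt/pair_strain         (T-1, H, W)
    /sequences/<id>/pred/displacement      (T-1, 2, H, W)   written by infer
    /sequences/<id>/pred/strain            (T-1, H, W)

Acquisition metadata are attributes on the sequence group; the manifest
(ids, lengths, split labels, provenance) lives in root attributes.
Arrays are stored float32; metric computations accumulate in float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import hilbert

from .containers import DEFAULT_META, RFFrame, RFSequence
from .simulate import GroundTruth
from .strain import StrainField
from .transforms import DisplacementField

__all__ = [
    "DatasetManifest",
    "write_dataset",
    "read_dataset",
    "write_predictions",
    "read_predictions",
    "bmode",
]


class FormatError(RuntimeError):
    """Raised when a dataset file does not match the expected layout."""


@dataclass
class DatasetManifest:
    sequence_ids: list = field(default_factory=list)
    lengths: list = field(default_factory=list)
    splits: dict = field(default_factory=dict)
    provenance: str = ""

    def validate(self):
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("sequence ids must be unique")
        if any(n < 2 for n in self.lengths):
            raise ValueError("sequences must have at least 2 frames")
        return self


def _gt_arrays(truths: list[GroundTruth]):
    return {
        "pair_displacement": np.stack(
            [t.pair_displacement.stack() for t in truths]),
        "ref_displacement": np.stack(
            [t.ref_displacement.stack() for t in truths]),
        "cum_displacement": np.stack(
            [t.displacement.stack() for t in truths]),
        "strain": np.stack([t.strain.values for t in truths]),
        "ref_strain": np.stack([t.ref_strain.values for t in truths]),
        "pair_strain": np.stack([t.pair_strain.values for t in truths]),
        "cumulative_strain": np.array(
            [t.cumulative_strain for t in truths]),
    }


def write_dataset(path, sequences, ground_truth=None,
                  manifest: DatasetManifest | None = None):
    """Write sequences (and optional per-sequence ground truth) to HDF5."""
    sequences = list(sequences)
    if manifest is None:
        manifest = DatasetManifest(
            sequence_ids=[s.seq_id for s in sequences],
            lengths=[len(s) for s in sequences],
            provenance="simulated")
    manifest.validate()
    with h5py.File(path, "w") as fh:
        root = fh.create_group("sequences")
        for i, seq in enumerate(sequences):
            grp = root.create_group(manifest.sequence_ids[i])
            grp.create_dataset("rf", data=seq.frames.astype(np.float32))
            grp.create_dataset("timestamps", data=seq.timestamps)
            for key, value in seq.meta.items():
                grp.attrs[key] = value
            if ground_truth is not None and ground_truth[i] is not None:
                gt_grp = grp.create_group("gt")
                for key, arr in _gt_arrays(ground_truth[i]).items():
                    gt_grp.create_dataset(key, data=arr.astype(np.float32))
        fh.attrs["manifest"] = json.dumps({
            "sequence_ids": manifest.sequence_ids,
            "lengths": manifest.lengths,
            "splits": manifest.splits,
            "provenance": manifest.provenance})


def _read_gt(grp) -> list[GroundTruth]:
    need = ["pair_displacement", "ref_displacement", "cum_displacement",
            "strain", "ref_strain", "pair_strain"]
    for key in need:
        if key not in grp:
            raise FormatError(f"missing ground-truth dataset {grp.name}/{key}")
    n = grp["strain"].shape[0]
    cum = grp["cumulative_strain"][...] if "cumulative_strain" in grp \
        else np.zeros(n)
    out = []
    for t in range(n):
        out.append(GroundTruth(
            displacement=DisplacementField.from_stack(
                grp["cum_displacement"][t].astype(np.float64)),
            strain=StrainField(grp["strain"][t], 0),
            ref_displacement=DisplacementField.from_stack(
                grp["ref_displacement"][t].astype(np.float64)),
            ref_strain=StrainField(grp["ref_strain"][t], 0),
            pair_displacement=DisplacementField.from_stack(
                grp["pair_displacement"][t].astype(np.float64)),
            pair_strain=StrainField(grp["pair_strain"][t], 0),
            cumulative_strain=float(cum[t])))
    return out


def read_dataset(path):
    """Read ``(sequences, ground_truth, manifest)`` from an HDF5 dataset.

    ``ground_truth[i]`` is ``None`` for sequences stored without labels.
    """
    sequences, truths = [], []
    with h5py.File(path, "r") as fh:
        if "sequences" not in fh:
            raise FormatError("missing /sequences group")
        raw = json.loads(fh.attrs.get("manifest", "{}"))
        manifest = DatasetManifest(
            sequence_ids=raw.get("sequence_ids",
                                 sorted(fh["sequences"].keys())),
            lengths=raw.get("lengths", []),
            splits=raw.get("splits", {}),
            provenance=raw.get("provenance", ""))
        for seq_id in manifest.sequence_ids:
            if seq_id not in fh["sequences"]:
                raise FormatError(f"missing group /sequences/{seq_id}")
            grp = fh["sequences"][seq_id]
            if "rf" not in grp:
                raise FormatError(f"missing dataset /sequences/{seq_id}/rf")
            rf = grp["rf"][...]
            if rf.ndim != 3:
                raise FormatError(
                    f"/sequences/{seq_id}/rf must be 3D, got {rf.shape}")
            meta = {k: grp.attrs[k] for k in DEFAULT_META if k in grp.attrs}
            seq = RFSequence(rf, meta={**DEFAULT_META, **meta},
                             timestamps=grp["timestamps"][...]
                             if "timestamps" in grp else None,
                             seq_id=seq_id)
            sequences.append(seq)
            truths.append(_read_gt(grp["gt"]) if "gt" in grp else None)
        if not manifest.lengths:
            manifest.lengths = [len(s) for s in sequences]
    return sequences, truths, manifest.validate()


def write_predictions(path, seq_id: str, displacements, strains):
    """Store per-pair displacement and strain estimates next to a sequence.

    Never touches the source ``rf`` data; re-running inference replaces
    only the ``pred`` group.
    """
    disp = np.stack([d.stack() for d in displacements]).astype(np.float32)
    strn = np.stack([s.values for s in strains]).astype(np.float32)
    with h5py.File(path, "r+") as fh:
        grp = fh["sequences"][seq_id]
        if "pred" in grp:
            del grp["pred"]
        pred = grp.create_group("pred")
        pred.create_dataset("displacement", data=disp)
        pred.create_dataset("strain", data=strn)
        pred.attrs["strain_window"] = strains[0].window_length


def read_predictions(path, seq_id: str):
    with h5py.File(path, "r") as fh:
        grp = fh["sequences"][seq_id]
        if "pred" not in grp:
            raise FormatError(f"no predictions stored for {seq_id}")
        disp = grp["pred"]["displacement"][...].astype(np.float64)
        strn = grp["pred"]["strain"][...].astype(np.float64)
        window = int(grp["pred"].attrs.get("strain_window", 0))
    fields = [DisplacementField.from_stack(d) for d in disp]
    strains = [StrainField(s, window) for s in strn]
    return fields, strains


def import_mat_sequence(path, rf_key: str | None = None,
                        seq_id: str | None = None) -> RFSequence:
    """Best-effort import of a MATLAB file holding an RF frame stack.

    Looks for a 3D array (frames x axial x lateral, or axial x lateral
    x frames with the frame axis last, which is transposed) under
    ``rf_key`` or, failing that, the first 3D numeric variable. This is
    a convenience shim for public RF databases distributed as .mat
    files; the exact variable layout of any given release should be
    checked against its documentation.
    """
    from scipy.io import loadmat

    data = loadmat(path)
    candidates = {k: v for k, v in data.items()
                  if not k.startswith("__") and isinstance(v, np.ndarray)}
    if rf_key is not None:
        if rf_key not in candidates:
            raise FormatError(f"no variable {rf_key!r} in {path}")
        arr = candidates[rf_key]
    else:
        arrs = [v for v in candidates.values()
                if v.ndim == 3 and np.issubdtype(v.dtype, np.number)]
        if not arrs:
            raise FormatError(f"no 3D numeric variable found in {path}")
        arr = arrs[0]
    if arr.ndim != 3:
        raise FormatError("expected a 3D RF stack")
    if arr.shape[0] > arr.shape[2]:
        # axial x lateral x frames layout: move the frame axis first
        arr = np.moveaxis(arr, 2, 0)
    return RFSequence(np.ascontiguousarray(arr, dtype=np.float32),
                      seq_id=seq_id or "imported")


def bmode(rf, dynamic_range_db: float = 50.0) -> np.ndarray:
    """Envelope-detected, log-compressed image in [0, 1].

    Per scan line: magnitude of the analytic signal (Hilbert transform
    along depth), then ``20*log10(env/max)`` clipped to
    ``[-dynamic_range_db, 0]`` and rescaled to [0, 1].
    """
    samples = rf.samples if isinstance(rf, RFFrame) else np.asarray(rf)
    samples = samples.astype(np.float64)
    if samples.ndim != 2 or samples.shape[0] < 8:
        raise ValueError("need a 2D RF frame with >= 8 axial samples")
    env = np.abs(hilbert(samples, axis=0))
    peak = env.max()
    if peak == 0:
        return np.zeros_like(env)
    db = 20.0 * np.log10(np.maximum(env / peak, 1e-30))
    db = np.clip(db, -dynamic_range_db, 0.0)
    return db / dynamic_range_db + 1.0
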