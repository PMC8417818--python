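"""Quantitative evaluation of displacement and strain estimates.

Metrics:

* **NRMSE** — root-mean-square displacement error normalised by the mean
  ground-truth displacement, in percent:
  ``sqrt(sum((pred-label)^2)/N) * 100*N / sum(label)``.
* **SNRe** — elastographic signal-to-noise ratio, mean/std of a strain
  image (population standard deviation; whole image unless a region of
  interest is given).
* **similarity / consistency** — the positive LNCC scores between the
  pre frame and the motion-compensated post frame, and between
  successive motion-compensated strain fields.
* **TRE** — target registration error: residual distance (pixels)
  between manually paired landmarks in the first and last frame of a
  sequence after mapping through the estimated displacement field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .losses import LossWeights, lncc
from .strain import StrainField, lsq_strain
from .transforms import DisplacementField, compose_displacements, warp

__all__ = [
    "LandmarkSet",
    "MetricReport",
    "nrmse",
    "snre",
    "sequence_scores",
    "tre",
    "read_landmarks",
    "write_landmarks",
]


def nrmse(predicted: np.ndarray, label: np.ndarray) -> float:
    """Normalised RMSE in percent of the mean label value."""
    p = np.asarray(predicted, dtype=np.float64)
    l = np.asarray(label, dtype=np.float64)
    if p.shape != l.shape:
        raise ValueError("shapes differ")
    mean_label = l.mean()
    if mean_label == 0:
        raise ValueError("zero-mean label: NRMSE normalisation undefined")
    rmse = np.sqrt(((p - l) ** 2).mean())
    return float(100.0 * rmse / mean_label)


def snre(strain, roi=None) -> float:
    """Elastographic SNR: mean over (population) std of the strain image."""
    values = strain.values if isinstance(strain, StrainField) \
        else np.asarray(strain, dtype=np.float64)
    if roi is not None:
        values = values[roi]
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 pixels")
    sd = values.std()
    if sd == 0:
        raise ValueError("degenerate (constant) strain image")
    return float(values.mean() / sd)


@dataclass
class LandmarkSet:
    """Corresponding points in the first and last frame of a sequence."""

    first: np.ndarray  # (k, 2) = (axial, lateral), sample units
    last: np.ndarray   # (k, 2)

    def __post_init__(self):
        self.first = np.atleast_2d(np.asarray(self.first, dtype=np.float64))
        self.last = np.atleast_2d(np.asarray(self.last, dtype=np.float64))
        if self.first.shape != self.last.shape or self.first.shape[1] != 2:
            raise ValueError("landmark arrays must be matching (k, 2)")


@dataclass
class MetricReport:
    similarity: float = np.nan
    consistency: float = np.nan
    snre: float = np.nan
    nrmse: float = np.nan
    tre_mean: float = np.nan
    per_step: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"similarity": self.similarity,
                "consistency": self.consistency,
                "snre": self.snre, "nrmse": self.nrmse,
                "tre_mean": self.tre_mean, "per_step": self.per_step}


def _bilinear_at(grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
    h, w = grid.shape
    y = np.clip(pts[:, 0], 0, h - 1)
    x = np.clip(pts[:, 1], 0, w - 1)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
    ty, tx = y - y0, x - x0
    return (grid[y0, x0] * (1 - ty) * (1 - tx)
            + grid[y0, x0 + 1] * (1 - ty) * tx
            + grid[y0 + 1, x0] * ty * (1 - tx)
            + grid[y0 + 1, x0 + 1] * ty * tx)


def tre(landmarks: LandmarkSet,
        displacement_first_to_last: DisplacementField) -> float:
    """Mean Euclidean residual after mapping first-frame landmarks through
    the field (bilinear sampling of the field at each landmark)."""
    d = displacement_first_to_last
    h, w = d.shape
    pts = landmarks.first
    if (pts < -0.5).any() or (pts[:, 0] > h - 0.5).any() \
            or (pts[:, 1] > w - 0.5).any():
        raise ValueError("landmark outside the image grid")
    mapped = pts + np.stack([_bilinear_at(d.axial, pts),
                             _bilinear_at(d.lateral, pts)], axis=1)
    residual = mapped - landmarks.last
    return float(np.sqrt((residual ** 2).sum(axis=1)).mean())


def sequence_scores(sequence, displacements, strains=None,
                    ground_truth=None, weights: LossWeights | None = None,
                    strain_window: int = 43) -> MetricReport:
    """Per-step and averaged metrics for one evaluated sequence.

    ``displacements`` holds one consecutive-pair field per interframe
    step (network convention: field on the earlier frame's grid mapping
    into the later frame). Strains default to the LSQSE of each field's
    axial channel. When ground truth is available the NRMSE of the
    accumulated (first-to-current) axial displacement is reported per
    step, mirroring the increasing-compression evaluation protocol.
    """
    weights = weights or LossWeights()
    frames = sequence.frames if hasattr(sequence, "frames") \
        else np.asarray(sequence)
    if len(displacements) != len(frames) - 1:
        raise ValueError("need one displacement per consecutive pair")
    if strains is None:
        strains = [lsq_strain(d.axial, strain_window) for d in displacements]
    per_step = []
    cumulative = None
    for t, d in enumerate(displacements, start=1):
        pre = np.asarray(frames[t - 1], dtype=np.float64)
        post = np.asarray(frames[t], dtype=np.float64)
        warped, valid = warp(post, d)
        sim = lncc(pre, warped, weights.lncc_window, valid, weights.epsilon)
        entry = {"step": t, "similarity": float(sim)}
        if t > 1:
            prev = strains[t - 2].values
            curr_w, valid_s = warp(strains[t - 1].values, d)
            entry["consistency"] = float(lncc(prev, curr_w,
                                              weights.lncc_window, valid_s,
                                              weights.epsilon))
        entry["snre"] = snre(np.abs(strains[t - 1].values) + 1e-12) \
            if strains[t - 1].values.std() > 0 else np.nan
        cumulative = d if cumulative is None \
            else compose_displacements(d, cumulative)
        if ground_truth is not None:
            label = ground_truth[t - 1].ref_displacement.axial
            entry["nrmse"] = nrmse(-cumulative.axial, -label)
        per_step.append(entry)
    report = MetricReport(per_step=per_step)
    report.similarity = float(np.mean([e["similarity"] for e in per_step]))
    cons = [e["consistency"] for e in per_step if "consistency" in e]
    report.consistency = float(np.mean(cons)) if cons else np.nan
    snres = [e["snre"] for e in per_step if np.isfinite(e["snre"])]
    report.snre = float(np.mean(snres)) if snres else np.nan
    if ground_truth is not None:
        report.nrmse = float(np.mean([e["nrmse"] for e in per_step]))
    return report


# ------------------------------------------------------------ landmark files
def write_landmarks(path, cases: dict[str, LandmarkSet]):
    """CSV layout: case,pair,frame,axial,lateral (frame in {first,last})."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case", "pair", "frame", "axial", "lateral"])
        for case, lm in cases.items():
            for i, (a, b) in enumerate(zip(lm.first, lm.last)):
                writer.writerow([case, i, "first", a[0], a[1]])
                writer.writerow([case, i, "last", b[0], b[1]])


def read_landmarks(path) -> dict[str, LandmarkSet]:
    first: dict[str, dict[int, tuple]] = {}
    last: dict[str, dict[int, tuple]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            store = first if row["frame"] == "first" else last
            store.setdefault(row["case"], {})[int(row["pair"])] = (
                float(row["axial"]), float(row["lateral"]))
    out = {}
    for case in first:
        pairs = sorted(first[case])
        out[case] = LandmarkSet(
            np.array([first[case][i] for i in pairs]),
            np.array([last[case][i] for i in pairs]))
    return out
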