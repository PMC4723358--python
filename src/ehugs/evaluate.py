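"""Dice-ratio evaluation and atlas construction.

Because groupwise registration has no explicit template, the common-space
ground truth is the per-voxel majority vote of all aligned label maps;
each image's warped tissue mask is then scored against it with the Dice
overlap 2|A n B| / (|A| + |B|).  The atlas is the voxelwise mean of the
aligned intensities plus per-tissue frequency (probability) maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GridMismatchError, ImageVolume, LabelVolume

logger = logging.getLogger("ehugs")

DEFAULT_TISSUE_NAMES = {1: "WM", 2: "GM", 3: "CSF"}


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks.

    Returns 0 (logged) when both masks are empty.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise GridMismatchError("dice requires masks on a common grid")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        logger.debug("dice of two empty masks: returning 0 by convention")
        return 0.0
    return 2.0 * int(np.logical_and(A, B).sum()) / (na + nb)


def majority_vote_labels(aligned_labels: list[LabelVolume]) -> LabelVolume:
    """Per-voxel most frequent label across aligned label maps.

    Background (0) participates in the vote; ties break toward the lowest
    label code (labels are scanned in ascending order and argmax keeps
    the first maximum).
    """
    if not aligned_labels:
        raise ValueError("majority vote needs at least one label volume")
    shape = aligned_labels[0].data.shape
    codes = sorted({0} | {int(c) for lv in aligned_labels for c in lv.label_set})
    counts = np.zeros((len(codes), *shape), dtype=np.int32)
    for lv in aligned_labels:
        if lv.data.shape != shape:
            raise GridMismatchError("label volumes must share a grid")
        for ci, c in enumerate(codes):
            counts[ci] += lv.data == c
    winner = np.asarray(codes, dtype=np.int32)[counts.argmax(axis=0)]
    return LabelVolume(winner, aligned_labels[0].spacing, "majority_vote",
                       frozenset(c for c in codes if c != 0))


@dataclass
class DiceReport:
    """Per-image per-tissue Dice table plus mean/sd summary."""

    per_image: pd.DataFrame  # rows: image ids; columns: tissue names + "overall"
    summary: pd.DataFrame  # rows: mean, sd; columns as above

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index_label="image_id")


def dice_report(
    aligned_labels: list[LabelVolume],
    tissues: dict[int, str] | list[int] | None = None,
    reference: LabelVolume | None = None,
) -> DiceReport:
    """Dice of every image's tissue masks against the majority-vote truth.

    ``tissues`` maps label codes to column names (default 1/2/3 ->
    WM/GM/CSF restricted to codes actually present).  A tissue absent
    from both the image and the reference is reported as missing (NaN),
    not 0.  The "overall" column is the unweighted mean across tissues.
    """
    if not aligned_labels:
        raise ValueError("dice_report needs at least one label volume")
    if tissues is None:
        present = sorted({int(c) for lv in aligned_labels for c in lv.label_set})
        tissues = {c: DEFAULT_TISSUE_NAMES.get(c, f"label{c}") for c in present}
    elif not isinstance(tissues, dict):
        tissues = {int(c): DEFAULT_TISSUE_NAMES.get(int(c), f"label{c}") for c in tissues}
    gt = reference if reference is not None else majority_vote_labels(aligned_labels)
    rows = {}
    for lv in aligned_labels:
        vals = {}
        for code, name in tissues.items():
            a = lv.data == code
            b = gt.data == code
            vals[name] = np.nan if (not a.any() and not b.any()) else dice(a, b)
        vals["overall"] = float(np.nanmean(list(vals.values()))) if vals else np.nan
        rows[lv.id] = vals
    per_image = pd.DataFrame.from_dict(rows, orient="index")
    summary = pd.DataFrame({"mean": per_image.mean(), "sd": per_image.std()}).T
    return DiceReport(per_image, summary)


@dataclass
class Atlas:
    """Mean intensity image plus per-label probability maps (incl. background)."""

    mean_image: ImageVolume
    tissue_probability: dict  # label code -> probability array in [0, 1]

    def __post_init__(self):
        total = sum(self.tissue_probability.values())
        if not np.allclose(total, 1.0):
            raise ValueError("per-voxel tissue probabilities must sum to 1")


def build_atlas(
    aligned_images: list[ImageVolume],
    aligned_labels: list[LabelVolume] | None = None,
) -> Atlas:
    """Simple-averaging atlas: mean image and label frequency maps."""
    if not aligned_images:
        raise ValueError("build_atlas needs at least one image")
    mean = np.mean([img.data for img in aligned_images], axis=0)
    mean_img = ImageVolume(mean, aligned_images[0].spacing, "atlas_mean")
    probs: dict[int, np.ndarray] = {}
    if aligned_labels:
        codes = sorted({0} | {int(c) for lv in aligned_labels for c in lv.label_set})
        n = len(aligned_labels)
        for c in codes:
            probs[c] = np.sum([lv.data == c for lv in aligned_labels], axis=0) / n
    else:
        probs[0] = np.ones_like(mean)
    return Atlas(mean_img, probs)


def atlas_sharpness(atlas_mean: ImageVolume) -> float:
    """Root-mean-square gradient magnitude of the mean image.

    A relative score for comparing runs: blurring spreads a fixed amount
    of intensity change over more voxels, which lowers the RMS gradient
    (unlike the plain mean |gradient|, which is invariant for monotone
    edges).  Higher = sharper.
    """
    grads = np.gradient(atlas_mean.data)
    if atlas_mean.data.ndim == 1:
        grads = [grads]
    mag2 = np.sum([g * g for g in grads], axis=0)
    return float(np.sqrt(mag2.mean()))


def paired_improvement(before: pd.Series, after: pd.Series) -> dict:
    """Plain paired comparison of two Dice columns (mean difference, Wilcoxon-free).

    Returns the mean paired difference and the fraction of images that
    improved; a lightweight check for fixture-level experiments.
    """
    diff = (after - before).dropna()
    return {
        "mean_difference": float(diff.mean()),
        "fraction_improved": float((diff > 0).mean()) if len(diff) else np.nan,
        "n": int(len(diff)),
    }
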