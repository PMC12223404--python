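"""Septal-reference enhancement thresholding.

Shared by the LGE area-at-risk measurement and the threshold-based MEMRI
deficit: the threshold is the mean + k·SD (default k = 2) of a remote
septal myocardial ROI.  LGE counts voxels strictly above mean + k·SD
(hyper-enhancement); the MEMRI variant counts voxels strictly below
mean − k·SD, because at the end of occlusion the ischemic territory is
hypo-intense relative to the manganese-enhanced remote wall.  Fractions are
percentages of LV myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, LabelMap, SECTOR_SEPTAL


@dataclass
class ReferenceStats:
    """Remote-ROI intensity statistics (sample mean and SD, n−1 denominator)."""

    mean: float
    sd: float
    n: int
    roi_code: int = SECTOR_SEPTAL


@dataclass
class EnhancementResult:
    fraction_pct_lv: float
    threshold_value: float
    polarity: str
    modality: str
    n_voxels: int = 0
    n_lv_voxels: int = 0


def septal_reference(volume: ImageVolume, labels: LabelMap) -> ReferenceStats:
    """Mean and sample SD over the septal myocardial reference ROI."""
    mask = labels.sector_mask(SECTOR_SEPTAL)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"septal reference ROI has {n} voxels; need >= 2 for an SD")
    vals = volume.data[mask]
    return ReferenceStats(float(vals.mean()), float(vals.std(ddof=1)), n)


def threshold_fraction(
    volume: ImageVolume,
    labels: LabelMap,
    ref: ReferenceStats,
    k: float = 2.0,
    polarity: str = "above",
    modality: str = "LGE",
) -> EnhancementResult:
    """Fraction of LV myocardium beyond the reference-derived threshold.

    ``above``: strictly greater than mean + k·sd (ties excluded);
    ``below``: strictly less than mean − k·sd.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if polarity not in ("above", "below"):
        raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")
    myo = labels.myocardium_mask()
    n_lv = int(myo.sum())
    if n_lv == 0:
        raise ValueError("label map contains no myocardium")
    vals = volume.data[myo]
    if polarity == "above":
        thr = ref.mean + k * ref.sd
        n = int((vals > thr).sum())
    else:
        thr = ref.mean - k * ref.sd
        n = int((vals < thr).sum())
    return EnhancementResult(100.0 * n / n_lv, float(thr), polarity, modality, n, n_lv)
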