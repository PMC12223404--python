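"""Left-ventricular volumetrics and segmental wall mechanics from label maps.

Cavity volumes use slice summation (Simpson's rule on masks): voxel count ×
voxel volume, in µL.  EF = 100·(EDV − ESV)/EDV with ED/ES taken as the
frames of maximal/minimal cavity volume.  Wall thickness is measured on one
short-axis slice by casting radial rays from the cavity centroid and taking
the epicardial-minus-endocardial boundary radius per ray, averaged within
angular segments; fractional wall thickening per segment is
fWT = 100·(WT_ES − WT_ED)/WT_ED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CAVITY, MYOCARDIUM, LabelMap

# Segment 1 starts at the anterior-septal junction (135°) and numbering runs
# counterclockwise, so with 4 segments: 1=septal, 2=inferior, 3=lateral,
# 4=anterior — consistent with the phantom's sector convention.
SEGMENT_START_DEG = 135.0
SEGMENT_NAMES_4 = {1: "septal", 2: "inferior", 3: "lateral", 4: "anterior"}


@dataclass
class VolumetricsResult:
    edv_ul: float
    esv_ul: float
    ef_pct: float | None
    frame_ed: int
    frame_es: int
    ef_defined: bool = True


@dataclass
class WallThicknessProfile:
    segment_id: int
    wt_mm: float
    n_rays: int


@dataclass
class SegmentFWT:
    segment_id: int
    wt_ed_mm: float
    wt_es_mm: float
    fwt_pct: float | None


def cavity_volume(labels: LabelMap) -> float:
    """LV cavity volume in µL by slice summation over the cavity mask."""
    n = int(labels.cavity_mask().sum())
    return n * labels.voxel_volume_ul


def ejection_fraction(volumes_per_frame) -> VolumetricsResult:
    """EDV/ESV/EF from per-frame cavity volumes; ties go to the earliest frame."""
    vols = np.asarray(volumes_per_frame, dtype=np.float64)
    if vols.size < 2:
        raise ValueError("need volumes for at least two frames")
    frame_ed = int(np.argmax(vols))
    frame_es = int(np.argmin(vols))
    edv, esv = float(vols[frame_ed]), float(vols[frame_es])
    if edv <= 0:
        return VolumetricsResult(edv, esv, None, frame_ed, frame_es, ef_defined=False)
    return VolumetricsResult(edv, esv, 100.0 * (edv - esv) / edv, frame_ed, frame_es)


def wall_thickness(
    labels: LabelMap,
    slice_index: int,
    n_segments: int = 4,
    rays_per_segment: int = 16,
) -> list[WallThicknessProfile]:
    """Segmental wall thickness on one slice by radial ray casting.

    Rays start at the cavity centroid; per ray the endocardial and epicardial
    boundaries are the midpoints of the last-inside/first-outside sample
    pairs (half-voxel accuracy at the 0.25-voxel sampling step used).  Rays
    that never cross myocardium are excluded; more than 25% exclusions is an
    error, as is a slice without a cavity.
    """
    if not (0 <= slice_index < labels.shape[2]):
        raise ValueError(f"slice_index {slice_index} out of range")
    tissue = labels.tissue[:, :, slice_index]
    dx, dy = labels.voxel_size[0], labels.voxel_size[1]
    cav = tissue == CAVITY
    if not cav.any():
        raise ValueError("slice has no cavity: endocardial boundary undefined")
    ii, jj = np.nonzero(cav)
    cx = (ii.mean() + 0.5) * dx
    cy = (jj.mean() + 0.5) * dy
    nx, ny = tissue.shape
    r_max = float(np.hypot(nx * dx, ny * dy))
    step = 0.25 * min(dx, dy)
    radii = np.arange(step, r_max, step)

    n_rays = n_segments * rays_per_segment
    seg_width = 360.0 / n_segments
    angles = SEGMENT_START_DEG + (np.arange(n_rays) + 0.5) * (360.0 / n_rays)
    seg_of_ray = np.arange(n_rays) // rays_per_segment + 1

    thickness = np.full(n_rays, np.nan)
    for r_idx, theta in enumerate(angles):
        a = np.deg2rad(theta)
        xs = cx + radii * np.cos(a)
        ys = cy + radii * np.sin(a)
        i = np.floor(xs / dx).astype(int)
        j = np.floor(ys / dy).astype(int)
        inside = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
        lab = np.where(inside, tissue[np.clip(i, 0, nx - 1), np.clip(j, 0, ny - 1)], -1)
        in_myo = lab == MYOCARDIUM
        if not in_myo.any():
            continue
        first = int(np.argmax(in_myo))
        after = np.nonzero(~in_myo[first:])[0]
        last = first + (int(after[0]) - 1) if after.size else len(radii) - 1
        r_endo = radii[first] - step / 2.0
        r_epi = radii[last] + step / 2.0
        thickness[r_idx] = r_epi - r_endo

    excluded = int(np.isnan(thickness).sum())
    if excluded > 0.25 * n_rays:
        raise ValueError(f"open annulus: {excluded}/{n_rays} rays found no myocardium")

    out = []
    for s in range(1, n_segments + 1):
        vals = thickness[seg_of_ray == s]
        vals = vals[~np.isnan(vals)]
        out.append(WallThicknessProfile(s, float(vals.mean()), int(vals.size)))
    return out


def fractional_wall_thickening(
    wt_ed: list[WallThicknessProfile], wt_es: list[WallThicknessProfile]
) -> list[SegmentFWT]:
    """Per-segment fWT = 100·(WT_ES − WT_ED)/WT_ED; zero ED thickness flagged."""
    if len(wt_ed) != len(wt_es):
        raise ValueError("segment counts differ between phases")
    out = []
    for ed, es in zip(wt_ed, wt_es):
        if ed.segment_id != es.segment_id:
            raise ValueError("segment ids do not match between phases")
        fwt = 100.0 * (es.wt_mm - ed.wt_mm) / ed.wt_mm if ed.wt_mm > 0 else None
        out.append(SegmentFWT(ed.segment_id, ed.wt_mm, es.wt_mm, fwt))
    return out
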