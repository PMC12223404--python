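"""Dynamic manganese-uptake quantification.

The perfusion-deficit metric follows the slope criterion: per myocardial
pixel, the signal-intensity slope over the occlusion window, by default the
two-point form ΔSI/Δt = (SI at end of ischemia − SI at start) / interval;
pixels with a nonpositive slope (slope ≤ 0, zero included) count as deficit,
expressed as a percentage of LV myocardium (%LV).  A per-voxel OLS slope
over all occlusion frames is available as a robustness alternative, and ROI
time-courses are analyzed with windowed linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DynamicSeries, LabelMap, SECTOR_CODES, SECTOR_NAMES


@dataclass
class TimeCourse:
    """Mean ROI signal intensity over time for one sector and window set."""

    t: np.ndarray
    si: np.ndarray
    roi_code: int
    windows: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.si = np.asarray(self.si, dtype=np.float64)
        if self.t.size != self.si.size or self.t.size < 2:
            raise ValueError("need matching t/si with at least two points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def roi_name(self) -> str:
        return SECTOR_NAMES.get(self.roi_code, str(self.roi_code))


@dataclass
class SlopeMap:
    """Per-voxel SI slope (a.u./min) over an analysis window.

    ``slope`` is NaN outside the myocardium; ``mode`` records whether the
    two-point endpoint formula or per-voxel OLS produced it.
    """

    slope: np.ndarray
    window: tuple[float, float]
    n_frames_used: int
    mode: str


@dataclass
class DeficitResult:
    """Perfusion-deficit extent as % of LV myocardium."""

    deficit_pct_lv: float
    method: str
    n_deficit_voxels: int
    n_lv_voxels: int


def split_windows(
    series: DynamicSeries, t_occlusion: float = 30.0
) -> tuple[DynamicSeries, DynamicSeries]:
    """Partition frames at the occlusion-release time.

    Frames with t ≤ t_occlusion are tagged ischemia, later frames
    reperfusion; both windows must be non-empty.
    """
    isch = series.times_min <= t_occlusion
    if not isch.any() or isch.all():
        raise ValueError(
            f"t_occlusion={t_occlusion} min leaves an empty window "
            f"(acquisition spans {series.times_min[0]}–{series.times_min[-1]} min)"
        )
    def subset(sel: np.ndarray, tag: str) -> DynamicSeries:
        frames = [f for f, s in zip(series.frames, sel) if s]
        return DynamicSeries(frames, series.times_min[sel], [tag] * int(sel.sum()))

    return subset(isch, "ischemia"), subset(~isch, "reperfusion")


def extract_roi_timecourse(
    series: DynamicSeries, labels: LabelMap, roi_code: int | str
) -> TimeCourse:
    """Per-frame mean intensity over one myocardial sector."""
    code = SECTOR_CODES[roi_code] if isinstance(roi_code, str) else int(roi_code)
    mask = labels.sector_mask(code)
    if not mask.any():
        name = SECTOR_NAMES.get(code, str(code))
        raise ValueError(f"ROI {name!r} is empty on this label map")
    si = np.array([f.data[mask].mean() for f in series.frames])
    return TimeCourse(series.times_min.copy(), si, code, list(series.windows))


def fit_window_slope(
    tc: TimeCourse, window: str | None = None
) -> tuple[float, float, float]:
    """OLS line of SI on t within one window; returns (slope, intercept, p).

    p is the two-sided test of zero slope from the t-statistic on the OLS
    slope.  The exactly-constant degenerate case (zero slope, zero residual)
    is reported as non-significant (p = 1); an exact nonzero trend has p = 0.
    """
    if window is None:
        sel = np.ones(tc.t.size, dtype=bool)
    else:
        sel = np.array([w == window for w in tc.windows])
    t, si = tc.t[sel], tc.si[sel]
    if t.size < 3:
        raise ValueError(f"need >= 3 frames in window {window!r}, got {t.size}")
    dt = t - t.mean()
    slope = float(dt @ (si - si.mean()) / (dt @ dt))
    intercept = float(si.mean() - slope * t.mean())
    resid = si - (intercept + slope * t)
    ss_res = float(resid @ resid)
    if np.isclose(ss_res, 0.0, atol=1e-24 * max(1.0, float(si @ si))):
        p = 1.0 if np.isclose(slope, 0.0) else 0.0
        return slope, intercept, p
    se = np.sqrt(ss_res / (t.size - 2) / (dt @ dt))
    tstat = slope / se
    p = float(2.0 * stats.t.sf(abs(tstat), df=t.size - 2))
    return slope, intercept, p


def pixel_slope_map(
    series: DynamicSeries,
    labels: LabelMap,
    window: str = "ischemia",
    mode: str = "endpoint",
) -> SlopeMap:
    """Per-voxel SI slope over one window.

    ``endpoint`` (default): (last − first frame) / elapsed time — the
    two-point ΔSI/Δt definition.  ``ols``: least-squares slope over every
    frame in the window.  Both agree exactly on linear trajectories.
    """
    if mode not in ("endpoint", "ols"):
        raise ValueError(f"unknown slope mode {mode!r}")
    sel = np.array([w == window for w in series.windows])
    if sel.sum() < 2:
        raise ValueError(f"window {window!r} holds {int(sel.sum())} frames; need >= 2")
    t = series.times_min[sel]
    if t[-1] == t[0]:
        raise ValueError("window start and end times coincide")
    data = np.stack([f.data for f, s in zip(series.frames, sel) if s], axis=0)
    myo = labels.myocardium_mask()
    if mode == "endpoint":
        slope = (data[-1] - data[0]) / (t[-1] - t[0])
    else:
        dt = (t - t.mean()).reshape(-1, 1, 1, 1)
        slope = (dt * (data - data.mean(axis=0))).sum(axis=0) / (dt**2).sum()
    slope = np.where(myo, slope, np.nan)
    return SlopeMap(slope, (float(t[0]), float(t[-1])), int(sel.sum()), mode)


def deficit_from_slopes(smap: SlopeMap, labels: LabelMap) -> DeficitResult:
    """Nonpositive-slope deficit extent as % of LV myocardium."""
    myo = labels.myocardium_mask()
    n_lv = int(myo.sum())
    if n_lv == 0:
        raise ValueError("label map contains no myocardium")
    slopes = smap.slope[myo]
    if np.isnan(slopes).any():
        raise ValueError("slope map undefined on part of the myocardium")
    n_def = int((slopes <= 0).sum())
    return DeficitResult(100.0 * n_def / n_lv, "slope", n_def, n_lv)
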