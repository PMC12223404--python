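"""Variable-flip-angle T1 estimation for spoiled gradient-echo acquisitions.

The steady-state SPGR (FLASH) signal is

    S(α) = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR / T1).

The linear fit uses the standard linearization y = S/sin α against
x = S/tan α, whose slope is E1 and intercept M0·(1 − E1).  A vectorized
damped Gauss–Newton refinement minimizing Σ_α (S_obs − S(α))² per voxel is
available on top of the linear estimate.  Multiplicative shading is handled
by a log-domain polynomial-surface bias estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, LabelMap

T1_MIN_MS = 100.0
T1_MAX_MS = 10000.0


def spgr_signal(alpha_deg, m0, t1_ms, tr_ms):
    """Closed-form SPGR steady-state signal; broadcasts over array inputs."""
    alpha_deg = np.asarray(alpha_deg, dtype=np.float64)
    t1_ms = np.asarray(t1_ms, dtype=np.float64)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if np.any(alpha_deg < 0) or np.any(alpha_deg > 90):
        raise ValueError("alpha_deg must lie in [0, 90]")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    out = m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return out if out.ndim else float(out)


@dataclass
class VFAStack:
    """Multi-flip-angle SPGR volumes sharing one grid.

    ``mask`` restricts the fit (anything outside keeps ``fit_ok=False``);
    ``te_ms`` is carried as metadata only.
    """

    volumes: list[ImageVolume]
    flip_angles_deg: list[float]
    tr_ms: float
    te_ms: float | None = None
    mask: np.ndarray | LabelMap | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.flip_angles_deg):
            raise ValueError("one volume per flip angle required")
        if len(set(self.flip_angles_deg)) < 2:
            raise ValueError("at least two distinct flip angles required")
        if list(self.flip_angles_deg) != sorted(self.flip_angles_deg):
            raise ValueError("flip angles must be strictly increasing")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError("volumes do not share a grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def signals(self) -> np.ndarray:
        """Stacked signals, shape ``(n_alpha, nx, ny, nz)``."""
        return np.stack([v.data for v in self.volumes], axis=0)

    def fit_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.mask, LabelMap):
            return self.mask.myocardium_mask()
        return np.asarray(self.mask, dtype=bool)


@dataclass
class T1Map:
    """Per-voxel T1/M0 estimates with a validity flag."""

    t1_ms: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray
    method: str


def fit_t1_linear(stack: VFAStack) -> T1Map:
    """Linearized VFA fit: per-voxel least-squares line of S/sin α on S/tan α.

    Voxels whose slope falls outside (0, 1), or with fewer than two positive
    signals, are flagged ``fit_ok=False`` (values NaN) rather than clamped.
    """
    alphas = np.deg2rad(np.asarray(stack.flip_angles_deg))
    s = stack.signals()
    mask = stack.fit_mask()
    n_alpha = len(alphas)
    sv = s.reshape(n_alpha, -1)
    usable = sv > 0
    w = usable.astype(np.float64)
    n_use = w.sum(axis=0)

    sin_a = np.sin(alphas)[:, None]
    tan_a = np.tan(alphas)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(usable, sv / sin_a, 0.0)
        x = np.where(usable, sv / tan_a, 0.0)
        xm = x.sum(axis=0) / n_use
        ym = y.sum(axis=0) / n_use
        dx = np.where(usable, x - xm, 0.0)
        dy = np.where(usable, y - ym, 0.0)
        sxx = (dx * dx).sum(axis=0)
        slope = np.where(sxx > 0, (dx * dy).sum(axis=0) / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym - slope * xm
        ok = (
            mask.ravel()
            & (n_use >= 2)
            & np.isfinite(slope)
            & (slope > 0.0)
            & (slope < 1.0)
        )
        t1 = np.full(sv.shape[1], np.nan)
        m0 = np.full(sv.shape[1], np.nan)
        t1[ok] = -stack.tr_ms / np.log(slope[ok])
        m0[ok] = intercept[ok] / (1.0 - slope[ok])
    ok &= np.isfinite(t1) & (t1 > 0)
    t1[~ok] = np.nan
    m0[~ok] = np.nan
    shp = stack.shape
    return T1Map(t1.reshape(shp), m0.reshape(shp), ok.reshape(shp), "linear")


def fit_t1_nonlinear(stack: VFAStack, init: T1Map, max_iter: int = 50) -> T1Map:
    """Damped Gauss–Newton refinement of (M0, T1) per voxel.

    Iterates only on voxels with a valid linear initialization; each step is
    halved until the residual does not increase, so the refined residual is
    never worse than the initial one.  T1 is kept within the physiological
    window [100, 10000] ms; voxels that cannot improve retain their
    initial values.
    """
    alphas = np.deg2rad(np.asarray(stack.flip_angles_deg))
    sin_a, cos_a = np.sin(alphas)[:, None], np.cos(alphas)[:, None]
    tr = stack.tr_ms
    s = stack.signals().reshape(len(alphas), -1)
    ok = init.fit_ok.ravel().copy()
    idx = np.flatnonzero(ok & np.isfinite(init.t1_ms.ravel()) & np.isfinite(init.m0.ravel()))
    t1 = init.t1_ms.ravel().copy()
    m0 = init.m0.ravel().copy()

    if idx.size:
        t1w = np.clip(t1[idx], T1_MIN_MS, T1_MAX_MS)
        m0w = m0[idx].copy()
        sobs = s[:, idx]

        def model_and_resid(m0v, t1v):
            e1 = np.exp(-tr / t1v)[None, :]
            mod = m0v[None, :] * sin_a * (1.0 - e1) / (1.0 - e1 * cos_a)
            r = sobs - mod
            return mod, r, (r * r).sum(axis=0)

        _, _, cost = model_and_resid(m0w, t1w)
        for _ in range(max_iter):
            e1 = np.exp(-tr / t1w)[None, :]
            denom = 1.0 - e1 * cos_a
            mod = m0w[None, :] * sin_a * (1.0 - e1) / denom
            r = sobs - mod
            # Jacobian columns: dS/dM0 and dS/dT1 (chain rule through E1)
            j_m0 = sin_a * (1.0 - e1) / denom
            ds_de1 = m0w[None, :] * sin_a * (cos_a - 1.0) / denom**2
            de1_dt1 = e1 * tr / (t1w**2)[None, :]
            j_t1 = ds_de1 * de1_dt1
            # 2x2 normal equations per voxel
            a11 = (j_m0 * j_m0).sum(axis=0)
            a12 = (j_m0 * j_t1).sum(axis=0)
            a22 = (j_t1 * j_t1).sum(axis=0)
            b1 = (j_m0 * r).sum(axis=0)
            b2 = (j_t1 * r).sum(axis=0)
            det = a11 * a22 - a12 * a12
            good = np.abs(det) > 1e-30
            dm0 = np.where(good, (a22 * b1 - a12 * b2) / np.where(good, det, 1.0), 0.0)
            dt1 = np.where(good, (a11 * b2 - a12 * b1) / np.where(good, det, 1.0), 0.0)

            step = np.ones_like(t1w)
            improved = np.zeros_like(t1w, dtype=bool)
            m0_new, t1_new = m0w.copy(), t1w.copy()
            for _half in range(12):
                trial_m0 = m0w + step * dm0
                trial_t1 = np.clip(t1w + step * dt1, T1_MIN_MS, T1_MAX_MS)
                _, _, trial_cost = model_and_resid(trial_m0, trial_t1)
                better = ~improved & (trial_cost <= cost)
                m0_new[better] = trial_m0[better]
                t1_new[better] = trial_t1[better]
                cost[better] = trial_cost[better]
                improved |= better
                if improved.all():
                    break
                step *= 0.5
            m0w, t1w = m0_new, t1_new
            if np.max(np.abs(dm0[improved]) if improved.any() else 0.0) < 1e-12 and (
                np.max(np.abs(dt1[improved]) if improved.any() else 0.0) < 1e-9
            ):
                break
        t1[idx] = t1w
        m0[idx] = m0w

    shp = stack.shape
    return T1Map(t1.reshape(shp), m0.reshape(shp), ok.reshape(shp), "nonlinear")


def correct_bias_field(
    volume: ImageVolume, mask: np.ndarray | LabelMap, order: int = 2
) -> tuple[ImageVolume, ImageVolume]:
    """Estimate and remove a smooth multiplicative shading field.

    Per slice, a 2D polynomial surface of total degree ≤ ``order`` is fit by
    least squares to the log-intensity of positive masked voxels; the
    exponentiated surface, normalized to unit mean over the mask, is divided
    out.  Returns (corrected volume, estimated field).
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    m = mask.myocardium_mask() if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    data = volume.data
    nx, ny, nz = data.shape
    xh = np.linspace(-1.0, 1.0, nx)[:, None] * np.ones((1, ny))
    yh = np.linspace(-1.0, 1.0, ny)[None, :] * np.ones((nx, 1))
    terms = [
        np.ones_like(xh) if (i, j) == (0, 0) else xh**i * yh**j
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    design = np.stack([t.ravel() for t in terms], axis=1)

    log_field = np.zeros_like(data)
    fitted_any = False
    for k in range(nz):
        sl_mask = m[:, :, k] & (data[:, :, k] > 0)
        if sl_mask.sum() < design.shape[1]:
            continue
        sel = sl_mask.ravel()
        coef, *_ = np.linalg.lstsq(design[sel], np.log(data[:, :, k].ravel()[sel]), rcond=None)
        log_field[:, :, k] = (design @ coef).reshape(nx, ny)
        fitted_any = True
    if not fitted_any:
        raise ValueError("no slice had enough positive masked voxels to fit")
    field = np.exp(log_field)
    field /= field[m].mean()
    corrected = data / field
    return ImageVolume(corrected, volume.voxel_size), ImageVolume(field, volume.voxel_size)
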