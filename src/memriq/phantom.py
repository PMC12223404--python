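"""Digital short-axis left-ventricle phantom with full ground truth.

The phantom is an annulus (myocardium) around a circular cavity, replicated
across slices, on a grid matching a typical preclinical 7T acquisition
(matrix 120 × 110 × 10, FOV 28 × 25 × 8 mm³).  It emulates four acquisitions:

* a multi-flip-angle SPGR stack for T1 mapping,
* an 11-frame / 66-min dynamic manganese-uptake series spanning 30 min of
  coronary occlusion followed by reperfusion,
* a single late-enhancement (LGE-like) volume with a bright sector,
* a 20-frame cine with sinusoidal wall motion for volumetrics.

Every generator returns the exact ground truth (ischemic mask, deficit
fraction, cavity volumes, enhanced fraction) so downstream estimators can be
tested for recovery rather than plausibility.

Kinetic model: perfused myocardium follows a saturating mono-exponential
wash-in ``SI(t) = s0·(1 + u_max·(1 − exp(−t/tau_up)))``; ischemic tissue
receives no tracer and follows a linear non-increase
``SI(t) = s0·(1 − d_rate·min(t, t_occlusion))`` that freezes at reperfusion.
These are the simplest forms consistent with the observed ROI dynamics
(steady uptake in perfused wall, flat-to-declining signal in the occluded
lateral territory); no compartment model is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    BACKGROUND,
    CAVITY,
    MYOCARDIUM,
    DynamicSeries,
    ImageVolume,
    LabelMap,
    angle_in_interval,
    assign_sectors,
    inplane_coordinates_mm,
    polar_angle_deg,
)
from .t1 import spgr_signal


class GeometryError(ValueError):
    """Requested anatomy does not fit the imaging grid."""


@dataclass
class PhantomSpec:
    """Geometry, degradation and reproducibility parameters of the phantom.

    Defaults give a mouse-sized LV: endocardial/epicardial radii 1.5/2.5 mm
    at end-diastole, 0.8/2.2 mm at end-systole (wall thickens from 1.0 to
    1.4 mm in systole), on the 120 × 110 × 10 grid with 28 × 25 × 8 mm³ FOV.
    """

    grid_shape: tuple[int, int, int] = (120, 110, 10)
    voxel_size: tuple[float, float, float] = (28.0 / 120.0, 25.0 / 110.0, 0.8)
    center_mm: tuple[float, float] | None = None  # defaults to grid center
    r_endo_ed: float = 1.5
    r_epi_ed: float = 2.5
    r_endo_es: float = 0.8
    r_epi_es: float = 2.2
    ischemic_sector_deg: tuple[float, float] | None = (-54.0, 54.0)
    ischemic_slices: tuple[int, int] | None = None  # inclusive; None = all
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    bias_amplitude: float = 0.0
    shift_mm: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_endo_ed >= self.r_epi_ed or self.r_endo_es >= self.r_epi_es:
            raise ValueError("endocardial radius must be smaller than epicardial")
        if min(self.r_endo_ed, self.r_endo_es) < 0:
            raise ValueError("radii must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.ischemic_sector_deg is not None:
            lo, hi = self.ischemic_sector_deg
            width = (hi - lo) % 360.0
            if width <= 0:
                raise ValueError("ischemic sector width must lie in (0, 360) degrees")

    @property
    def center(self) -> tuple[float, float]:
        """Annulus center: the voxel center nearest the grid middle.

        Aligning the center with a voxel center (rather than the voxel
        corner the exact FOV midpoint falls on for even matrices) avoids the
        degenerate grid registration in which no voxel row/column passes
        through the cavity center and small-cavity voxel counts are
        systematically biased low.
        """
        if self.center_mm is not None:
            return self.center_mm
        nx, ny, _ = self.grid_shape
        return ((nx // 2 + 0.5) * self.voxel_size[0], (ny // 2 + 0.5) * self.voxel_size[1])

    def radii(self, phase: str) -> tuple[float, float]:
        if phase == "ED":
            return self.r_endo_ed, self.r_epi_ed
        if phase == "ES":
            return self.r_endo_es, self.r_epi_es
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")


@dataclass
class UptakeKinetics:
    """Manganese uptake/decline kinetics of the dynamic series.

    ``u_max`` is the fractional plateau enhancement of perfused tissue,
    ``tau_up`` the wash-in time constant (min), ``d_rate`` the fractional
    per-minute decline of the ischemic territory during occlusion.
    """

    s0: float = 100.0
    u_max: float = 1.5
    tau_up: float = 15.0
    d_rate: float = 0.003
    t_occlusion: float = 30.0
    t_total: float = 66.0
    n_frames: int = 11
    cavity_si: float = 60.0
    background_si: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_up <= 0:
            raise ValueError("tau_up must be positive")
        if self.d_rate < 0:
            raise ValueError("d_rate must be >= 0")
        if self.n_frames < 2:
            raise ValueError("at least two frames are needed to estimate a slope")
        if not (0 < self.t_occlusion < self.t_total):
            raise ValueError("t_occlusion must lie strictly inside (0, t_total)")

    def timestamps(self) -> np.ndarray:
        """Frame timestamps (min): midpoints of equal acquisition intervals."""
        dt = self.t_total / self.n_frames
        return dt / 2.0 + dt * np.arange(self.n_frames)

    def perfused_si(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.s0 * (1.0 + self.u_max * (1.0 - np.exp(-np.asarray(t, float) / self.tau_up)))

    def ischemic_si(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.s0 * (1.0 - self.d_rate * np.minimum(np.asarray(t, float), self.t_occlusion))


@dataclass
class GroundTruth:
    """Truth manifest attached to each simulated acquisition."""

    t1_true_ms: np.ndarray | None = None
    ischemic_mask: np.ndarray | None = None
    deficit_fraction_true: float | None = None
    cavity_volume_true_ul: np.ndarray | None = None
    enhanced_fraction_true: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry


def make_lv_labelmap(spec: PhantomSpec, phase: str = "ED") -> LabelMap:
    """Voxelize the annulus geometry for one cardiac phase.

    Cavity: in-plane radius ρ < r_endo; myocardium: r_endo ≤ ρ ≤ r_epi.
    Myocardial voxels additionally carry one of the four sector codes.
    """
    r_endo, r_epi = spec.radii(phase)
    return _voxelize_annulus(spec, r_endo, r_epi)


def _voxelize_annulus(
    spec: PhantomSpec,
    r_endo: float,
    r_epi: float,
    r_endo_by_angle=None,
    r_epi_by_angle=None,
) -> LabelMap:
    nx, ny, nz = spec.grid_shape
    cx, cy = spec.center
    fov_x, fov_y = nx * spec.voxel_size[0], ny * spec.voxel_size[1]
    margin = min(cx, fov_x - cx, cy, fov_y - cy)
    if r_epi > margin:
        raise GeometryError(
            f"epicardial radius {r_epi:.2f} mm exceeds the in-plane FOV margin {margin:.2f} mm"
        )
    x, y = inplane_coordinates_mm(spec.grid_shape, spec.voxel_size, (cx, cy))
    rho = np.hypot(x, y)
    theta = polar_angle_deg(x, y)
    if r_endo_by_angle is not None:
        r_in = r_endo_by_angle(theta)
        r_out = r_epi_by_angle(theta)
    else:
        r_in = np.full_like(rho, r_endo)
        r_out = np.full_like(rho, r_epi)
    plane = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    plane[rho < r_in] = CAVITY
    plane[(rho >= r_in) & (rho <= r_out)] = MYOCARDIUM
    sectors_plane = np.where(plane == MYOCARDIUM, assign_sectors(theta), 0).astype(np.int16)
    tissue = np.repeat(plane[:, :, None], nz, axis=2)
    sector = np.repeat(sectors_plane[:, :, None], nz, axis=2)
    return LabelMap(tissue=tissue, voxel_size=spec.voxel_size, sector=sector)


def ischemic_mask(spec: PhantomSpec, labels: LabelMap) -> np.ndarray:
    """True ischemic voxels: myocardium within the spec's angular sector/slices."""
    if spec.ischemic_sector_deg is None:
        return np.zeros(labels.shape, dtype=bool)
    x, y = inplane_coordinates_mm(labels.shape, labels.voxel_size, spec.center)
    theta = polar_angle_deg(x, y)
    in_sector = angle_in_interval(theta, spec.ischemic_sector_deg)
    mask = labels.myocardium_mask() & in_sector[:, :, None]
    if spec.ischemic_slices is not None:
        z0, z1 = spec.ischemic_slices
        zsel = np.zeros(labels.shape[2], dtype=bool)
        zsel[z0 : z1 + 1] = True
        mask &= zsel[None, None, :]
    return mask


def sector_width_for_fraction(fraction_pct: float) -> tuple[float, float]:
    """Angular interval (centered on the lateral wall) whose myocardial share
    is approximately ``fraction_pct`` percent of the annulus."""
    half = 360.0 * fraction_pct / 100.0 / 2.0
    return (-half, half)


# ---------------------------------------------------------------------------
# signal degradation


def bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative shading: exp of a fixed zero-mean in-plane
    quadratic scaled by ``bias_amplitude``, identical across slices."""
    nx, ny, nz = spec.grid_shape
    if spec.bias_amplitude == 0:
        return np.ones((nx, ny, nz))
    xh = np.linspace(-1.0, 1.0, nx)[:, None]
    yh = np.linspace(-1.0, 1.0, ny)[None, :]
    p = 0.7 * xh - 0.5 * yh + 0.4 * xh * yh - 0.6 * xh**2 + 0.3 * yh**2
    p = p - p.mean()
    f = np.exp(spec.bias_amplitude * p)
    f = f / f.mean()
    return np.repeat(f[:, :, None], nz, axis=2)


def _apply_noise(data: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma == 0:
        return data
    if spec.noise_model == "gaussian":
        return data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    # Rician: magnitude of the complex signal with i.i.d. Gaussian quadratures
    re = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    im = rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return np.hypot(re, im)


def _apply_shift(data: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Whole-pixel in-plane translation (edge padding with the border value 0)."""
    if spec.shift_mm is None:
        return data
    si = int(round(spec.shift_mm[0] / spec.voxel_size[0]))
    sj = int(round(spec.shift_mm[1] / spec.voxel_size[1]))
    out = np.zeros_like(data)
    nx, ny = data.shape[0], data.shape[1]
    xs_src = slice(max(0, -si), min(nx, nx - si))
    xs_dst = slice(max(0, si), min(nx, nx + si))
    ys_src = slice(max(0, -sj), min(ny, ny - sj))
    ys_dst = slice(max(0, sj), min(ny, ny + sj))
    out[xs_dst, ys_dst, :] = data[xs_src, ys_src, :]
    return out


# ---------------------------------------------------------------------------
# simulated acquisitions


def simulate_memri_dynamics(
    spec: PhantomSpec, kin: UptakeKinetics | None = None
) -> tuple[DynamicSeries, GroundTruth]:
    """Dynamic contrast series over occlusion + reperfusion with truth.

    Perfused myocardium washes in mono-exponentially; the ischemic sector
    declines linearly until ``t_occlusion`` and stays flat afterwards.
    Cavity and background hold constant baselines.  Bias, noise and the
    optional post-occlusion rigid shift are applied last, in that order.
    """
    kin = kin or UptakeKinetics()
    labels = make_lv_labelmap(spec, "ED")
    isch = ischemic_mask(spec, labels)
    myo = labels.myocardium_mask()
    perfused = myo & ~isch
    times = kin.timestamps()
    bias = bias_field(spec)
    rng = np.random.default_rng(spec.seed)

    frames: list[ImageVolume] = []
    windows: list[str] = []
    for t in times:
        vol = np.full(labels.shape, kin.background_si, dtype=np.float64)
        vol[labels.cavity_mask()] = kin.cavity_si
        vol[perfused] = kin.perfused_si(t)
        vol[isch] = kin.ischemic_si(t)
        vol *= bias
        vol = _apply_noise(vol, spec, rng)
        if t > kin.t_occlusion:
            vol = _apply_shift(vol, spec)
        frames.append(ImageVolume(vol, spec.voxel_size))
        windows.append("ischemia" if t <= kin.t_occlusion else "reperfusion")

    n_myo = int(myo.sum())
    truth = GroundTruth(
        ischemic_mask=isch,
        deficit_fraction_true=100.0 * isch.sum() / n_myo if n_myo else 0.0,
        extras={"labels": labels, "kinetics": kin},
    )
    return DynamicSeries(frames, times, windows), truth


def make_t1_truth(
    labels: LabelMap,
    t1_myo_ms: float = 1490.0,
    t1_blood_ms: float = 2200.0,
    m0: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """True T1 and M0 volumes: uniform myocardium (native mouse myocardium at
    7T is ≈1490 ms), brighter/longer blood pool, zero background."""
    t1 = np.zeros(labels.shape)
    t1[labels.myocardium_mask()] = t1_myo_ms
    t1[labels.cavity_mask()] = t1_blood_ms
    m0_vol = np.where(t1 > 0, m0, 0.0)
    return t1, m0_vol


def simulate_vfa_stack(
    spec: PhantomSpec,
    t1_map: np.ndarray,
    m0: np.ndarray,
    flip_angles_deg: list[float] = (2.0, 5.0, 8.0, 11.0, 14.0),
    tr_ms: float = 11.1,
) -> list[ImageVolume]:
    """Multi-flip-angle SPGR volumes from a true (T1, M0) pair.

    Signal is the SPGR steady-state closed form wherever T1 > 0, zero
    elsewhere; the spec's bias field and noise are applied per volume.
    """
    flip_angles_deg = list(flip_angles_deg)
    if any(a <= 0 or a > 90 for a in flip_angles_deg):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    labels = make_lv_labelmap(spec, "ED")
    myo = labels.myocardium_mask()
    if np.any(t1_map[myo] <= 0):
        raise ValueError("T1 must be positive throughout the myocardium")
    bias = bias_field(spec)
    rng = np.random.default_rng(spec.seed)
    pos = t1_map > 0
    volumes = []
    for alpha in flip_angles_deg:
        vol = np.zeros(spec.grid_shape)
        vol[pos] = spgr_signal(alpha, m0[pos], t1_map[pos], tr_ms)
        vol *= bias
        vol = _apply_noise(vol, spec, rng)
        volumes.append(ImageVolume(vol, spec.voxel_size))
    return volumes


def simulate_lge_volume(
    spec: PhantomSpec,
    enhanced_sector_deg: tuple[float, float] | None,
    enhancement_factor: float = 2.0,
    baseline_si: float = 100.0,
    cavity_si: float = 60.0,
    background_si: float = 5.0,
) -> tuple[ImageVolume, GroundTruth]:
    """Single post-contrast volume with a hyper-enhanced myocardial sector.

    ``enhanced_sector_deg=None`` (or an empty sector) yields a valid volume
    with zero true enhanced fraction.
    """
    if enhancement_factor <= 1:
        raise ValueError("enhancement_factor must exceed 1")
    labels = make_lv_labelmap(spec, "ED")
    myo = labels.myocardium_mask()
    vol = np.full(labels.shape, background_si, dtype=np.float64)
    vol[labels.cavity_mask()] = cavity_si
    vol[myo] = baseline_si
    if enhanced_sector_deg is not None:
        enh_spec = replace(spec, ischemic_sector_deg=enhanced_sector_deg)
        enh = ischemic_mask(enh_spec, labels)
    else:
        enh = np.zeros(labels.shape, dtype=bool)
    vol[enh] = baseline_si * enhancement_factor
    vol *= bias_field(spec)
    vol = _apply_noise(vol, spec, np.random.default_rng(spec.seed))
    n_myo = int(myo.sum())
    truth = GroundTruth(
        ischemic_mask=enh,
        enhanced_fraction_true=100.0 * enh.sum() / n_myo if n_myo else 0.0,
        extras={"labels": labels},
    )
    return ImageVolume(vol, spec.voxel_size), truth


def simulate_cine(
    spec: PhantomSpec,
    n_frames: int = 20,
    impaired_sector_deg: tuple[float, float] | None = None,
) -> tuple[list[LabelMap], GroundTruth]:
    """Cine label maps with sinusoidal radius interpolation between ED and ES.

    Frame f uses ``r(f) = r_ed + (r_es − r_ed)·(1 − cos(2πf/n))/2``, so frame
    0 is end-diastole and the mid-cycle frame end-systole.  An optional
    ``impaired_sector_deg`` freezes that sector at its ED geometry in every
    frame (akinetic wall), which suppresses both thickening and inward motion
    there.  True cavity volumes are computed analytically per frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    phase = (1.0 - np.cos(2.0 * np.pi * np.arange(n_frames) / n_frames)) / 2.0
    maps: list[LabelMap] = []
    volumes_true = np.empty(n_frames)
    nz = spec.grid_shape[2]
    slab_mm = nz * spec.voxel_size[2]
    for f in range(n_frames):
        r_endo = spec.r_endo_ed + (spec.r_endo_es - spec.r_endo_ed) * phase[f]
        r_epi = spec.r_epi_ed + (spec.r_epi_es - spec.r_epi_ed) * phase[f]
        if impaired_sector_deg is None:
            maps.append(_voxelize_annulus(spec, r_endo, r_epi))
            volumes_true[f] = np.pi * r_endo**2 * slab_mm
        else:
            lo, hi = impaired_sector_deg
            width = (hi - lo) % 360.0

            def r_in(theta, _r=r_endo):
                inside = angle_in_interval(theta, (lo, hi))
                return np.where(inside, spec.r_endo_ed, _r)

            def r_out(theta, _r=r_epi):
                inside = angle_in_interval(theta, (lo, hi))
                return np.where(inside, spec.r_epi_ed, _r)

            maps.append(_voxelize_annulus(spec, r_endo, r_epi, r_in, r_out))
            frac = width / 360.0
            volumes_true[f] = (
                np.pi * slab_mm * (frac * spec.r_endo_ed**2 + (1 - frac) * r_endo**2)
            )
    truth = GroundTruth(cavity_volume_true_ul=volumes_true)
    return maps, truth
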