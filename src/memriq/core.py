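"""Shared containers for image volumes and label maps.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` = (x, y, slice); voxel centers sit at
``(i + 0.5) * dx`` etc. (half-voxel convention).  Intensities are arbitrary
units; spatial units are mm, volumes are reported in µL (1 mm³ = 1 µL).

Tissue codes: 0 = background, 1 = LV cavity, 2 = LV myocardium.
Sector codes (myocardium only): 1 = septal, 2 = lateral, 3 = anterior,
4 = inferior; 0 = no sector.  The lateral sector is centered on 0° and the
septal on 180° in the in-plane polar angle, matching the convention that the
LAD territory lies in the lateral wall of the mouse short-axis view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND = 0
CAVITY = 1
MYOCARDIUM = 2

SECTOR_NONE = 0
SECTOR_SEPTAL = 1
SECTOR_LATERAL = 2
SECTOR_ANTERIOR = 3
SECTOR_INFERIOR = 4

SECTOR_NAMES = {
    SECTOR_SEPTAL: "septal",
    SECTOR_LATERAL: "lateral",
    SECTOR_ANTERIOR: "anterior",
    SECTOR_INFERIOR: "inferior",
}
SECTOR_CODES = {v: k for k, v in SECTOR_NAMES.items()}


@dataclass
class ImageVolume:
    """3D scalar intensity grid with voxel spacing metadata.

    Parameters
    ----------
    data
        Intensity array of shape ``(nx, ny, nz)``.
    voxel_size
        ``(dx, dy, dz)`` in mm; ``dz`` is the slice thickness.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL (= mm³)."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class LabelMap:
    """Integer tissue map plus a parallel sector map on the same grid.

    ``tissue`` codes background/cavity/myocardium; ``sector`` carries the
    septal/lateral/anterior/inferior codes on myocardial voxels.
    """

    tissue: np.ndarray
    voxel_size: tuple[float, float, float]
    sector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=np.int16)
        if self.tissue.ndim != 3:
            raise ValueError("tissue map must be 3D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.sector is None:
            self.sector = np.zeros_like(self.tissue)
        else:
            self.sector = np.asarray(self.sector, dtype=np.int16)
            if self.sector.shape != self.tissue.shape:
                raise ValueError("sector map must match tissue map shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue.shape

    @property
    def voxel_volume_ul(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def cavity_mask(self) -> np.ndarray:
        return self.tissue == CAVITY

    def myocardium_mask(self) -> np.ndarray:
        return self.tissue == MYOCARDIUM

    def sector_mask(self, sector: int | str) -> np.ndarray:
        """Myocardial voxels belonging to one sector (by code or name)."""
        code = SECTOR_CODES[sector] if isinstance(sector, str) else int(sector)
        return (self.tissue == MYOCARDIUM) & (self.sector == code)


@dataclass
class DynamicSeries:
    """Ordered dynamic acquisition: one volume per timestamp on a shared grid.

    ``windows`` tags each frame as ``"ischemia"`` or ``"reperfusion"``.
    """

    frames: list[ImageVolume]
    times_min: np.ndarray
    windows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=np.float64)
        if len(self.frames) != len(self.times_min):
            raise ValueError("one timestamp per frame required")
        if len(self.frames) >= 2 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("timestamps must be strictly increasing")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames do not share a grid: {shapes}")
        if not self.windows:
            self.windows = ["" for _ in self.frames]
        if len(self.windows) != len(self.frames):
            raise ValueError("one window tag per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.frames[0].voxel_size

    def as_4d(self) -> np.ndarray:
        """Stack frames into an array of shape ``(nt, nx, ny, nz)``."""
        return np.stack([f.data for f in self.frames], axis=0)


def inplane_coordinates_mm(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    center_mm: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane voxel-center coordinates (mm) relative to ``center_mm``.

    Returns two 2D arrays ``(x, y)`` of shape ``(nx, ny)``.
    """
    nx, ny = shape[0], shape[1]
    dx, dy = voxel_size[0], voxel_size[1]
    x = (np.arange(nx) + 0.5) * dx - center_mm[0]
    y = (np.arange(ny) + 0.5) * dy - center_mm[1]
    return np.meshgrid(x, y, indexing="ij")


def polar_angle_deg(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Polar angle in degrees in [0, 360), counterclockwise from +x."""
    return np.degrees(np.arctan2(y, x)) % 360.0


def angle_in_interval(theta_deg: np.ndarray, interval_deg: tuple[float, float]) -> np.ndarray:
    """Membership of angles in a possibly wrapping interval [lo, hi) degrees."""
    lo, hi = (interval_deg[0] % 360.0, interval_deg[1] % 360.0)
    theta = np.asarray(theta_deg) % 360.0
    if lo <= hi:
        return (theta >= lo) & (theta < hi)
    return (theta >= lo) | (theta < hi)


def assign_sectors(theta_deg: np.ndarray) -> np.ndarray:
    """Map polar angles to the four 90° anatomical sectors.

    Lateral is centered at 0°, anterior at 90°, septal at 180°, inferior at
    270°; boundaries fall at 45°, 135°, 225° and 315°.
    """
    theta = np.asarray(theta_deg) % 360.0
    out = np.full(theta.shape, SECTOR_NONE, dtype=np.int16)
    out[(theta >= 315.0) | (theta < 45.0)] = SECTOR_LATERAL
    out[(theta >= 45.0) & (theta < 135.0)] = SECTOR_ANTERIOR
    out[(theta >= 135.0) & (theta < 225.0)] = SECTOR_SEPTAL
    out[(theta >= 225.0) & (theta < 315.0)] = SECTOR_INFERIOR
    return out
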