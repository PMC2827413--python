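"""Voxel phantoms: soil background with ellipsoidal tubers of known volume.

A phantom draws each voxel from one of two grey-level populations —
soil background or tuber material — with ground truth (label masks and
analytic ellipsoid volumes) computed before partial-volume blur and
noise are applied. A per-slice parallel-beam projection/back-projection
simulator adds realistic reconstruction artifacts for robustness tests.

Defaults place tuber grey levels (mean 3400) inside the default
segmentation window [2938, 3963] and soil (mean 2000) below it, at the
scanner's 141 um voxel pitch (spacing 0.141 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import iradon, radon

from tuberome.volumetry import VoxelVolume

__all__ = [
    "TuberSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "project_and_reconstruct",
    "linear_growth_specs",
    "sphere_spec",
]

GREY_MAX = 65535  # 16-bit scale
DEFAULT_SPACING_MM = 0.141
DEFAULT_SOIL_MEAN = 2000.0
DEFAULT_TUBER_MEAN = 3400.0
DEFAULT_GREY_SD = 50.0


@dataclass(frozen=True)
class TuberSpec:
    """One ellipsoidal tuber: center and semi-axes in voxels, grey stats.

    ``orientation`` rotates the ellipsoid about the vertical (z) axis,
    in degrees. Grey levels are on the 16-bit scale.
    """

    center: tuple[float, float, float]  # (z, y, x) voxels
    semi_axes: tuple[float, float, float]  # (az, ay, ax) voxels
    orientation: float = 0.0
    grey_mean: float = DEFAULT_TUBER_MEAN
    grey_sd: float = DEFAULT_GREY_SD

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must all be > 0")
        if not (0 <= self.grey_mean <= GREY_MAX):
            raise ValueError(f"grey_mean outside 16-bit range: {self.grey_mean}")
        if self.grey_sd < 0:
            raise ValueError("grey_sd must be >= 0")

    def analytic_volume_cm3(self, spacing_mm: float) -> float:
        """Exact ellipsoid volume 4/3*pi*a*b*c in cm^3 at the given spacing."""
        az, ay, ax = self.semi_axes
        edge_cm = spacing_mm / 10.0
        return 4.0 / 3.0 * math.pi * az * ay * ax * edge_cm**3

    def membership(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean mask of voxels whose centers lie inside the ellipsoid."""
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        dz = zz - cz
        dy = yy - cy
        dx = xx - cx
        theta = math.radians(self.orientation)
        # rotate in-plane coordinates into the ellipsoid frame (about z)
        dyr = math.cos(theta) * dy + math.sin(theta) * dx
        dxr = -math.sin(theta) * dy + math.cos(theta) * dx
        return (dz / az) ** 2 + (dyr / ay) ** 2 + (dxr / ax) ** 2 <= 1.0

    def _extent_ok(self, shape: tuple[int, int, int]) -> bool:
        # rotated bounding half-widths about z; z half-width unaffected
        cz, cy, cx = self.center
        az, ay, ax = self.semi_axes
        theta = math.radians(self.orientation)
        hy = math.hypot(ay * math.cos(theta), ax * math.sin(theta))
        hx = math.hypot(ay * math.sin(theta), ax * math.cos(theta))
        lo = (cz - az, cy - hy, cx - hx)
        hi = (cz + az, cy + hy, cx + hx)
        return all(l >= 0 for l in lo) and all(h <= s - 1 for h, s in zip(hi, shape))


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry, grey-level populations, blur and seed."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = DEFAULT_SPACING_MM
    soil_grey_mean: float = DEFAULT_SOIL_MEAN
    soil_grey_sd: float = DEFAULT_GREY_SD
    tubers: tuple[TuberSpec, ...] = ()
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(s < 8 for s in self.shape):
            raise ValueError("grid dimensions must all be >= 8")
        if not (0 <= self.soil_grey_mean <= GREY_MAX):
            raise ValueError("soil_grey_mean outside 16-bit range")
        if self.soil_grey_sd < 0 or self.blur_sigma < 0:
            raise ValueError("soil_grey_sd and blur_sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth computed before blur/noise: label masks and volumes.

    ``labels[z,y,x]`` carries the 1-based tuber index (0 = soil);
    ``volumes`` has one row per tuber: label, voxel_count (voxel-center
    membership) and the analytic ellipsoid volume in cm^3.
    """

    labels: np.ndarray
    volumes: pd.DataFrame = field(repr=False)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a grey-level phantom and its ground truth.

    Voxels inside a tuber ellipsoid (voxel-center membership) take that
    tuber's grey mean, others the soil mean; the mean image is blurred by
    ``blur_sigma`` (partial-volume emulation) and region-wise Gaussian
    noise (soil/tuber sds) is added. Overlapping tubers and tubers
    extending outside the grid are rejected.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    rows = []
    for i, tuber in enumerate(spec.tubers, start=1):
        if not tuber._extent_ok(spec.shape):
            raise ValueError(f"tuber {i} extends outside the grid")
        member = tuber.membership(spec.shape)
        if (labels[member] != 0).any():
            raise ValueError(f"tuber {i} overlaps an earlier tuber")
        labels[member] = i
        rows.append(
            {
                "label": i,
                "voxel_count": int(member.sum()),
                "true_volume_cm3": tuber.analytic_volume_cm3(spec.spacing),
            }
        )
    volumes = pd.DataFrame(rows, columns=["label", "voxel_count", "true_volume_cm3"])

    mean_img = np.full(spec.shape, spec.soil_grey_mean, dtype=float)
    sd_img = np.full(spec.shape, spec.soil_grey_sd, dtype=float)
    for i, tuber in enumerate(spec.tubers, start=1):
        mean_img[labels == i] = tuber.grey_mean
        sd_img[labels == i] = tuber.grey_sd

    if spec.blur_sigma > 0:
        mean_img = ndimage.gaussian_filter(mean_img, sigma=spec.blur_sigma)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    grey = mean_img + rng.standard_normal(spec.shape) * sd_img
    grey = np.clip(np.rint(grey), 0, GREY_MAX).astype(np.uint16)
    volume = VoxelVolume(grey=grey, spacing=spec.spacing, meta={"seed": spec.seed})
    return volume, PhantomTruth(labels=labels, volumes=volumes)


def project_and_reconstruct(volume: VoxelVolume, n_angles: int = 180) -> VoxelVolume:
    """Parallel-beam sinogram + filtered back-projection, slice by slice.

    Each horizontal (z) slice is projected at ``n_angles`` evenly spaced
    angles over 180 degrees and reconstructed by ramp-filtered
    back-projection. Grid and spacing are preserved; filter ringing and
    streaking emulate reconstruction artifacts of a real scanner.
    """
    if n_angles < 16:
        raise ValueError(f"n_angles must be >= 16, got {n_angles}")
    nz, ny, nx = volume.shape
    side = max(ny, nx)
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    out = np.empty(volume.shape, dtype=np.uint16)
    pad_y, pad_x = (side - ny) // 2, (side - nx) // 2
    for z in range(nz):
        sl = np.zeros((side, side), dtype=float)
        sl[pad_y : pad_y + ny, pad_x : pad_x + nx] = volume.grey[z].astype(float)
        sino = radon(sl, theta=theta, circle=False)
        rec = iradon(sino, theta=theta, circle=False, filter_name="ramp", output_size=side)
        rec = rec[pad_y : pad_y + ny, pad_x : pad_x + nx]
        out[z] = np.clip(np.rint(rec), 0, GREY_MAX).astype(np.uint16)
    meta = dict(volume.meta, reconstructed=True, n_angles=n_angles)
    return VoxelVolume(grey=out, spacing=volume.spacing, meta=meta)


def sphere_spec(
    radius_voxels: float,
    shape: tuple[int, int, int] | None = None,
    spacing: float = DEFAULT_SPACING_MM,
    blur_sigma: float = 0.0,
    grey_sd: float = DEFAULT_GREY_SD,
    soil_sd: float | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """Convenience phantom: one centered spherical tuber of given radius."""
    if shape is None:
        n = int(2 * radius_voxels + 11)
        shape = (n, n, n)
    center = tuple((s - 1) / 2.0 for s in shape)
    tuber = TuberSpec(center=center, semi_axes=(radius_voxels,) * 3, grey_sd=grey_sd)
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        soil_grey_sd=grey_sd if soil_sd is None else soil_sd,
        tubers=(tuber,),
        blur_sigma=blur_sigma,
        seed=seed,
    )


def linear_growth_specs(
    v0_cm3: float,
    dvdt_cm3_per_day: float,
    times_days: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0),
    spacing: float = 1.0,
    blur_sigma: float = 0.0,
    grey_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[PhantomSpec], list[float]]:
    """Phantom series for a tuber whose volume grows linearly in time.

    Returns one PhantomSpec per scan day (sphere with the radius implied
    by V(t) = v0 + dvdt*t) and the analytic volumes, for velocity
    recovery tests of the full scan -> segment -> measure -> fit chain.
    """
    if v0_cm3 <= 0 or dvdt_cm3_per_day < 0:
        raise ValueError("v0_cm3 must be > 0 and dvdt_cm3_per_day >= 0")
    volumes = [v0_cm3 + dvdt_cm3_per_day * t for t in times_days]
    edge_cm = spacing / 10.0
    radii = [(3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0) / edge_cm for v in volumes]
    n = int(2 * max(radii) + 11)
    specs = [
        sphere_spec(
            r, shape=(n, n, n), spacing=spacing, blur_sigma=blur_sigma,
            grey_sd=grey_sd, seed=seed + i,
        )
        for i, r in enumerate(radii)
    ]
    return specs, volumes
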