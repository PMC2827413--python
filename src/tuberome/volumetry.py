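"""Grey-level window segmentation and voxel-count volumetry of CT volumes.

Tubers buried in soil are segmented from reconstructed X-ray CT volumes by
an inclusive grey-level window (defaults 2938..3963 on the 16-bit scale),
labelled as 26-connected components, optionally corrected with manual mask
edits, and measured by counting voxels: each voxel contributes
``(spacing/10)**3`` cm^3. Volumes across repeated scans are linked into
per-tuber time series by greedy nearest-centroid tracking, and calculated
volumes can be validated against independent measurements by ordinary
least squares plus Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VoxelVolume",
    "GreyWindow",
    "SegmentationMask",
    "MaskEdit",
    "VolumeMeasurement",
    "segment",
    "apply_edits",
    "measure_volumes",
    "track_tubers",
    "validate_volumes",
]

#: mm per cm; volumes are reported in cm^3 while spacing is in mm.
_MM_PER_CM = 10.0


@dataclass
class VoxelVolume:
    """A reconstructed 3D grey-level grid with isotropic physical spacing.

    Parameters
    ----------
    grey : ndarray, shape (nz, ny, nx)
        Non-negative grey levels on the 16-bit scale (stored as any
        integer or float dtype; negativity is rejected).
    spacing : float
        Voxel edge length in millimetres (isotropic).
    meta : dict
        Free-form acquisition metadata.
    """

    grey: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grey = np.asarray(self.grey)
        if self.grey.ndim != 3:
            raise ValueError(f"grey must be 3D, got ndim={self.grey.ndim}")
        if self.grey.size == 0:
            raise ValueError("empty volume")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if np.min(self.grey) < 0:
            raise ValueError("grey levels must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grey.shape  # type: ignore[return-value]

    def voxel_volume_cm3(self) -> float:
        """Physical volume of one voxel in cm^3."""
        return float((self.spacing / _MM_PER_CM) ** 3)


@dataclass(frozen=True)
class GreyWindow:
    """Inclusive grey-level window [lower, upper] classifying tuber voxels.

    Defaults are the thresholds used for potato tubers in soil on the
    16-bit scale: 2938 and 3963.
    """

    lower: float = 2938.0
    upper: float = 3963.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"window lower {self.lower} > upper {self.upper}")


@dataclass
class SegmentationMask:
    """Labelled foreground components of a volume.

    ``labels`` is a 3D grid of non-negative integers (0 = background);
    ``components`` is a table with one row per positive label:
    ``label, voxel_count, centroid_z, centroid_y, centroid_x``.
    """

    labels: np.ndarray
    components: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")

    @property
    def label_ids(self) -> list[int]:
        return [int(v) for v in self.components["label"]]


@dataclass(frozen=True)
class MaskEdit:
    """A manual correction: add or remove a box/sphere region of voxels.

    ``region`` is either ``("box", (z0, z1, y0, y1, x0, x1))`` with
    half-open bounds, or ``("sphere", (cz, cy, cx), radius)`` in voxel
    coordinates. ``add`` requires a positive ``target_label``.
    """

    action: Literal["add", "remove"]
    region: tuple
    target_label: int | None = None

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "add" and (self.target_label is None or self.target_label <= 0):
            raise ValueError("add edits require a positive target_label")
        if self.region[0] not in ("box", "sphere"):
            raise ValueError(f"unknown region kind {self.region[0]!r}")


@dataclass(frozen=True)
class VolumeMeasurement:
    """One tuber volume observation: identifier, scan time (days), cm^3."""

    tuber_id: int
    time: float
    volume: float

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _components_table(labels: np.ndarray) -> pd.DataFrame:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(
            columns=["label", "voxel_count", "centroid_z", "centroid_y", "centroid_x"]
        ).astype({"label": int, "voxel_count": int})
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=ids)
    centroids = ndimage.center_of_mass(np.ones(labels.shape), labels, index=ids)
    cz, cy, cx = np.asarray(centroids).T
    return pd.DataFrame(
        {
            "label": ids.astype(int),
            "voxel_count": counts.astype(int),
            "centroid_z": cz,
            "centroid_y": cy,
            "centroid_x": cx,
        }
    )


def segment(
    volume: VoxelVolume,
    window: GreyWindow = GreyWindow(),
    min_voxels: int = 64,
    connectivity: int = 26,
) -> SegmentationMask:
    """Threshold a volume to the grey window and label connected components.

    Voxels with ``window.lower <= grey <= window.upper`` (inclusive on both
    bounds) form the foreground; 26-connected components (configurable to 6)
    are labelled and components smaller than ``min_voxels`` are discarded.
    A window that selects no voxel yields an empty mask, not an error.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    fg = (volume.grey >= window.lower) & (volume.grey <= window.upper)
    labels, _ = ndimage.label(fg, structure=_connectivity_structure(connectivity))
    if labels.max() > 0 and min_voxels > 1:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_voxels]
        if small.size:
            labels[np.isin(labels, small)] = 0
        # relabel to consecutive 1..n
        keep = np.unique(labels)
        remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
        remap[keep] = np.arange(len(keep))
        labels = remap[labels]
    return SegmentationMask(labels=labels, components=_components_table(labels))


def _region_index(shape: tuple[int, int, int], region: tuple) -> np.ndarray:
    """Boolean voxel mask for a MaskEdit region, clipped to the grid."""
    kind = region[0]
    mask = np.zeros(shape, dtype=bool)
    if kind == "box":
        z0, z1, y0, y1, x0, x1 = region[1]
        z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
        mask[z0:z1, y0:y1, x0:x1] = True
    else:  # sphere
        (cz, cy, cx), r = region[1], region[2]
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not mask.any():
        raise ValueError("edit region does not intersect the grid")
    return mask


def apply_edits(mask: SegmentationMask, edits: Sequence[MaskEdit]) -> SegmentationMask:
    """Apply manual corrections in order and recompute the component table.

    ``add`` sets region voxels to the edit's target label; ``remove`` sets
    them to background. The input mask is not modified.
    """
    labels = mask.labels.copy()
    for edit in edits:
        idx = _region_index(labels.shape, edit.region)
        if edit.action == "add":
            labels[idx] = edit.target_label
        else:
            labels[idx] = 0
    return SegmentationMask(labels=labels, components=_components_table(labels))


def measure_volumes(
    mask: SegmentationMask, spacing: float, time: float = 0.0
) -> list[VolumeMeasurement]:
    """Voxel-count volumetry: per label, volume = voxel_count * (spacing/10)^3 cm^3."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    vox_cm3 = (spacing / _MM_PER_CM) ** 3
    return [
        VolumeMeasurement(tuber_id=int(row.label), time=time, volume=float(row.voxel_count) * vox_cm3)
        for row in mask.components.itertuples()
    ]


def track_tubers(
    masks: Sequence[SegmentationMask], max_displacement: float = 10.0
) -> list[dict[int, int]]:
    """Link component labels across time points into stable tuber ids.

    Greedy nearest-centroid matching between consecutive scans: candidate
    (previous tuber, current component) pairs are sorted by centroid
    distance and matched one-to-one while the distance stays within
    ``max_displacement`` voxels. Unmatched components start new tuber ids.

    Returns one ``{label: tuber_id}`` mapping per time point.
    """
    if len(masks) < 2:
        raise ValueError("tracking requires >= 2 time points")
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")

    def centroids(m: SegmentationMask) -> dict[int, np.ndarray]:
        return {
            int(r.label): np.array([r.centroid_z, r.centroid_y, r.centroid_x])
            for r in m.components.itertuples()
        }

    next_id = 0
    mappings: list[dict[int, int]] = []
    prev_pos: dict[int, np.ndarray] = {}  # tuber_id -> last centroid
    first = {}
    for label, pos in centroids(masks[0]).items():
        first[label] = next_id
        prev_pos[next_id] = pos
        next_id += 1
    mappings.append(first)

    for m in masks[1:]:
        cur = centroids(m)
        pairs = sorted(
            (
                (float(np.linalg.norm(prev_pos[tid] - pos)), tid, label)
                for tid in prev_pos
                for label, pos in cur.items()
            ),
            key=lambda t: t[0],
        )
        mapping: dict[int, int] = {}
        used_tids: set[int] = set()
        for dist, tid, label in pairs:
            if dist > max_displacement:
                break
            if tid in used_tids or label in mapping:
                continue
            mapping[label] = tid
            used_tids.add(tid)
        for label in cur:
            if label not in mapping:
                mapping[label] = next_id
                next_id += 1
        for label, tid in mapping.items():
            prev_pos[tid] = cur[label]
        mappings.append(mapping)
    return mappings


def validate_volumes(
    calculated: Sequence[float], measured: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of calculated on measured volumes plus Pearson correlation.

    Returns ``(slope, intercept, pearson_r)``; perfectly agreeing series
    give slope 1, intercept 0, r = 1.
    """
    calculated = np.asarray(calculated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if calculated.shape != measured.shape or calculated.ndim != 1 or len(calculated) < 3:
        raise ValueError("calculated and measured must be equal-length 1D with >= 3 points")
    if np.ptp(measured) == 0:
        raise ValueError("measured volumes have zero variance")
    fit = stats.linregress(measured, calculated)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
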