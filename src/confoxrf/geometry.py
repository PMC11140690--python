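"""Voxelized sample model: CT segmentation, registration, ray path lengths.

The sample structure comes from a segmented micro-CT volume registered to
the XRF scan grid.  Absorption correction needs, for every voxel, the exact
per-material path lengths of the excitation ray (upstream, to the source)
and the detection ray (to the detector).  Rays are traversed with an
incremental face-crossing (Amanatides-Woo style) walk; the starting voxel
contributes the chord from its *center* to its exit face, because the
probing volume is modeled as centered in the voxel.

Axis convention: arrays are indexed ``(x, y, z)``; ``z`` increases with
depth into the sample, the surface being the ``z = 0`` face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.feature import match_template
from skimage.filters import threshold_multiotsu

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "BeamGeometry",
    "PathSegments",
    "segment_ct",
    "register_template",
    "trace_path",
    "resample_bicubic",
    "default_geometry",
    "read_ct_volume",
    "write_label_volume",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid; pitches in um; voxel i spans [i, i+1)*pitch + origin."""

    shape: tuple[int, int, int]
    pitch_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")
        if len(self.pitch_um) != 3 or any(p <= 0 for p in self.pitch_um):
            raise ValueError("pitches must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "pitch_um", tuple(float(p) for p in self.pitch_um))
        object.__setattr__(self, "origin_um", tuple(float(o) for o in self.origin_um))

    @classmethod
    def isotropic(cls, shape, pitch_um: float, origin_um=(0.0, 0.0, 0.0)) -> "VoxelGrid":
        return cls(tuple(shape), (pitch_um,) * 3, tuple(origin_um))

    def voxel_center(self, index) -> np.ndarray:
        i = np.asarray(index, dtype=float)
        return (i + 0.5) * np.asarray(self.pitch_um) + np.asarray(self.origin_um)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * p for n, p in zip(self.shape, self.pitch_um))


@dataclass(frozen=True)
class LabelVolume:
    """Material-ID mask on a voxel grid; label 0 is void/air."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {lab.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integers")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def material_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass(frozen=True)
class BeamGeometry:
    """Excitation and detection directions of the confocal bench.

    ``excitation_dir`` points along the propagation of the incoming beam
    (into the sample); ``detection_dir`` points from the emitting voxel
    toward the detector (out of the sample).  Both are normalized on
    construction and must be non-parallel.
    """

    excitation_dir: tuple[float, float, float]
    detection_dir: tuple[float, float, float]

    def __post_init__(self) -> None:
        e = _normalize(self.excitation_dir)
        d = _normalize(self.detection_dir)
        if abs(float(np.dot(e, d))) > 1.0 - 1e-9:
            raise ValueError("excitation and detection directions are parallel")
        object.__setattr__(self, "excitation_dir", tuple(e))
        object.__setattr__(self, "detection_dir", tuple(d))

    @property
    def detection_angle_deg(self) -> float:
        """Angle alpha between the detection axis and the sample surface."""
        dz = abs(self.detection_dir[2])
        return float(np.degrees(np.arcsin(min(dz, 1.0))))

    def mirrored_x(self) -> "BeamGeometry":
        ex, ey, ez = self.excitation_dir
        dx, dy, dz = self.detection_dir
        return BeamGeometry((-ex, ey, ez), (-dx, dy, dz))


def _normalize(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n == 0.0:
        raise ValueError("zero direction vector")
    return a / n


def default_geometry() -> BeamGeometry:
    """Both beams in the xz plane at 45 deg to the surface, opposite sides."""
    s = np.sqrt(0.5)
    return BeamGeometry(excitation_dir=(s, 0.0, s), detection_dir=(s, 0.0, -s))


@dataclass(frozen=True)
class PathSegments:
    """Per-material chord lengths of one traced ray."""

    lengths_um: Mapping[int, float]     # material label -> path length, um
    voxel_counts: Mapping[int, int]     # material label -> traversed voxels
    total_um: float

    def __post_init__(self) -> None:
        s = sum(self.lengths_um.values())
        if self.total_um > 0 and abs(s - self.total_um) > 1e-9 * max(self.total_um, 1.0):
            raise ValueError("per-material lengths do not sum to the total")

    def length(self, label: int) -> float:
        return float(self.lengths_um.get(label, 0.0))


# ---------------------------------------------------------------------------
# Segmentation and registration
# ---------------------------------------------------------------------------

def segment_ct(
    gray_volume: np.ndarray,
    thresholds: Sequence[float] | str = "auto",
    n_classes: int = 2,
) -> np.ndarray:
    """Threshold a grayscale CT volume into material classes.

    With explicit ``thresholds`` (strictly increasing), K thresholds yield
    K+1 classes, class 0 being void.  With ``thresholds="auto"`` the
    thresholds are chosen by multi-class Otsu on the gray histogram.
    """
    gray = np.asarray(gray_volume)
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError("thresholds must be a sequence or 'auto'")
        if np.ptp(gray) == 0:
            raise ValueError("constant volume: no separable gray classes")
        thr = threshold_multiotsu(gray, classes=n_classes)
    else:
        thr = np.asarray(thresholds, dtype=float)
        if thr.ndim != 1 or thr.size == 0:
            raise ValueError("need at least one threshold")
        if np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly increasing")
    return np.digitize(gray, thr).astype(np.uint8)


def register_template(
    reference_map: np.ndarray, moving_map: np.ndarray
) -> tuple[tuple[int, ...], float]:
    """Integer-voxel offset of ``moving_map`` inside ``reference_map``.

    Maximizes normalized cross-correlation over integer shifts; returns the
    offset of the moving map's corner within the reference and the NCC score
    in [-1, 1].  Sub-voxel refinement is deliberately not attempted.
    """
    ref = np.asarray(reference_map, dtype=float)
    mov = np.asarray(moving_map, dtype=float)
    if any(m > r for m, r in zip(mov.shape, ref.shape)):
        raise ValueError("moving map must fit inside the reference map")
    if float(np.std(mov)) == 0.0:
        raise ValueError("degenerate template: zero variance")
    ncc = match_template(ref, mov)
    idx = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    return tuple(int(i) for i in idx), float(ncc[idx])


# ---------------------------------------------------------------------------
# Ray traversal
# ---------------------------------------------------------------------------

def trace_path(
    labels: LabelVolume,
    start_voxel: Sequence[int],
    direction: Sequence[float],
) -> PathSegments:
    """Exact ray/voxel traversal from a voxel center to the grid boundary.

    Incremental face-crossing walk: at each step the chord between
    consecutive face crossings is attributed to the current voxel's
    material.  The start voxel contributes its chord from the voxel center
    to its exit face.  Boundary ties (corner hits) advance all tied axes at
    once, consistent with half-open voxel intervals.
    """
    d = _normalize(direction)
    grid = labels.grid
    shape = np.asarray(grid.shape)
    idx = np.asarray(start_voxel, dtype=int).copy()
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError(f"start voxel {tuple(idx)} outside grid {grid.shape}")

    pitch = np.asarray(grid.pitch_um)
    step = np.where(d > 0, 1, np.where(d < 0, -1, 0))
    with np.errstate(divide="ignore"):
        t_delta = np.where(d != 0, pitch / np.abs(d), np.inf)
        # parametric distance from the voxel center to the first face crossing
        t_max = np.where(d != 0, 0.5 * pitch / np.abs(d), np.inf)

    lengths: dict[int, float] = {}
    counts: dict[int, int] = {}
    t = 0.0
    lab_arr = labels.labels
    while True:
        lab = int(lab_arr[idx[0], idx[1], idx[2]])
        t_next = float(t_max.min())
        chord = t_next - t
        lengths[lab] = lengths.get(lab, 0.0) + chord
        counts[lab] = counts.get(lab, 0) + 1
        # advance every axis whose crossing coincides with t_next
        advance = t_max <= t_next + 1e-12 * max(t_next, 1.0)
        idx = idx + np.where(advance, step, 0)
        t_max = t_max + np.where(advance, t_delta, 0.0)
        t = t_next
        if np.any(idx < 0) or np.any(idx >= shape):
            break
    return PathSegments(lengths_um=lengths, voxel_counts=counts, total_um=t)


# ---------------------------------------------------------------------------
# Grid resampling
# ---------------------------------------------------------------------------

def resample_bicubic(
    values: np.ndarray,
    source_pitch_um: Sequence[float] | float,
    target_pitch_um: Sequence[float] | float,
) -> np.ndarray:
    """Bicubic (order-3 spline) resampling of a map onto a new pitch.

    Used to bring coarse XRF scan grids onto the micro-CT voxel size.  The
    output grid covers the same physical extent (cell-centered samples);
    constant maps stay constant.
    """
    arr = np.asarray(values, dtype=float)
    src = np.broadcast_to(np.asarray(source_pitch_um, dtype=float), (arr.ndim,))
    tgt = np.broadcast_to(np.asarray(target_pitch_um, dtype=float), (arr.ndim,))
    if np.any(src <= 0) or np.any(tgt <= 0):
        raise ValueError("pitches must be positive")
    out_shape = tuple(
        max(1, int(round(n * f))) for n, f in zip(arr.shape, src / tgt)
    )
    # Odd-reflection padding continues linear trends exactly across the
    # border, so spline-prefilter boundary effects stay out of the data.
    pads = tuple(min(12, n - 1) for n in arr.shape)
    padded = arr
    for ax, p in enumerate(pads):
        if p > 0:
            width = [(0, 0)] * arr.ndim
            width[ax] = (p, p)
            padded = np.pad(padded, width, mode="reflect", reflect_type="odd")
    axes_coords = [
        ((np.arange(m) + 0.5) * t) / s - 0.5 + p
        for m, t, s, p in zip(out_shape, tgt, src, pads)
    ]
    mesh = np.meshgrid(*axes_coords, indexing="ij")
    out = ndimage.map_coordinates(
        padded, np.stack(mesh), order=3, mode="mirror"
    )
    return out.reshape(out_shape)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_ct_volume(path: str | Path, pitch_um: float | Sequence[float]) -> tuple[np.ndarray, VoxelGrid]:
    """Read a CT volume from a multi-page TIFF or a directory of TIFF slices.

    TIFF pages are depth slices (z); the returned array is re-ordered to the
    package's (x, y, z) axis convention.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.tif")) + sorted(p.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices in {p}")
        vol = np.stack([tifffile.imread(f) for f in files], axis=0)
    else:
        vol = tifffile.imread(p)
    if vol.ndim == 2:
        vol = vol[None]
    # pages are (z, y, x) -> (x, y, z)
    vol = np.transpose(vol, (2, 1, 0))
    pitch = np.broadcast_to(np.asarray(pitch_um, dtype=float), (3,))
    grid = VoxelGrid(vol.shape, tuple(pitch))
    return vol, grid


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Save a label mask as an unsigned-8-bit multi-page TIFF (z pages)."""
    lab = np.transpose(volume.labels.astype(np.uint8), (2, 1, 0))
    tifffile.imwrite(path, lab, photometric="minisblack")
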