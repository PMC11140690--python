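"""Energy-dependent probing-volume model and Gaussian weighting kernels.

The confocal probing volume is formed by the overlapping foci of the
excitation and detection polycapillary optics; its size shrinks with
fluorescence energy (total-reflection focusing).  Its lateral profile is
modeled as a Gaussian whose FWHM follows a two-parameter exponential decay

    FWHM(E) = A * exp(-k * E),

calibrated from depth scans of thin metal foils.  For each fluorescence
line the correction term is spatially mixed with a circular kernel of
radius 2*sigma: positive Gaussian weights at the voxel centers inside the
radius, renormalized to sum to one, with no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import OptimizeWarning, curve_fit

from .xsections import FWHM_PER_SIGMA

__all__ = [
    "PVCalibrationPoint",
    "PVModel",
    "Kernel",
    "fwhm_from_scan",
    "fit_pv_model",
    "kernel_for_line",
    "span_in_voxels",
    "identity_kernel",
    "pv_model_from_yaml",
    "pv_model_to_yaml",
    "calibration_points_from_csv",
]


@dataclass(frozen=True)
class PVCalibrationPoint:
    """One foil measurement: fluorescence line energy and probing-volume FWHM."""

    energy_keV: float
    fwhm_um: float
    element: str = ""

    def __post_init__(self) -> None:
        if self.energy_keV <= 0 or self.fwhm_um <= 0:
            raise ValueError("energy and FWHM must be positive")


@dataclass(frozen=True)
class PVModel:
    """FWHM(E) = A * exp(-k E); A in um, k in 1/keV (k >= 0)."""

    amplitude_um: float
    decay_per_keV: float
    points: tuple[PVCalibrationPoint, ...] = ()

    def __post_init__(self) -> None:
        if self.amplitude_um <= 0:
            raise ValueError("amplitude must be positive")
        if self.decay_per_keV < 0:
            raise ValueError(
                "negative decay: probing volume cannot grow with energy"
            )

    def fwhm(self, energy_keV) -> np.ndarray | float:
        e = np.asarray(energy_keV, dtype=float)
        out = self.amplitude_um * np.exp(-self.decay_per_keV * e)
        return out if e.ndim else float(out)

    def sigma(self, energy_keV) -> np.ndarray | float:
        f = self.fwhm(energy_keV)
        return f / FWHM_PER_SIGMA


@dataclass(frozen=True)
class Kernel:
    """Discrete circular Gaussian weighting kernel on the voxel grid.

    ``offsets`` are integer voxel offsets (n, ndim) whose centers lie within
    the 2*sigma radius; ``weights`` are the matching normalized Gaussian
    weights.  ``ndim`` is 2 for in-scan-plane (xz) smoothing, 3 for the
    spherical variant used on volume scans.
    """

    offsets: np.ndarray
    weights: np.ndarray
    sigma_um: float
    pitch_um: float
    ndim: int = 2

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=int)
        w = np.asarray(self.weights, dtype=float)
        if off.ndim != 2 or off.shape[0] != w.size or off.shape[1] != self.ndim:
            raise ValueError("offsets/weights shape mismatch")
        if np.any(w <= 0):
            raise ValueError("kernel weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "weights", w)

    @property
    def span(self) -> int:
        """Kernel diameter along an axis, in voxels (odd)."""
        if self.offsets.size == 0:
            return 1
        return int(2 * np.max(np.abs(self.offsets)) + 1)

    @property
    def is_identity(self) -> bool:
        return self.offsets.shape[0] == 1

    def to_array(self) -> np.ndarray:
        """Dense weight array of shape (span,)*ndim (zeros outside the circle)."""
        half = self.span // 2
        arr = np.zeros((self.span,) * self.ndim)
        for off, w in zip(self.offsets, self.weights):
            arr[tuple(int(o) + half for o in off)] = w
        return arr


def identity_kernel(pitch_um: float, ndim: int = 2) -> Kernel:
    return Kernel(
        offsets=np.zeros((1, ndim), dtype=int),
        weights=np.ones(1),
        sigma_um=0.0,
        pitch_um=pitch_um,
        ndim=ndim,
    )


def fwhm_from_scan(positions_um, intensities) -> float:
    """FWHM of a foil depth scan by least-squares Gaussian fit.

    The profile must contain a single dominant peak; a flat or
    non-convergent profile is rejected with diagnostics.
    """
    x = np.asarray(positions_um, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matching arrays with >= 4 samples")
    span = float(np.ptp(y))
    if span <= 0 or span < 1e-6 * max(abs(float(np.max(y))), 1.0):
        raise ValueError("flat profile: no peak to fit")

    def gauss(x, a, x0, sigma, b):
        return a * np.exp(-0.5 * ((x - x0) / sigma) ** 2) + b

    b0 = float(np.min(y))
    a0 = float(np.max(y)) - b0
    w = np.clip(y - b0, 0, None)
    x0 = float(np.sum(x * w) / np.sum(w))
    s0 = float(np.sqrt(np.sum(w * (x - x0) ** 2) / np.sum(w))) or float(np.ptp(x)) / 4
    try:
        with warnings.catch_warnings():
            # noiseless profiles fit exactly; the singular covariance is fine
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(gauss, x, y, p0=[a0, x0, s0, b0], maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"Gaussian fit did not converge: {err}") from err
    a, _, sigma, _ = popt
    if a <= 0 or not np.isfinite(sigma):
        raise ValueError(
            f"Gaussian fit degenerate (amplitude={a:.3g}, sigma={sigma:.3g})"
        )
    return float(FWHM_PER_SIGMA * abs(sigma))


def fit_pv_model(points: Sequence[PVCalibrationPoint]) -> PVModel:
    """Fit FWHM(E) = A exp(-kE) to foil calibration points.

    Two points: closed form (reproduced exactly).  More: least squares on
    log-FWHM.  Duplicate energies with conflicting FWHM are rejected.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least two calibration points")
    by_e: dict[float, float] = {}
    for p in pts:
        if p.energy_keV in by_e and not np.isclose(by_e[p.energy_keV], p.fwhm_um):
            raise ValueError(
                f"conflicting FWHM at {p.energy_keV} keV: "
                f"{by_e[p.energy_keV]} vs {p.fwhm_um} um"
            )
        by_e[p.energy_keV] = p.fwhm_um
    e = np.array(sorted(by_e))
    f = np.array([by_e[v] for v in e])
    if e.size < 2:
        raise ValueError("need at least two distinct energies")
    if e.size == 2:
        k = float(np.log(f[0] / f[1]) / (e[1] - e[0]))
        a = float(f[0] * np.exp(k * e[0]))
    else:
        slope, intercept = np.polyfit(e, np.log(f), 1)
        k, a = float(-slope), float(np.exp(intercept))
    if abs(k) < 1e-15:
        k = 0.0
    return PVModel(amplitude_um=a, decay_per_keV=k, points=tuple(pts))


def span_in_voxels(fwhm_um: float, pitch_um: float) -> int:
    """Diameter of the 2*sigma support along an axis, in voxels (odd)."""
    if fwhm_um <= 0 or pitch_um <= 0:
        raise ValueError("FWHM and pitch must be positive")
    sigma = fwhm_um / FWHM_PER_SIGMA
    return int(2 * np.floor(2.0 * sigma / pitch_um) + 1)


def kernel_for_line(
    model: PVModel, line_energy_keV: float, pitch_um: float, ndim: int = 2
) -> Kernel:
    """Gaussian weighting kernel for one fluorescence line.

    sigma = FWHM(E) / (2 sqrt(2 ln 2)); support = voxels whose center lies
    within 2*sigma of the center voxel; weights renormalized over the
    clipped support.  If the support does not reach beyond the center voxel
    the identity kernel is returned (point probing volume).
    """
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    sigma = float(model.sigma(line_energy_keV))
    radius = 2.0 * sigma
    if radius < pitch_um / 2.0 or sigma == 0.0:
        return identity_kernel(pitch_um, ndim=ndim)
    half = int(np.floor(radius / pitch_um))
    rng = np.arange(-half, half + 1)
    grids = np.meshgrid(*([rng] * ndim), indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.sqrt(np.sum((offsets * pitch_um) ** 2, axis=1))
    inside = dist <= radius + 1e-9
    offsets = offsets[inside]
    w = np.exp(-0.5 * (dist[inside] / sigma) ** 2)
    w = w / w.sum()
    return Kernel(
        offsets=offsets, weights=w, sigma_um=sigma, pitch_um=pitch_um, ndim=ndim
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def pv_model_to_yaml(model: PVModel, path: str | Path) -> None:
    doc = {
        "amplitude_um": float(model.amplitude_um),
        "decay_per_keV": float(model.decay_per_keV),
        "points": [
            {"energy_keV": p.energy_keV, "fwhm_um": p.fwhm_um, "element": p.element}
            for p in model.points
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def pv_model_from_yaml(path: str | Path) -> PVModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pts = tuple(
        PVCalibrationPoint(p["energy_keV"], p["fwhm_um"], p.get("element", ""))
        for p in doc.get("points", [])
    )
    return PVModel(doc["amplitude_um"], doc["decay_per_keV"], pts)


def calibration_points_from_csv(path: str | Path) -> list[PVCalibrationPoint]:
    """Read calibration points from CSV ``element,line,energy_keV,fwhm_um``."""
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        PVCalibrationPoint(
            float(r["energy_keV"]), float(r["fwhm_um"]), r.get("element", "")
        )
        for r in rows
    ]
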