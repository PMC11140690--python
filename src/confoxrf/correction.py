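"""Voxel-wise absorption correction of confocal micro-XRF intensity maps.

For every voxel and fluorescence line j the correction term

    K_j(x, y, z) = mu*l_exc(x, y, z)  +  sum_i mu_i(E_j) * L_i(x, y, z)

adds the effective optical depth of the excitation path (polychromatic,
spectrally weighted by the source spectrum times the photoabsorption of the
fluorescing element above its edge) and of the detection path (linear
combination of the per-material attenuation at the line energy times the
per-material path lengths to the surface).  The corrected intensity is

    I_corr,j = I_meas,j * exp(K~_j),

where K~ is K mixed over the energy-dependent probing volume by a circular
Gaussian kernel.  K is the non-negative total optical depth, so corrected
intensities never fall below measured ones.

Voxels whose counting statistics are too poor (relative Poisson error of the
net-peak counts >= 10% by default) are flagged invalid rather than
corrected; exports write NaN for them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import ndimage

from . import xsections
from .geometry import BeamGeometry, LabelVolume, VoxelGrid, trace_path
from .materials import AttenuationTable
from .probing_volume import Kernel
from .xsections import CrossSectionSource, FluorescenceLine

__all__ = [
    "FluorescenceLine",
    "Spectrum",
    "monochromatic",
    "IntensityMap",
    "ExcitationProfile",
    "CorrectionField",
    "excitation_term",
    "excitation_profile_along_ray",
    "detection_term",
    "correction_field",
    "smooth_field",
    "apply_correction",
    "counting_mask",
    "roi_mean",
    "orientation_deviation",
    "save_maps",
    "load_maps",
]


@dataclass(frozen=True)
class Spectrum:
    """Excitation spectrum on an energy grid (keV).

    ``weights`` are a spectral photon density (integrated with trapezoidal
    measure) unless ``discrete`` is set, in which case each entry is the
    intensity of an individual line (e.g. monochromatic or few-line
    excitation) and no energy measure is applied.
    """

    energies_keV: np.ndarray
    weights: np.ndarray
    discrete: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape:
            raise ValueError("need matching 1-D energy and weight arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("spectral weights must be non-negative")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "weights", w)

    @property
    def is_monochromatic(self) -> bool:
        return int(np.count_nonzero(self.weights)) == 1


def monochromatic(energy_keV: float) -> Spectrum:
    """Single-energy excitation (delta line represented on a 2-point grid)."""
    return Spectrum(
        np.array([energy_keV, energy_keV * (1 + 1e-9)]),
        np.array([1.0, 0.0]),
        discrete=True,
    )


@dataclass(frozen=True)
class IntensityMap:
    """Per-line voxel map of net-peak intensity in cps (plus raw counts)."""

    line: FluorescenceLine
    grid: VoxelGrid
    values: np.ndarray                 # cps
    counts: np.ndarray | None = None   # raw integer counts
    livetime_s: float | None = None
    valid: np.ndarray | None = None    # boolean mask; None = all valid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("values shape does not match the grid")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "values", v)
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.shape != v.shape or np.any(c < 0):
                raise ValueError("counts must be non-negative and match the grid")
            object.__setattr__(self, "counts", c)
            if self.livetime_s is not None and self.livetime_s > 0:
                expect = c / self.livetime_s
                check = (
                    np.ones(v.shape, dtype=bool) if self.valid is None
                    else np.asarray(self.valid, bool)
                )
                if not np.allclose(v[check], expect[check], rtol=1e-6, atol=1e-9):
                    raise ValueError(
                        "values must equal counts / livetime on valid voxels"
                    )
        if self.valid is not None:
            m = np.asarray(self.valid, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("valid mask shape does not match the grid")
            object.__setattr__(self, "valid", m)

    def masked_values(self) -> np.ndarray:
        """Values with invalid voxels as NaN (export convention)."""
        if self.valid is None:
            return self.values.copy()
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


@dataclass(frozen=True)
class ExcitationProfile:
    """Spectral weights along one excitation ray and the resulting mu*l.

    ``weights`` has shape (n_depth, n_energy): the depth-attenuated source
    spectrum restricted to energies above the line's edge, already weighted
    by the fluorescing element's photoabsorption.
    """

    energies_keV: np.ndarray
    weights: np.ndarray
    mul_exc: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("spectral weights must be non-negative")


@dataclass(frozen=True)
class CorrectionField:
    """Per-line voxel map of the correction exponent K (dimensionless)."""

    line: FluorescenceLine
    grid: VoxelGrid
    K: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.K, dtype=float)
        if k.shape != self.grid.shape:
            raise ValueError("K shape does not match the grid")
        if np.any(k < -1e-12):
            raise ValueError("correction term must be non-negative")
        object.__setattr__(self, "K", np.clip(k, 0.0, None))


# ---------------------------------------------------------------------------
# Excitation and detection exponents
# ---------------------------------------------------------------------------

def _line_photo_weights(
    spectrum: Spectrum, line: FluorescenceLine, source: CrossSectionSource | None
):
    """(energies, S0*tau integration weights) above the line's edge.

    The spectral average is treated as an energy integral: a node is
    inserted at the absorption edge (linear interpolation of the source
    spectrum) and trapezoidal measures are folded into the weights, so the
    result is stable against the working grid.  Discrete (monochromatic)
    spectra keep their plain line weights."""
    above = spectrum.energies_keV > line.edge_keV
    if not np.any(above) or float(np.sum(spectrum.weights[above])) <= 0.0:
        raise ValueError(
            f"no spectral weight above the {line.element} {line.name} edge "
            f"({line.edge_keV} keV): line cannot be excited"
        )
    e = spectrum.energies_keV[above]
    w = spectrum.weights[above]
    if not spectrum.discrete and e.size > 1:
        lo = spectrum.energies_keV[0]
        if e[0] > line.edge_keV * (1 + 1e-12) and line.edge_keV >= lo:
            edge = line.edge_keV * (1 + 1e-9)
            w_edge = float(np.interp(edge, spectrum.energies_keV, spectrum.weights))
            e = np.concatenate([[edge], e])
            w = np.concatenate([[w_edge], w])
        # trapezoidal measure on the clipped grid
        de = np.diff(e)
        measure = np.zeros_like(e)
        measure[:-1] += de / 2.0
        measure[1:] += de / 2.0
        w = w * measure
    tau = np.asarray(xsections.photoabsorption(line.element, e, source=source))
    return e, w * tau


def _material_mu_matrix(
    atten: Mapping[int, AttenuationTable], energies: np.ndarray
) -> dict[int, np.ndarray]:
    return {lab: np.asarray(tab(energies)) for lab, tab in atten.items()}


def excitation_term(
    spectrum: Spectrum,
    labels: LabelVolume,
    atten: Mapping[int, AttenuationTable],
    geom: BeamGeometry,
    line: FluorescenceLine,
    source: CrossSectionSource | None = None,
) -> np.ndarray:
    """Per-voxel effective optical depth mu*l of the excitation path.

    For each voxel the upstream path (against the excitation direction) is
    traced through the label volume; the depth-attenuated spectrum is

        S_depth(E) = S0(E) * exp(-sum_m mu_m(E) * l_m),

    and the effective exponent is the spectrally weighted average over the
    energies that can excite the line,

        mu*l = -ln [ sum S_depth tau_el / sum S0 tau_el ],

    with tau_el the photoabsorption of the fluorescing element.  For a
    monochromatic spectrum this reduces exactly to mu(E0) * l.
    """
    e, w0 = _line_photo_weights(spectrum, line, source)
    denom = float(np.sum(w0))
    mu_of = _material_mu_matrix(atten, e)
    upstream = tuple(-c for c in geom.excitation_dir)
    out = np.zeros(labels.grid.shape)
    path_cache: dict[tuple[tuple[int, float], ...], float] = {}
    for idx in np.ndindex(labels.grid.shape):
        seg = trace_path(labels, idx, upstream)
        key = tuple(sorted((lab, round(l, 9)) for lab, l in seg.lengths_um.items() if lab != 0))
        if key in path_cache:
            out[idx] = path_cache[key]
            continue
        optical = np.zeros_like(e)
        for lab, length in seg.lengths_um.items():
            if lab != 0 and lab in mu_of:
                optical = optical + mu_of[lab] * length
        val = -np.log(np.sum(w0 * np.exp(-optical)) / denom)
        val = float(max(val, 0.0))
        path_cache[key] = val
        out[idx] = val
    return out


def excitation_profile_along_ray(
    spectrum: Spectrum,
    labels: LabelVolume,
    atten: Mapping[int, AttenuationTable],
    geom: BeamGeometry,
    line: FluorescenceLine,
    voxels: Sequence[Sequence[int]],
    source: CrossSectionSource | None = None,
) -> ExcitationProfile:
    """Depth-attenuated spectral weights and mu*l for a sequence of voxels."""
    e, w0 = _line_photo_weights(spectrum, line, source)
    denom = float(np.sum(w0))
    mu_of = _material_mu_matrix(atten, e)
    upstream = tuple(-c for c in geom.excitation_dir)
    weights = np.zeros((len(voxels), e.size))
    mul = np.zeros(len(voxels))
    for i, idx in enumerate(voxels):
        seg = trace_path(labels, tuple(idx), upstream)
        optical = np.zeros_like(e)
        for lab, length in seg.lengths_um.items():
            if lab != 0 and lab in mu_of:
                optical = optical + mu_of[lab] * length
        weights[i] = w0 * np.exp(-optical)
        mul[i] = max(-np.log(np.sum(weights[i]) / denom), 0.0)
    return ExcitationProfile(energies_keV=e, weights=weights, mul_exc=mul)


def detection_term(
    labels: LabelVolume,
    atten: Mapping[int, AttenuationTable],
    geom: BeamGeometry,
    line: FluorescenceLine,
    voxel: Sequence[int],
) -> float:
    """Optical depth of the detection path from one voxel to the surface:
    sum_i mu_i(E_j) * L_i with exact per-material chord lengths."""
    seg = trace_path(labels, tuple(voxel), geom.detection_dir)
    total = 0.0
    for lab, length in seg.lengths_um.items():
        if lab != 0 and lab in atten:
            total += float(atten[lab](line.energy_keV)) * length
    return total


def _detection_volume(
    labels: LabelVolume,
    atten: Mapping[int, AttenuationTable],
    geom: BeamGeometry,
    line: FluorescenceLine,
) -> np.ndarray:
    mu_at_line = {lab: float(tab(line.energy_keV)) for lab, tab in atten.items()}
    out = np.zeros(labels.grid.shape)
    cache: dict[tuple, float] = {}
    for idx in np.ndindex(labels.grid.shape):
        seg = trace_path(labels, idx, geom.detection_dir)
        key = tuple(sorted((lab, round(l, 9)) for lab, l in seg.lengths_um.items() if lab != 0))
        if key not in cache:
            cache[key] = sum(
                mu_at_line[lab] * length
                for lab, length in seg.lengths_um.items()
                if lab != 0 and lab in mu_at_line
            )
        out[idx] = cache[key]
    return out


def correction_field(
    labels: LabelVolume,
    atten: Mapping[int, AttenuationTable],
    geom: BeamGeometry,
    spectrum: Spectrum,
    line: FluorescenceLine,
    source: CrossSectionSource | None = None,
) -> CorrectionField:
    """Voxel-wise correction exponent K_j = mu*l_exc + detection term."""
    for lab in labels.material_ids:
        if lab not in atten:
            raise ValueError(f"no attenuation table for material label {lab}")
    exc = excitation_term(spectrum, labels, atten, geom, line, source=source)
    det = _detection_volume(labels, atten, geom, line)
    return CorrectionField(line=line, grid=labels.grid, K=exc + det)


# ---------------------------------------------------------------------------
# Probing-volume smoothing and application
# ---------------------------------------------------------------------------

def smooth_field(field: CorrectionField, kernel: Kernel) -> CorrectionField:
    """Mix K over the probing volume: weighted sum over the circular 2*sigma
    support around each voxel, weights renormalized where the support is
    clipped by the map border."""
    if kernel.is_identity:
        return field
    w = kernel.to_array()
    if kernel.ndim == 2:
        w3 = w[:, None, :]           # kernel acts in the xz scan plane
    elif kernel.ndim == 3:
        w3 = w
    else:
        raise ValueError("kernel must be 2-D or 3-D")
    num = ndimage.convolve(field.K, w3, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(field.K), w3, mode="constant", cval=0.0)
    return replace(field, K=num / den)


def apply_correction(
    meas: IntensityMap,
    field: CorrectionField,
    mask: np.ndarray | None = None,
) -> IntensityMap:
    """I_corr = I_meas * exp(K~) on masked-in voxels.

    Masked-out voxels keep their measured values and are flagged invalid
    (exports replace them with NaN); they are never zeroed.
    """
    if meas.grid != field.grid:
        raise ValueError("intensity map and correction field grids differ")
    valid = np.ones(meas.grid.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if valid.shape != meas.grid.shape:
        raise ValueError("mask shape does not match the grid")
    corr = meas.values.copy()
    corr[valid] = meas.values[valid] * np.exp(field.K[valid])
    return replace(meas, values=corr, counts=None, livetime_s=None, valid=valid)


def counting_mask(meas: IntensityMap, max_rel_err: float = 0.10) -> np.ndarray:
    """Voxels whose Poisson counting error 1/sqrt(N) is strictly below the
    cutoff (default 10%, i.e. N > 100)."""
    if meas.counts is None:
        raise ValueError("counting mask requires raw counts")
    if not 0 < max_rel_err < 1:
        raise ValueError("max_rel_err must be in (0, 1)")
    n = np.asarray(meas.counts, dtype=float)
    with np.errstate(divide="ignore"):
        rel = np.where(n > 0, 1.0 / np.sqrt(np.clip(n, 1e-300, None)), np.inf)
    return rel < max_rel_err


def roi_mean(
    meas: IntensityMap,
    roi: tuple[slice, ...],
    mask: np.ndarray | None = None,
) -> float:
    """Arithmetic mean of the valid voxels inside a rectangular ROI."""
    if len(roi) != 3:
        raise ValueError("ROI must be three slices (x, y, z)")
    sub = meas.values[roi]
    if sub.size == 0:
        raise ValueError("ROI lies outside the grid")
    keep = np.ones_like(sub, dtype=bool)
    if meas.valid is not None:
        keep &= meas.valid[roi]
    if mask is not None:
        keep &= np.asarray(mask, bool)[roi]
    if not np.any(keep):
        raise ValueError("no valid voxels inside the ROI")
    return float(np.mean(sub[keep]))


def orientation_deviation(mean_a: float, mean_b: float) -> float:
    """Relative deviation of two ROI means, percent: 100 |a-b| / (a+b)."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    s = mean_a + mean_b
    if s == 0:
        raise ValueError("both means are zero")
    return 100.0 * abs(mean_a - mean_b) / s


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def save_maps(
    path: str | Path,
    maps: Mapping[str, IntensityMap],
    labels: LabelVolume | None = None,
    suffix: str = "",
) -> None:
    """Write intensity maps to HDF5: one group per line under /lines.

    Datasets ``values`` (NaN for invalid voxels) and optional ``counts``;
    attributes carry line energy, livetime and pitch.
    """
    with h5py.File(path, "a") as fh:
        root = fh.require_group("lines" + suffix)
        for key, m in maps.items():
            if key in root:
                del root[key]
            g = root.create_group(key)
            g.create_dataset("values", data=m.masked_values())
            if m.counts is not None:
                g.create_dataset("counts", data=m.counts)
            g.attrs["element"] = m.line.element
            g.attrs["line"] = m.line.name
            g.attrs["energy_keV"] = m.line.energy_keV
            g.attrs["edge_keV"] = m.line.edge_keV
            g.attrs["pitch_um"] = m.grid.pitch_um
            if m.livetime_s is not None:
                g.attrs["livetime_s"] = m.livetime_s
        if labels is not None:
            if "labels" in fh:
                del fh["labels"]
            d = fh.create_dataset("labels", data=labels.labels.astype(np.uint8))
            d.attrs["pitch_um"] = labels.grid.pitch_um


def load_maps(path: str | Path, suffix: str = "") -> tuple[dict[str, IntensityMap], LabelVolume | None]:
    """Read intensity maps (and the label volume, if present) from HDF5."""
    out: dict[str, IntensityMap] = {}
    with h5py.File(path, "r") as fh:
        root = fh["lines" + suffix]
        for key, g in root.items():
            values = np.asarray(g["values"])
            valid = None
            if np.any(np.isnan(values)):
                valid = ~np.isnan(values)
                values = np.where(valid, values, 0.0)
            pitch = tuple(float(p) for p in g.attrs["pitch_um"])
            grid = VoxelGrid(values.shape, pitch)
            fluor = FluorescenceLine(
                element=str(g.attrs["element"]),
                name=str(g.attrs["line"]),
                energy_keV=float(g.attrs["energy_keV"]),
                edge_keV=float(g.attrs["edge_keV"]),
            )
            counts = np.asarray(g["counts"]) if "counts" in g else None
            livetime = float(g.attrs["livetime_s"]) if "livetime_s" in g.attrs else None
            out[key] = IntensityMap(
                line=fluor, grid=grid, values=values, counts=counts,
                livetime_s=livetime, valid=valid,
            )
        labels = None
        if "labels" in fh:
            lab = np.asarray(fh["labels"])
            pitch = tuple(float(p) for p in fh["labels"].attrs["pitch_um"])
            labels = LabelVolume(VoxelGrid(lab.shape, pitch), lab.astype(np.int64))
    return out, labels
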