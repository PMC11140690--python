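"""Synthetic phantoms, tube spectra and forward-simulated confocal scans.

The forward model is the exact inverse of the voxel-wise correction:
expected counts are the zero-absorption emission rate attenuated by
exp(-K~) over the live time, with optional Poisson counting noise.  Three
phantom scenes mirror the measurement situations of a composite sample:

* ``interface``        - a plane interface between two materials (A1-style),
* ``overlap_with_gap`` - one material partially overlapping the other with a
                         void gap beneath the overlap (A2-style),
* ``inclusion``        - a dense ellipsoidal micro-inclusion inside one
                         material (A3-style).

Default grids use a 6 um pitch, matching the fine scan step at which a
47 um FWHM probing volume spans 13 voxels.  Emission truth is specified
directly as cps at zero absorption, which decouples the simulator from
fundamental-parameter physics; Sherman-based truth can be computed with
:mod:`confoxrf.sherman` when absolute scales are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .correction import CorrectionField, IntensityMap, Spectrum
from .geometry import BeamGeometry, LabelVolume, VoxelGrid
from .materials import Material, bovine_dentine, sdr_flow_plus
from .probing_volume import Kernel
from .xsections import FluorescenceLine, K_EDGES, line as lookup_line
from . import xsections

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "Phantom",
    "tube_spectrum",
    "make_phantom",
    "forward_measure",
    "rotate_180",
    "default_phantom_spec",
]

#: densities (g/cm^3) of common tube filter foils
_FILTER_DENSITY = {"Al": 2.70, "Cu": 8.96, "Mo": 10.22, "Zr": 6.52, "Ti": 4.51}

#: anode characteristic lines: (Ka keV, Kb keV); K edge from the shared table
_ANODE_LINES = {"Mo": (17.479, 19.608), "Cu": (8.048, 8.905), "W": None}


@dataclass(frozen=True)
class TubeSpec:
    """X-ray tube model: anode, accelerating voltage, optional filter."""

    anode: str = "Mo"
    kv: float = 30.0
    filter_element: str | None = None
    filter_thickness_um: float = 0.0
    step_keV: float = 0.1

    def __post_init__(self) -> None:
        if self.kv < 1.0:
            raise ValueError("tube voltage below 1 kV is not supported")
        if self.step_keV <= 0:
            raise ValueError("energy grid step must be positive")


def tube_spectrum(spec: TubeSpec, source=None) -> Spectrum:
    """Kramers continuum plus Gaussian characteristic anode lines.

    Photon-number continuum N(E) proportional to (E_max/E - 1), zero above
    the Duane-Hunt limit E_max = kV.  If the tube voltage exceeds the anode
    K edge, Ka and Kb lines are added as narrow Gaussians whose integrated
    intensity scales with the overvoltage as (U - 1)^1.67 relative to the
    continuum.  An optional filter foil attenuates the spectrum.  The result
    is normalized to unit integral.
    """
    e = np.arange(1.0, spec.kv + spec.step_keV / 2, spec.step_keV)
    if e.size < 2:
        raise ValueError("energy grid too coarse for the tube voltage")
    w = np.clip(spec.kv / e - 1.0, 0.0, None)

    k_edge = K_EDGES.get(spec.anode)
    lines = _ANODE_LINES.get(spec.anode)
    if k_edge is not None and lines is not None and spec.kv > k_edge:
        overvoltage = spec.kv / k_edge
        continuum_area = float(np.trapezoid(w, e))
        strength = continuum_area * (overvoltage - 1.0) ** 1.67
        sigma = 0.15  # keV, nominal detector-free line width
        for energy, frac in zip(lines, (0.35, 0.07)):
            w = w + (
                strength * frac / (sigma * np.sqrt(2 * np.pi))
            ) * np.exp(-0.5 * ((e - energy) / sigma) ** 2)

    if spec.filter_element is not None and spec.filter_thickness_um > 0:
        src = source or xsections.default_source()
        rho = _FILTER_DENSITY.get(spec.filter_element)
        if rho is None:
            raise ValueError(f"no bundled density for filter {spec.filter_element}")
        mu = rho * np.asarray(src.mass_attenuation(spec.filter_element, e)) * 1e-4
        w = w * np.exp(-mu * spec.filter_thickness_um)

    area = float(np.trapezoid(w, e))
    if area <= 0:
        raise ValueError("spectrum has no intensity")
    return Spectrum(e, w / area)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic scene definition.

    ``emission_cps`` maps a line label (e.g. ``"Ca_Ka"``) to the true
    zero-absorption emission rate (cps) per material label.  Geometry fields
    are interpreted per scene kind; lengths in um.
    """

    kind: str                                    # interface | overlap_with_gap | inclusion
    grid: VoxelGrid
    materials: Mapping[int, Material]
    emission_cps: Mapping[str, Mapping[int, float]]
    interface_frac: float = 0.5                  # x position of the interface
    overlap_depth_um: float = 60.0               # overlap layer thickness (A2)
    gap_um: float = 18.0                         # void gap under the overlap (A2)
    inclusion_center_um: tuple[float, float, float] | None = None
    inclusion_semiaxes_um: tuple[float, float, float] = (150.0, 45.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("interface", "overlap_with_gap", "inclusion"):
            raise ValueError(f"unknown scene kind {self.kind!r}")
        for lbl, per_mat in self.emission_cps.items():
            if any(v < 0 for v in per_mat.values()):
                raise ValueError(f"negative emission rate for {lbl}")
        if self.kind == "inclusion":
            center = self.inclusion_center_um or tuple(
                0.5 * x for x in self.grid.extent_um
            )
            ext = self.grid.extent_um
            for c, a, e in zip(center, self.inclusion_semiaxes_um, ext):
                if c - a < 0 or c + a > e:
                    raise ValueError("inclusion must lie fully inside the grid")


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    labels: LabelVolume
    truth: dict[str, IntensityMap]


def _lines_for(spec: PhantomSpec) -> dict[str, FluorescenceLine]:
    out = {}
    for key in spec.emission_cps:
        element, name = key.split("_")
        out[key] = lookup_line(element, name)
    return out


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic label volume plus per-line true intensity maps.

    Truth is constant per material per line; void voxels (label 0) emit
    nothing.
    """
    nx, ny, nz = spec.grid.shape
    px, py, pz = spec.grid.pitch_um
    labels = np.zeros(spec.grid.shape, dtype=np.int64)

    if spec.kind == "interface":
        split = int(round(nx * spec.interface_frac))
        labels[:split] = 1
        labels[split:] = 2
    elif spec.kind == "overlap_with_gap":
        split = int(round(nx * spec.interface_frac))
        over = max(1, int(round(spec.overlap_depth_um / pz)))
        gap = max(1, int(round(spec.gap_um / pz)))
        width = max(1, int(round(nx * 0.2)))
        labels[:split] = 1
        labels[split:] = 2
        sl = slice(split, min(nx, split + width))
        labels[sl, :, :over] = 1                      # overlapping tongue
        labels[sl, :, over:over + gap] = 0            # void gap underneath
    else:  # inclusion
        labels[:] = 1
        center = np.asarray(
            spec.inclusion_center_um or tuple(0.5 * x for x in spec.grid.extent_um)
        )
        axes = np.asarray(spec.inclusion_semiaxes_um)
        ix = (np.arange(nx) + 0.5) * px
        iy = (np.arange(ny) + 0.5) * py
        iz = (np.arange(nz) + 0.5) * pz
        xx, yy, zz = np.meshgrid(ix, iy, iz, indexing="ij")
        r2 = (
            ((xx - center[0]) / axes[0]) ** 2
            + ((yy - center[1]) / axes[1]) ** 2
            + ((zz - center[2]) / axes[2]) ** 2
        )
        labels[r2 <= 1.0] = 2

    vol = LabelVolume(spec.grid, labels)
    lines = _lines_for(spec)
    truth: dict[str, IntensityMap] = {}
    for key, per_mat in spec.emission_cps.items():
        values = np.zeros(spec.grid.shape)
        for mat_label, cps in per_mat.items():
            values[labels == mat_label] = cps
        truth[key] = IntensityMap(line=lines[key], grid=spec.grid, values=values)
    return Phantom(spec=spec, labels=vol, truth=truth)


def default_phantom_spec(kind: str = "interface", seed: int = 0) -> PhantomSpec:
    """Study-condition phantoms: SDR-flow+-like filling against dentine.

    The interface scene uses a 64 x 1 x 48 grid at 6 um pitch (fine-scan
    conditions); emission rates follow the corrected-mean scale of the
    composite use case (Ca and Zn hosted in dentine, Ba/Yb/Sr in the
    filling).
    """
    filling = sdr_flow_plus()
    dentine = bovine_dentine()
    materials = {1: filling, 2: dentine}
    emission = {
        "Ca_Ka": {1: 30.0, 2: 1350.0},
        "Zn_Ka": {1: 0.0, 2: 2.8},
        "Ba_La": {1: 730.0, 2: 0.0},
        "Yb_La": {1: 300.0, 2: 0.0},
        "Sr_Ka": {1: 38.0, 2: 2.0},
    }
    if kind == "interface":
        grid = VoxelGrid.isotropic((64, 1, 48), 6.0)
        return PhantomSpec("interface", grid, materials, emission, seed=seed)
    if kind == "overlap_with_gap":
        grid = VoxelGrid.isotropic((64, 1, 48), 6.0)
        return PhantomSpec(
            "overlap_with_gap", grid, materials, emission,
            overlap_depth_um=60.0, gap_um=18.0, seed=seed,
        )
    if kind == "inclusion":
        grid = VoxelGrid.isotropic((48, 16, 24), 18.0)
        # dense grain inside the filling, ~300 x 90 x 190 um
        inclusion = Material(
            name="dense grain",
            mass_fractions={"O": 0.35, "Si": 0.15, "Ba": 0.30, "Yb": 0.20},
            density=3.2,
        )
        return PhantomSpec(
            "inclusion", grid,
            materials={1: filling, 2: inclusion},
            emission_cps={
                "Ba_La": {1: 730.0, 2: 1500.0},
                "Yb_La": {1: 300.0, 2: 0.0},
                "Sr_Ka": {1: 38.0, 2: 10.0},
            },
            inclusion_center_um=(432.0, 144.0, 216.0),
            inclusion_semiaxes_um=(150.0, 45.0, 95.0),
            seed=seed,
        )
    raise ValueError(f"unknown scene kind {kind!r}")


# ---------------------------------------------------------------------------
# Forward measurement and orientation flip
# ---------------------------------------------------------------------------

def forward_measure(
    truth: IntensityMap,
    field: CorrectionField,
    kernel: Kernel | None = None,
    livetime_s: float = 130.0,
    seed: int | None = None,
    noise: bool = True,
) -> IntensityMap:
    """Simulated measurement: truth attenuated by exp(-K~) plus counting noise.

    Expected counts are truth * exp(-K~) * livetime; with ``noise`` they are
    drawn from a Poisson distribution seeded by ``seed``; without, the
    expectation itself is returned (machine-precision inverse of the
    correction).
    """
    if livetime_s <= 0:
        raise ValueError("livetime must be positive")
    if truth.grid != field.grid:
        raise ValueError("truth and correction field grids differ")
    ksm = field
    if kernel is not None and not kernel.is_identity:
        from .correction import smooth_field

        ksm = smooth_field(field, kernel)
    expected_counts = truth.values * np.exp(-ksm.K) * livetime_s
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected_counts).astype(np.int64)
    else:
        counts = expected_counts
    return IntensityMap(
        line=truth.line,
        grid=truth.grid,
        values=counts / livetime_s,
        counts=counts,
        livetime_s=livetime_s,
    )


def rotate_180(
    labels: LabelVolume,
    maps: Mapping[str, IntensityMap],
    geom: BeamGeometry,
) -> tuple[LabelVolume, dict[str, IntensityMap], BeamGeometry]:
    """Scene after rotating the sample by 180 deg about the depth axis.

    Labels and maps are reflected in x and y while the bench geometry stays
    fixed, so the material adjacency to the excitation and detection sides
    is exchanged.  Applying the rotation twice restores the scene exactly.
    """
    def flip(a: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(a[::-1, ::-1, :])

    new_labels = LabelVolume(labels.grid, flip(labels.labels))
    new_maps = {}
    for key, m in maps.items():
        new_maps[key] = replace(
            m,
            values=flip(m.values),
            counts=None if m.counts is None else flip(np.asarray(m.counts)),
            valid=None if m.valid is None else flip(m.valid),
        )
    return new_labels, new_maps, geom
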