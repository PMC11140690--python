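"""Materials and energy-dependent linear attenuation coefficients.

A :class:`Material` is a named elemental composition (mass fractions) with a
bulk density.  Its linear attenuation coefficient follows the mixture rule

    mu(E) = rho * sum_i w_i * (mu/rho)_i(E),

with per-element mass attenuation coefficients (mu/rho)_i supplied by a
pluggable :class:`~confoxrf.xsections.CrossSectionSource`.  All lengths are
micrometres, energies keV, linear attenuation in 1/um.

Measured attenuation curves (from transmission or XAS experiments, reduced
via the Lambert-Beer law) can override calculated ones inside their energy
range; see :func:`blend_measured`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import xsections
from .xsections import CrossSectionSource, default_source

__all__ = [
    "Material",
    "AttenuationTable",
    "TransmissionMeasurement",
    "linear_attenuation",
    "mud_from_transmission",
    "mu_from_mud",
    "attenuation_envelope",
    "blend_measured",
    "material_from_yaml",
    "material_to_yaml",
    "attenuation_from_csv",
    "attenuation_to_csv",
    "sdr_flow_plus",
    "bovine_dentine",
    "dental_resin",
]

#: cm^2/g * g/cm^3 -> 1/cm -> 1/um
_PER_CM_TO_PER_UM = 1e-4


@dataclass(frozen=True)
class Material:
    """Elemental composition (mass fractions) plus bulk density in g/cm^3.

    Mass fractions are renormalized to sum to 1 on construction provided
    their sum lies within ``sum_tolerance`` of unity; compositions further
    off are rejected as likely data errors.
    """

    name: str
    mass_fractions: Mapping[str, float]
    density: float
    density_uncertainty: float | None = None
    sum_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.density_uncertainty is not None and self.density_uncertainty < 0:
            raise ValueError("density uncertainty must be non-negative")
        fr = dict(self.mass_fractions)
        if not fr:
            raise ValueError(f"{self.name}: empty composition")
        for sym, w in fr.items():
            xsections.atomic_number(sym)  # raises on unknown symbols
            if w < 0:
                raise ValueError(f"{self.name}: negative fraction for {sym}")
        total = sum(fr.values())
        if abs(total - 1.0) > self.sum_tolerance:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total:.4f}, outside "
                f"1 +/- {self.sum_tolerance}"
            )
        object.__setattr__(
            self, "mass_fractions", {s: w / total for s, w in fr.items()}
        )

    def with_density(self, density: float) -> "Material":
        return replace(self, density=density)

    def mass_attenuation(self, energies_keV, source: CrossSectionSource | None = None):
        """Compound mu/rho in cm^2/g (mixture rule over elements)."""
        src = source or default_source()
        e = np.asarray(energies_keV, dtype=float)
        out = np.zeros_like(np.atleast_1d(e), dtype=float)
        for sym, w in self.mass_fractions.items():
            if w > 0:
                out = out + w * np.atleast_1d(src.mass_attenuation(sym, e))
        return out if e.ndim else float(out[0])


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated linear attenuation mu(E) of one material, in 1/um.

    Evaluation between grid points uses log-log interpolation (falling back
    to linear interpolation if any tabulated value is zero, e.g. for the
    degenerate zero-density case).
    """

    energies_keV: np.ndarray
    mu_per_um: np.ndarray
    provenance: str = "calculated"   # calculated | measured | blended
    material: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        m = np.asarray(self.mu_per_um, dtype=float)
        if e.ndim != 1 or e.shape != m.shape or e.size < 2:
            raise ValueError("need matching 1-D arrays with >= 2 points")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("attenuation must be non-negative")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_per_um", m)

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies_keV[0]), float(self.energies_keV[-1])

    def __call__(self, energies_keV) -> np.ndarray:
        e = np.atleast_1d(np.asarray(energies_keV, dtype=float))
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(f"energy outside table range [{lo}, {hi}] keV")
        if np.all(self.mu_per_um > 0):
            out = np.exp(
                np.interp(np.log(e), np.log(self.energies_keV), np.log(self.mu_per_um))
            )
        else:
            out = np.interp(e, self.energies_keV, self.mu_per_um)
        return out if np.ndim(energies_keV) else float(out[0])


@dataclass(frozen=True)
class TransmissionMeasurement:
    """One transmission data point: intensity with/without the sample."""

    energy_keV: float
    intensity_on: float      # I(E), measured through the sample
    intensity_off: float     # I0(E), measured off the sample
    thickness_um: float | None = None

    def __post_init__(self) -> None:
        if self.intensity_on <= 0 or self.intensity_off <= 0:
            raise ValueError("intensities must be positive")
        if self.intensity_on > self.intensity_off:
            raise ValueError(
                "I(E) > I0(E): non-physical transmission above unity"
            )


def mud_from_transmission(m: TransmissionMeasurement) -> float:
    """Optical depth mu*d = ln(I0/I) from a transmission measurement."""
    return float(np.log(m.intensity_off / m.intensity_on))


def mu_from_mud(mud: float, thickness_um: float) -> float:
    """Linear attenuation (1/um) from optical depth and known thickness."""
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    if mud < 0:
        raise ValueError("optical depth must be non-negative")
    return mud / thickness_um


def _edge_knots(
    material: Material, lo: float, hi: float, source: CrossSectionSource
) -> list[float]:
    refine = getattr(source, "edge_bracket", None)
    knots: list[float] = []
    for sym in material.mass_fractions:
        for edge in xsections.edge_energies(sym):
            if lo < edge < hi:
                if refine is not None:
                    knots.extend(refine(sym, edge))
                else:
                    knots += [edge * (1 - 2e-4), edge * (1 + 2e-4)]
    return knots


def linear_attenuation(
    material: Material,
    energies_keV,
    source: CrossSectionSource | None = None,
    insert_edge_knots: bool = True,
) -> AttenuationTable:
    """Calculated linear attenuation table mu(E) in 1/um.

    Knots are inserted on both sides of every tabulated absorption edge of
    the constituent elements so that log-log interpolation never spans an
    edge discontinuity.
    """
    src = source or default_source()
    e = np.unique(np.asarray(energies_keV, dtype=float))
    if e.size < 2:
        raise ValueError("need at least two energies")
    if insert_edge_knots:
        knots = _edge_knots(material, e[0], e[-1], src)
        if knots:
            e = np.unique(np.concatenate([e, knots]))
    mu_rho = material.mass_attenuation(e, source=src)
    mu = material.density * np.asarray(mu_rho) * _PER_CM_TO_PER_UM
    return AttenuationTable(e, mu, provenance="calculated", material=material.name)


def attenuation_envelope(
    material: Material,
    energies_keV,
    source: CrossSectionSource | None = None,
) -> tuple[AttenuationTable, AttenuationTable]:
    """(lower, upper) attenuation tables at density rho -/+ its uncertainty.

    mu is linear in density, so the bounds are exact rescalings of the
    nominal curve.
    """
    if material.density_uncertainty is None:
        raise ValueError(f"{material.name}: density_uncertainty not set")
    nominal = linear_attenuation(material, energies_keV, source=source)
    rho = material.density
    lo = (rho - material.density_uncertainty) / rho
    hi = (rho + material.density_uncertainty) / rho
    if lo < 0:
        raise ValueError("density uncertainty exceeds density")
    lower = replace(nominal, mu_per_um=nominal.mu_per_um * lo)
    upper = replace(nominal, mu_per_um=nominal.mu_per_um * hi)
    return lower, upper


def blend_measured(
    calculated: AttenuationTable, measured: AttenuationTable
) -> AttenuationTable:
    """Merge a measured mu(E) curve into a calculated one.

    Measured values win inside their energy range, calculated values are
    kept elsewhere; continuity at the seams is not enforced and the result
    is flagged ``blended``.
    """
    lo, hi = measured.energy_range
    grid = np.unique(
        np.concatenate([calculated.energies_keV, measured.energies_keV])
    )
    inside = (grid >= lo) & (grid <= hi)
    mu = np.empty_like(grid)
    mu[inside] = measured(grid[inside])
    mu[~inside] = calculated(grid[~inside])
    return AttenuationTable(
        grid, mu, provenance="blended", material=calculated.material
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def material_from_yaml(path: str | Path) -> Material:
    """Load a material from YAML (name, density, density_uncertainty, fractions)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Material(
        name=doc["name"],
        mass_fractions={str(k): float(v) for k, v in doc["fractions"].items()},
        density=float(doc["density"]),
        density_uncertainty=(
            float(doc["density_uncertainty"])
            if doc.get("density_uncertainty") is not None
            else None
        ),
        sum_tolerance=float(doc.get("sum_tolerance", 0.01)),
    )


def material_to_yaml(material: Material, path: str | Path) -> None:
    doc = {
        "name": material.name,
        "density": float(material.density),
        "density_uncertainty": material.density_uncertainty,
        "fractions": {k: float(v) for k, v in material.mass_fractions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def attenuation_from_csv(
    path: str | Path, provenance: str = "measured", material: str = ""
) -> AttenuationTable:
    """Read a mu(E) table from CSV with header ``energy_keV,mu_per_um``."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    e = np.array([float(r["energy_keV"]) for r in rows])
    mu = np.array([float(r["mu_per_um"]) for r in rows])
    order = np.argsort(e)
    return AttenuationTable(e[order], mu[order], provenance=provenance, material=material)


def attenuation_to_csv(table: AttenuationTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["energy_keV", "mu_per_um"])
        for e, mu in zip(table.energies_keV, table.mu_per_um):
            w.writerow([f"{e:.6g}", f"{mu:.8g}"])


# ---------------------------------------------------------------------------
# Example materials of the dental-composite use case
# ---------------------------------------------------------------------------

def sdr_flow_plus() -> Material:
    """SDR flow+ dental composite, bulk density 2.15 +/- 0.15 g/cm^3.

    Composition in wt% (heavy glass formers Ba, Yb, Sr in an organic resin
    matrix); the raw published fractions slightly oversubscribe 100% and are
    renormalized here.
    """
    raw = {
        "H": 3.0, "C": 36.0, "N": 2.9, "O": 31.0, "F": 3.7,
        "Na": 0.14, "Al": 3.8, "Si": 3.5, "Cl": 0.30, "K": 0.04,
        "Ca": 0.09, "Ti": 0.15, "Sr": 3.5, "Ba": 12.0, "Yb": 6.0,
    }
    total = sum(raw.values())
    return Material(
        name="SDR flow+",
        mass_fractions={k: v / total for k, v in raw.items()},
        density=2.15,
        density_uncertainty=0.15,
    )


def dental_resin() -> Material:
    """Unfilled methacrylate resin (bis-GMA/TEGDMA-like), density 1.20 g/cm^3.

    A light C/H/O polymer as used in dental adhesives; serves as the
    low-attenuation counterpart in high-contrast phantom scenes.
    """
    return Material(
        name="dental resin",
        mass_fractions={"C": 0.70, "H": 0.07, "O": 0.23},
        density=1.20,
        density_uncertainty=0.05,
    )


def bovine_dentine() -> Material:
    """Dry bovine dentine, bulk density 2.025 +/- 0.075 g/cm^3.

    Representative collagen + carbonated-apatite composition (mineral-phase
    Ca and P with an organic C/N/H/O matrix and trace Mg, Na, Zn, Sr); not a
    measured composition of any individual tooth.
    """
    fractions = {
        "H": 0.022, "C": 0.130, "N": 0.035, "O": 0.4045,
        "Na": 0.006, "Mg": 0.008, "P": 0.128, "Ca": 0.266,
        "Zn": 0.0002, "Sr": 0.0003,
    }
    return Material(
        name="bovine dentine",
        mass_fractions=fractions,
        density=2.025,
        density_uncertainty=0.075,
    )
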