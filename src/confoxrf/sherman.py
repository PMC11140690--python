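"""Sherman-equation forward XRF intensities and composition reconciliation.

For a thick (infinite-depth) homogeneous sample excited by a polychromatic
spectrum, the primary fluorescence intensity of line j of element ``el`` is

    I_j = G * eps(E_j) * w_el * int_edge^Emax  S0(E) tau_el(E) omega p
          / [ mu_s(E)/sin(psi_1) + mu_s(E_j)/sin(psi_2) ]  dE,

with tau_el the element's photoelectric mass attenuation, omega the
fluorescence yield, p the line transition fraction, mu_s the sample's total
mass attenuation (single source of truth: the same mixture rule used for
the absorption correction), psi_1/psi_2 the incidence and take-off angles
and G an effective geometry factor per line family.  Secondary enhancement
is omitted.

The composition workflow inverts this: free (heavy) element mass fractions
are adjusted by weighted least squares until calculated mu(E) values and
forward-calculated line intensities match the measured targets; dark-matrix
elements (H, C, N, O, F) are never free here and enter only through mu_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import xsections
from .correction import Spectrum
from .materials import Material
from .xsections import CrossSectionSource, FluorescenceLine, FLUORESCENCE_YIELD

__all__ = [
    "SetupParams",
    "MuTarget",
    "IntensityTarget",
    "CompositionFitProblem",
    "FitResult",
    "sherman_forward",
    "fit_composition",
    "validate_against_mu",
]

#: Ka/Kb/La transition fractions within their series
_TRANSITION_FRACTION = {"Ka": 0.88, "Kb": 0.12, "La": 0.80}

#: dark-matrix elements that must never be free in the heavy-element fit
DARK_MATRIX = frozenset({"H", "C", "N", "O", "F"})


@dataclass(frozen=True)
class SetupParams:
    """Spectrometer calibration: geometry factor, angles, detector efficiency."""

    geometry_factor: float = 1.0
    incidence_deg: float = 45.0
    takeoff_deg: float = 45.0
    efficiency: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for ang in (self.incidence_deg, self.takeoff_deg):
            if not 0.0 < ang < 90.0:
                raise ValueError("angles must lie strictly between 0 and 90 deg")
        if self.geometry_factor <= 0:
            raise ValueError("geometry factor must be positive")

    def eff(self, energy_keV: float) -> float:
        if self.efficiency is None:
            return 1.0
        v = float(self.efficiency(energy_keV))
        if not 0.0 <= v <= 1.0:
            raise ValueError("detector efficiency must lie in [0, 1]")
        return v


@dataclass(frozen=True)
class MuTarget:
    energy_keV: float
    mu_per_um: float
    sigma: float | None = None


@dataclass(frozen=True)
class IntensityTarget:
    line: FluorescenceLine
    intensity: float
    sigma: float | None = None


@dataclass(frozen=True)
class CompositionFitProblem:
    """Reconcile a composition against measured mu(E) and line intensities.

    ``free`` elements are adjusted; all others are fixed except the
    ``balance`` element, which absorbs the renormalization so fractions
    always sum to one.  ``weight_mu``/``weight_intensity`` set the relative
    pull of the two target families.
    """

    initial: Material
    free: tuple[str, ...]
    mu_targets: tuple[MuTarget, ...] = ()
    intensity_targets: tuple[IntensityTarget, ...] = ()
    balance: str = "O"
    weight_mu: float = 1.0
    weight_intensity: float = 1.0
    max_iterations: int = 200
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("no free elements: nothing to fit")
        if not (self.mu_targets or self.intensity_targets):
            raise ValueError("no targets to fit against")
        free = set(self.free)
        if free & DARK_MATRIX:
            raise ValueError(
                f"dark-matrix elements cannot be free: {sorted(free & DARK_MATRIX)}"
            )
        if self.balance in free:
            raise ValueError("balance element cannot be free")
        comp = set(self.initial.mass_fractions)
        missing = free - comp
        if missing:
            raise ValueError(f"free elements missing from composition: {sorted(missing)}")
        if self.balance not in comp:
            raise ValueError("balance element missing from composition")


@dataclass(frozen=True)
class FitResult:
    material: Material
    residuals: np.ndarray
    converged: bool
    n_evaluations: int
    cost: float


def sherman_forward(
    material: Material,
    spectrum: Spectrum,
    setup: SetupParams,
    fluor: FluorescenceLine,
    source: CrossSectionSource | None = None,
) -> float:
    """Thick-sample primary fluorescence intensity (calibrated arbitrary units)."""
    src = source or xsections.default_source()
    w_el = float(material.mass_fractions.get(fluor.element, 0.0))
    if w_el == 0.0:
        return 0.0
    above = spectrum.energies_keV > fluor.edge_keV
    if not np.any(above) or float(np.sum(spectrum.weights[above])) <= 0.0:
        raise ValueError(
            f"spectrum has no weight above the {fluor.element} edge "
            f"({fluor.edge_keV} keV)"
        )
    e = spectrum.energies_keV[above]
    s0 = spectrum.weights[above]
    tau = np.asarray(src.photo_mass_attenuation(fluor.element, e))
    mu_exc = np.asarray(material.mass_attenuation(e, source=src))
    mu_fluo = float(material.mass_attenuation(fluor.energy_keV, source=src))
    shell = "K" if fluor.name.startswith("K") else "L3"
    omega = FLUORESCENCE_YIELD.get((fluor.element, shell), 0.3)
    p = _TRANSITION_FRACTION.get(fluor.name, 1.0)
    chi = (
        mu_exc / np.sin(np.radians(setup.incidence_deg))
        + mu_fluo / np.sin(np.radians(setup.takeoff_deg))
    )
    integrand = s0 * tau * omega * p / chi
    if spectrum.discrete or e.size == 1:
        # discrete line excitation: no energy measure, sum the line weights
        integral = float(np.sum(integrand))
    else:
        integral = float(np.trapezoid(integrand, e))
    return setup.geometry_factor * setup.eff(fluor.energy_keV) * w_el * integral


def validate_against_mu(
    material: Material,
    measured_points: Sequence[tuple[float, float]],
    source: CrossSectionSource | None = None,
) -> tuple[np.ndarray, float]:
    """Per-point relative residuals (calc - meas)/meas of linear attenuation.

    Points are (energy keV, mu 1/um).  Returns the residual vector and the
    RMS (NaN when the point list is empty)."""
    from .materials import linear_attenuation

    if not measured_points:
        return np.zeros(0), float("nan")
    energies = [p[0] for p in measured_points]
    grid = np.unique(np.asarray(energies, dtype=float))
    if grid.size == 1:
        grid = np.array([grid[0] * 0.999, grid[0] * 1.001])
    table = linear_attenuation(material, grid, source=source)
    res = np.array(
        [(float(table(e)) - mu) / mu for e, mu in measured_points]
    )
    return res, float(np.sqrt(np.mean(res**2)))


def _compose(
    problem: CompositionFitProblem, z: np.ndarray
) -> Material:
    """Material with free fractions set from unconstrained parameters z.

    Free and balance fractions share the mass left over by the fixed
    elements through a softmax-style map, keeping every fraction in (0, 1)
    and the total exactly 1."""
    init = problem.initial.mass_fractions
    fixed = {
        s: w for s, w in init.items()
        if s not in problem.free and s != problem.balance
    }
    available = 1.0 - sum(fixed.values())
    expz = np.exp(z)
    denom = 1.0 + float(np.sum(expz))
    fractions = dict(fixed)
    for sym, ez in zip(problem.free, expz):
        fractions[sym] = available * float(ez) / denom
    fractions[problem.balance] = available / denom
    return Material(
        name=problem.initial.name,
        mass_fractions=fractions,
        density=problem.initial.density,
        density_uncertainty=problem.initial.density_uncertainty,
    )


def fit_composition(
    problem: CompositionFitProblem,
    spectrum: Spectrum,
    setup: SetupParams,
    source: CrossSectionSource | None = None,
) -> FitResult:
    """Weighted least squares over the free mass fractions.

    Residuals combine relative mu(E) mismatches and relative line-intensity
    mismatches; the fit runs in unconstrained coordinates via the simplex
    parameterization of :func:`_compose`.  Non-convergence within the
    iteration cap returns the best iterate flagged accordingly."""
    from .materials import linear_attenuation

    src = source or xsections.default_source()
    init = problem.initial.mass_fractions
    w_bal = max(init[problem.balance], 1e-6)
    z0 = np.array([
        np.log(max(init[s], 1e-6) / w_bal) for s in problem.free
    ])
    mu_grid = (
        np.unique(np.array([t.energy_keV for t in problem.mu_targets]))
        if problem.mu_targets else None
    )

    def residuals(z: np.ndarray) -> np.ndarray:
        mat = _compose(problem, z)
        out = []
        if problem.mu_targets:
            grid = mu_grid if mu_grid.size > 1 else np.array(
                [mu_grid[0] * 0.999, mu_grid[0] * 1.001]
            )
            table = linear_attenuation(mat, grid, source=src)
            for t in problem.mu_targets:
                scale = t.sigma if t.sigma else t.mu_per_um
                out.append(
                    problem.weight_mu * (float(table(t.energy_keV)) - t.mu_per_um) / scale
                )
        for t in problem.intensity_targets:
            calc = sherman_forward(mat, spectrum, setup, t.line, source=src)
            scale = t.sigma if t.sigma else max(abs(t.intensity), 1e-12)
            out.append(problem.weight_intensity * (calc - t.intensity) / scale)
        return np.asarray(out)

    sol = least_squares(
        residuals,
        z0,
        method="lm" if len(z0) <= len(residuals(z0)) else "trf",
        xtol=problem.tolerance,
        ftol=problem.tolerance,
        gtol=problem.tolerance,
        max_nfev=problem.max_iterations * max(len(z0), 1) * 4,
    )
    return FitResult(
        material=_compose(problem, sol.x),
        residuals=sol.fun,
        converged=bool(sol.success) and sol.status != 0,
        n_evaluations=int(sol.nfev),
        cost=float(sol.cost),
    )
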