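# Methods

This note records the models implemented in `confoxrf`, their assumptions,
the defaults and why, and the limits of what the synthetic tests show.

## Units and conventions

All lengths are micrometres, energies keV, linear attenuation coefficients
μ in 1/μm (voxel pitches are μm-scale, so optical depths are products of
O(10⁻²)/μm coefficients with O(10²) μm paths). Arrays are indexed
`(x, y, z)` with `z` increasing into the sample; voxel `i` spans the
half-open interval `[i, i+1)·s_v`, its center at `(i+0.5)·s_v`.

## Attenuation from composition

A material is a set of elemental mass fractions `w_i` plus a bulk density
ρ; the mixture rule gives `μ(E) = ρ · Σ w_i (μ/ρ)_i(E)`. Per-element mass
attenuation is computed at run time as photoelectric + coherent +
incoherent:

* photoelectric from the imaginary anomalous-scattering factor f″
  (Cromer–Liberman, via gemmi): σ_pe = 2 r_e λ f″;
* Rayleigh from the Thomson cross section weighted by the squared IT92
  atomic form factor F(q, Z);
* Compton from Klein–Nishina weighted by the incoherent scattering
  function approximated as S(q, Z) ≈ Z − F²/Z.

Accuracy: ~0.5% against standard tabulations in the 15–30 keV band (water
at 20 keV: 0.808 computed vs 0.8096 cm²/g tabulated), degrading to a few
percent below ~10 keV and near edges. That is adequate here because
composition and density uncertainties of real materials dominate (the
density envelope of the example materials alone spans ±4–7%). Validity
range 1–60 keV; photoabsorption of H and He is treated as zero (above
3 keV it is under 2% of their μ/ρ, and they are minor mass fractions).

Each element's curve is cached on a 220-point log-energy grid with a pair
of knots straddling every absorption edge; the edge position is located by
bisection on the f″ jump because the Cromer–Liberman internal edge can sit
a few eV away from the nominal value. Evaluation between knots is log-log
interpolation, which is exact for power laws and never spans an edge.
K edges are bundled for the common analytes, L3 (plus L2/L1 as
interpolation knots only) for the heavy glass formers. Externally measured
μ(E) curves (transmission or XAS, reduced via μd = ln(I0/I)) can override
calculated ones inside their energy range; continuity at the seams is
deliberately not enforced and the provenance is recorded as `blended`.
Log-log was chosen for interpolating measured curves as well — the
smoothest assumption consistent with attenuation physics — since no
interpolation rule is implied by the data themselves.

## Sample geometry

Micro-CT volumes are segmented by simple thresholding (explicit thresholds
or multi-class Otsu) and registered to the XRF grid by integer-shift
normalized cross-correlation (template matching); sub-voxel refinement is
deliberately omitted because voxel-level matching is what the correction
consumes. Per-voxel path lengths are computed by an exact incremental
face-crossing (Amanatides–Woo) traversal. The start voxel contributes the
chord *from its center* to its exit face — the probing volume is modeled
as centered in the voxel — so an axis-aligned path through N voxels has
length (N − ½)·s_v. Corner ties advance all tied axes at once, consistent
with half-open voxel intervals. Label 0 (void/air) contributes zero
attenuation; ambient-air attenuation is negligible on μm–mm scales.

Default beam geometry puts both beams in the xz plane at 45° to the
surface on opposite sides — a typical confocal bench convention, fully
configurable, since bench angles are instrument-specific.

Coarse XRF grids are brought onto the CT pitch by cubic-spline (bicubic)
resampling on cell-centered coordinates. Input borders are padded by odd
reflection before filtering, which continues linear trends exactly, so
constant maps stay constant and linear ramps resample to machine-level
accuracy away from pathological cases.

## Correction term

For line j at voxel v:

* **Excitation term.** The upstream path is traced against the excitation
  direction; the depth-attenuated spectrum is
  `S_d(E) = S₀(E)·exp(−Σ_m μ_m(E)·l_m)` and the effective exponent
  `μl_exc = −ln[⟨S_d⟩/⟨S₀⟩]` with the spectral average weighted by the
  fluorescing element's photoabsorption τ_el(E) above its edge. This is a
  reconstruction of the published procedure's summary (the detailed
  supplement was not available); it reduces exactly to μ(E₀)·l for
  monochromatic excitation, which anchors its correctness. The average is
  treated as an energy integral: a node is inserted at the edge and
  trapezoidal measures applied, making the value stable to 0.05% against
  grid refinement. Discrete line spectra bypass the measure.
* **Detection term.** `Σ_i μ_i(E_j)·L_i` with exact per-material chord
  lengths `L_i` along the detection ray to the surface (equal to
  `N_i·s_v` scaled by the beam obliquity for axis-aligned rays).

K = excitation + detection term is the non-negative total optical depth;
correction multiplies by exp(+K), so corrected intensities never fall
below measured ones. The sign convention is fixed by the physics: deeper
signal is attenuated, the correction restores it.

**Probing-volume mixing.** FWHM(E) = A·exp(−kE) is fit to thin-foil
calibration points (closed form for two points, least squares in log-FWHM
for more; k < 0 is rejected as unphysical). σ = FWHM/(2√(2 ln 2)) — the
standard Gaussian identity, stated here because calibration reports FWHM.
K is mixed over voxels whose centers lie within 2σ (circular support,
Gaussian weights renormalized over the clipped support, no interpolation).
The kernel is 2-D in the scan plane by default, with a 3-D spherical
variant for volume scans. With 47 μm FWHM on a 6 μm grid the support
spans 13 voxels. If 2σ < half a pitch the kernel degenerates to the
identity (point probing volume).

**Counting mask.** Voxels with relative Poisson error 1/√N ≥ 10%
(N ≤ 100) are flagged invalid, keep their measured values, and export as
NaN. The inequality is strict: N = 100 is excluded, N = 101 included.

**Validation statistics.** ROI means are arithmetic means over valid
voxels; the two-orientation deviation is 100·|a−b|/(a+b), computed at
full precision and rounded only for display. One published deviation row
(means 38 and 31 printed as 5%) is inconsistent with this formula — and
with every plausible alternative — while the remaining rows all match;
that row is documented as a presumed typo and excluded from checks.

## Forward simulator

The forward model is the exact inverse of the correction: expected counts
= truth·exp(−K̃)·livetime, with optional Poisson sampling from a seeded
generator. Emission truth is specified directly as zero-absorption cps per
material per line, decoupling phantom generation from fundamental-parameter
physics; Sherman-based truth is available through the `sherman` module
when absolute scales matter. Three scenes mirror the measurement
situations of a filled-tooth composite: a plane interface (with the
published fine-scan conditions: 64 × 1 × 48 voxels, 6 μm pitch, 130 s live
time, 30 kV), a partially overlapping interface with a void gap beneath
the overlap, and a dense ellipsoidal micro-inclusion (18 μm pitch,
~300 × 90 × 190 μm grain). Default emission rates follow the corrected-mean
scale of the published composite measurements (e.g. Ca Kα 1350 cps in
dentine, Ba Lα 730 cps in the filling). The orientation-flip operation
reflects labels and maps in x and y with the bench geometry fixed,
exchanging which material shadows which; it is an involution.

The tube spectrum is a Kramers photon-number continuum ∝ (E_max/E − 1)
with Gaussian characteristic anode lines (added when the tube voltage
exceeds the anode K edge, integrated strength ∝ (U−1)^1.67 relative to
the continuum, σ = 0.15 keV) and optional filter attenuation, normalized
to unit integral. This is a stand-in for the real post-polycapillary
spectrum, isolated behind the `Spectrum` interface precisely so a measured
spectrum can replace it.

What the phantoms do **not** emulate: spectral deconvolution residues,
detector dead time and pile-up, scattering background, partial-volume
composition gradients at interfaces, CT beam hardening, or registration
error between CT and XRF grids. Passing tests therefore demonstrate the
*internal* consistency and correctness of the correction machinery — path
lengths, spectral weighting, kernel mixing, statistics — not the fidelity
of any particular laboratory's instrument model.

## Sherman forward model and composition fit

The thick-sample (infinite depth) primary-fluorescence Sherman integral
is used — appropriate for bulk validation on an ~850 μm slice at these
energies. Secondary enhancement is omitted. Fluorescence yields and
transition fractions are bundled nominal values; they scale absolute
intensities only and cancel in relative fits (an effective geometry
factor per line family absorbs calibration). The attenuation inside the
integrand is the same mixture rule the correction uses — a single source
of truth, asserted by test.

The composition fit adjusts free heavy-element fractions against measured
μ(E) points and line intensities by least squares. Dark-matrix elements
(H, C, N, O, F) are never free — hard-X-ray data cannot constrain them —
and enter only through the matrix attenuation; a designated balance
element absorbs renormalization through a softmax-style parameterization
that keeps every fraction in (0, 1) and the total exactly 1. The relative
weighting of μ-residuals vs intensity-residuals is exposed as
configuration (default equal, both relative), since no principled universal
weighting exists for the reconcile-and-repeat workflow. Non-convergence
within the iteration cap returns the best iterate, flagged.

## Problem sizes and numerical choices

The validation suite and the acceptance script run the interface scenes at
the published fine-scan size (64 × 1 × 48 voxels) and the inclusion scene
at 48 × 16 × 24; these sizes keep every check CPU-cheap while leaving the
kernel span (13 voxels) and depth attenuation (optical depths up to ~19)
at realistic magnitudes. Monte-Carlo ray-sampling oracles use 10⁵ points
(0.5% agreement bound); spectral-grid oracles refine the energy step 8×
(0.1% bound). Ties, degenerate inputs and rejection paths (zero-variance
templates, flat foil scans, all-void volumes, N = 100 exactly) are pinned
by dedicated tests.

## Known limitations

* The computed cross sections are a few percent off below ~10 keV and near
  edges; supply measured μ(E) curves or tabulated per-element data via
  `TabulatedCrossSections` when that matters.
* The excitation-path spectral weighting is a documented reconstruction
  (exact in the monochromatic limit); comparing it against the original
  procedure's supplement remains open.
* The probing volume is an isotropic 2-D (or spherical 3-D) Gaussian; an
  ellipsoidal model along the beam axes would be more faithful and is a
  known improvement direction.
* Registration is integer-voxel only; no sub-voxel refinement.
* No voxel-wise concentration quantification — the correction returns
  corrected intensities, not mass fractions.
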