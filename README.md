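# confoxrf

Voxel-wise absorption correction for laboratory **confocal micro-XRF**
elemental maps of heterogeneous composite samples, with a forward simulator
that makes the whole pipeline verifiable without measurement data.

## The problem

Confocal micro-X-ray-fluorescence spectroscopy scans a micrometer-sized
probing volume — the overlap of the foci of two polycapillary optics —
through a sample and records net-peak fluorescence intensities per voxel.
Both the polychromatic excitation beam and the emitted fluorescence are
attenuated on their way through the sample, so the signal from depth is
systematically suppressed, and in composites (e.g. a tooth with a dental
filling) the suppression depends on which materials each ray crosses.
Uncorrected maps therefore show artificial depth gradients and
interface artifacts.

`confoxrf` corrects each voxel of a measured map `I_meas,j` for line *j*
using the Lambert–Beer law:

    I_corr,j(x,y,z) = I_meas,j(x,y,z) · exp( K_j(x,y,z) )

    K_j = μl_exc(x,y,z)  +  Σ_i μ_i(E_j) · N_i,j · s_v

where the first exponent term is the effective optical depth of the
excitation path (the depth-attenuated tube spectrum weighted by the
photoabsorption of the fluorescing element above its edge), and the second
is a linear combination over the materials *i* crossed by the detection
ray, with per-material voxel counts `N_i,j` and voxel pitch `s_v`. The
sample structure comes from a segmented, template-matching-registered
micro-CT volume; per-material attenuation `μ(E)` is computed from elemental
mass fractions and density (mixture rule over per-element cross sections)
or taken from measured transmission/XAS curves.

Because the probing-volume size is energy dependent — its FWHM follows
`FWHM(E) = A·exp(−k·E)`, calibrated from thin-foil depth scans (e.g.
47 μm at Ca Kα down to 15 μm at Sr Kα) — the correction term is mixed over
a circular 2σ Gaussian kernel before being applied.

A Sherman-equation forward model closes the loop on composition: bulk
fluorescence intensities are forward-calculated from mass fractions and
reconciled, together with measured `μ(E)` values, by a bounded
least-squares fit of the free (heavy) element fractions.

Intended users: spectroscopists running laboratory confocal micro-XRF /
micro-CT correlative measurements, and anyone needing a testable reference
implementation of voxel-wise absorption correction.

## Worked example

Simulate an interface scene (composite filling against bovine dentine,
64 × 1 × 48 voxels at 6 μm pitch), forward-attenuate the Ca Kα map with
Poisson counting noise at 130 s live time, then correct it:

```python
import confoxrf as cx
from confoxrf import simulate as sim

spec = sim.default_phantom_spec("interface")
phantom = sim.make_phantom(spec)
geom = cx.default_geometry()                       # 45°/45° in the xz plane
spectrum = sim.tube_spectrum(sim.TubeSpec(kv=30.0))
atten = {lab: cx.linear_attenuation(m, spectrum.energies_keV)
         for lab, m in spec.materials.items()}

pv = cx.fit_pv_model([cx.PVCalibrationPoint(3.7, 47.0, "Ca"),
                      cx.PVCalibrationPoint(14.2, 15.0, "Sr")])
line = phantom.truth["Ca_Ka"].line
kernel = cx.kernel_for_line(pv, line.energy_keV, 6.0)
print(f"Ca Ka probing volume: FWHM {float(pv.fwhm(line.energy_keV)):.1f} um, "
      f"kernel spans {kernel.span} voxels")

field = cx.smooth_field(
    cx.correction_field(phantom.labels, atten, geom, spectrum, line), kernel)
meas = sim.forward_measure(phantom.truth["Ca_Ka"], field,
                           livetime_s=130.0, seed=1)
mask = cx.counting_mask(meas)                      # Poisson error < 10%
corr = cx.apply_correction(meas, field, mask)

roi = (slice(40, 56), slice(0, 1), slice(2, 12))   # dentine side, shallow
print(f"measured  ROI mean: {cx.roi_mean(meas, roi, mask):7.1f} cps")
print(f"corrected ROI mean: {cx.roi_mean(corr, roi, mask):7.1f} cps   (true rate 1350.0)")
```

Output:

```
Ca Ka probing volume: FWHM 47.0 um, kernel spans 13 voxels
measured  ROI mean:    58.6 cps
corrected ROI mean:  1349.5 cps   (true rate 1350.0)
```

The measured ROI mean is depressed by more than a factor of 20 by
absorption; the corrected mean recovers the true emission rate to a
fraction of a percent. Voxels whose counting error exceeds 10% are flagged
invalid rather than corrected.

The same pipeline is available from the shell:

```bash
confoxrf simulate --scene interface --seed 3 --out sim.h5
confoxrf correct --maps sim.h5 --materials mats.yaml --pv pv.yaml --out corrected.h5
```

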