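"""Correction term K, probing-volume smoothing, application, statistics."""

import numpy as np
import pytest

import confoxrf as cx
from confoxrf import correction as co
from confoxrf.correction import (
    IntensityMap,
    Spectrum,
    apply_correction,
    correction_field,
    counting_mask,
    detection_term,
    excitation_term,
    monochromatic,
    orientation_deviation,
    roi_mean,
    smooth_field,
)
from confoxrf.geometry import BeamGeometry, LabelVolume, VoxelGrid
from confoxrf.probing_volume import identity_kernel, kernel_for_line
from confoxrf.xsections import line as lookup_line

from conftest import constant_table


ZN = lookup_line("Zn", "Ka")   # 8.639 keV, edge 9.659
CA = lookup_line("Ca", "Ka")


def column_labels(n=16, pitch=8.0, label=1):
    grid = VoxelGrid.isotropic((1, 1, n), pitch)
    return LabelVolume(grid, np.full(grid.shape, label, dtype=np.int64))


DOWN_Z = BeamGeometry((0, 0, 1.0), (1.0, 0, 0))       # excitation straight down
UP_Z = BeamGeometry((1.0, 0, 0), (0, 0, -1.0))        # detection straight up


class TestExcitationTerm:
    def test_surface_voxel_is_zero(self):
        vol = column_labels()
        mul = excitation_term(
            monochromatic(20.0), vol, {1: constant_table(0.01)}, DOWN_Z, ZN
        )
        # start voxel chord runs from its own center: half a voxel upstream
        assert mul[0, 0, 0] == pytest.approx(0.01 * 4.0, rel=1e-9)
        empty = LabelVolume(vol.grid, np.zeros(vol.grid.shape, dtype=np.int64))
        assert excitation_term(
            monochromatic(20.0), empty, {1: constant_table(0.01)}, DOWN_Z, ZN
        ).max() == 0.0

    def test_monochromatic_limit_is_mu_times_length(self):
        """20 keV beam through 100 um of mu = 0.01/um gives mu*l = 1.0."""
        vol = column_labels(n=16, pitch=8.0)
        mul = excitation_term(
            monochromatic(20.0), vol, {1: constant_table(0.01)}, DOWN_Z, ZN
        )
        # voxel 12: upstream path (12 + 0.5) * 8 = 100 um
        assert mul[0, 0, 12] == pytest.approx(1.0, rel=1e-12)

    def test_two_line_spectrum_matches_bruteforce(self):
        """Polychromatic effective mu*l vs an explicit-loop evaluation."""
        e_grid = np.array([12.0, 15.0, 18.0, 21.0])
        weights = np.array([0.0, 3.0, 0.0, 1.0])   # two discrete lines
        spectrum = Spectrum(e_grid, weights, discrete=True)
        mu_e = {12.0: 0.03, 15.0: 0.02, 18.0: 0.012, 21.0: 0.008}
        table = cx.AttenuationTable(e_grid, np.array([mu_e[e] for e in e_grid]))
        vol = column_labels(n=16, pitch=8.0)
        mul = excitation_term(spectrum, vol, {1: table}, DOWN_Z, ZN)

        src = cx.ComputedCrossSections()
        depth = (12 + 0.5) * 8.0
        num = den = 0.0
        for e, w in zip(e_grid, weights):
            if e <= ZN.edge_keV:
                continue
            tau = float(src.photo_mass_attenuation("Zn", e))
            num += w * tau * np.exp(-mu_e[e] * depth)
            den += w * tau
        assert mul[0, 0, 12] == pytest.approx(-np.log(num / den), rel=1e-12)

    def test_no_weight_above_edge_rejected(self):
        vol = column_labels()
        with pytest.raises(ValueError, match="excited"):
            excitation_term(
                monochromatic(9.0), vol, {1: constant_table(0.01)}, DOWN_Z, ZN
            )

    def test_mul_nondecreasing_with_depth(self, tube_30kv):
        vol = column_labels(n=24, pitch=6.0)
        table = constant_table(0.01)
        mul = excitation_term(tube_30kv, vol, {1: table}, DOWN_Z, ZN)
        assert np.all(np.diff(mul[0, 0]) > 0)

    def test_profile_weights_nonnegative_and_consistent(self, tube_30kv):
        vol = column_labels(n=8, pitch=6.0)
        prof = co.excitation_profile_along_ray(
            tube_30kv, vol, {1: constant_table(0.02)}, DOWN_Z, ZN,
            voxels=[(0, 0, i) for i in range(8)],
        )
        assert np.all(prof.weights >= 0)
        assert np.all(np.diff(prof.mul_exc) > 0)
        full = excitation_term(tube_30kv, vol, {1: constant_table(0.02)}, DOWN_Z, ZN)
        assert np.allclose(prof.mul_exc, full[0, 0, :])


class TestDetectionTerm:
    def test_surface_voxel_is_half_chord(self):
        vol = column_labels(n=10, pitch=6.0)
        val = detection_term(vol, {1: constant_table(0.02)}, UP_Z, ZN, (0, 0, 0))
        assert val == pytest.approx(0.02 * 3.0, rel=1e-12)

    def test_axis_aligned_hand_product(self):
        """10 voxels at 6 um, mu = 0.02/um: center-start gives 1.14."""
        vol = column_labels(n=10, pitch=6.0)
        val = detection_term(vol, {1: constant_table(0.02)}, UP_Z, ZN, (0, 0, 9))
        assert val == pytest.approx(0.02 * 9.5 * 6.0, rel=1e-12)  # 1.14

    def test_mixed_two_material_path(self):
        arr = np.ones((1, 1, 12), dtype=np.int64)
        arr[..., :5] = 2
        vol = LabelVolume(VoxelGrid.isotropic((1, 1, 12), 6.0), arr)
        atten = {1: constant_table(0.02), 2: constant_table(0.005)}
        val = detection_term(vol, atten, UP_Z, ZN, (0, 0, 11))
        by_hand = 0.02 * 6.5 * 6.0 + 0.005 * 5 * 6.0
        assert val == pytest.approx(by_hand, rel=1e-12)


class TestCorrectionField:
    def test_all_void_volume_gives_zero(self, geom):
        grid = VoxelGrid.isotropic((6, 1, 6), 6.0)
        vol = LabelVolume(grid, np.zeros(grid.shape, dtype=np.int64))
        field = correction_field(
            vol, {1: constant_table(0.02)}, geom, monochromatic(20.0), ZN
        )
        assert np.all(field.K == 0.0)

    def test_homogeneous_slab_linear_in_depth(self):
        """Monochromatic K grows linearly with z at slope
        mu_exc/sin(a_exc) + mu_line/sin(a_det) per unit depth."""
        vol = LabelVolume(
            VoxelGrid.isotropic((40, 1, 20), 6.0),
            np.ones((40, 1, 20), dtype=np.int64),
        )
        s = np.sqrt(0.5)
        geom = BeamGeometry((s, 0, s), (s, 0, -s))
        e0 = 20.0
        table = constant_table(0.01)
        field = correction_field(vol, {1: table}, geom, monochromatic(e0), ZN)
        # central column, away from the slanted entry/exit faces
        col = field.K[20, 0, :]
        z = np.arange(20)
        interior = slice(2, 12)
        slope = np.polyfit(z[interior], col[interior], 1)[0]
        expected = 0.01 * 6.0 / s + 0.01 * 6.0 / s
        assert slope == pytest.approx(expected, rel=1e-9)

    def test_interface_step_matches_piecewise_closed_form(self):
        """Two-material half-spaces: K gradients follow each material's mu."""
        arr = np.ones((32, 1, 16), dtype=np.int64)
        arr[16:] = 2
        vol = LabelVolume(VoxelGrid.isotropic((32, 1, 16), 6.0), arr)
        s = np.sqrt(0.5)
        geom = BeamGeometry((0, 0, 1.0), (s, 0, -s))
        mu1, mu2 = 0.02, 0.005
        atten = {1: constant_table(mu1), 2: constant_table(mu2)}
        field = correction_field(vol, atten, geom, monochromatic(20.0), ZN)
        # vertical excitation (depth * mu) + 45-degree detection (depth *
        # sqrt(2) * mu), entirely within one material away from the interface
        expect1 = mu1 * 6.0 * (1.0 + np.sqrt(2.0))
        dz = np.diff(field.K[4, 0, :8])       # material 1, detection stays inside
        assert np.allclose(dz, expect1, rtol=1e-6)
        expect2 = mu2 * 6.0 * (1.0 + np.sqrt(2.0))
        dz2 = np.diff(field.K[20, 0, :8])     # material 2 interior
        assert np.allclose(dz2, expect2, rtol=1e-6)

    def test_missing_material_table_rejected(self, geom):
        arr = np.ones((4, 1, 4), dtype=np.int64)
        arr[2:] = 2
        vol = LabelVolume(VoxelGrid.isotropic((4, 1, 4), 6.0), arr)
        with pytest.raises(ValueError, match="label 2"):
            correction_field(vol, {1: constant_table(0.01)}, geom,
                             monochromatic(20.0), ZN)


class TestSmoothField:
    def _field(self, K):
        return co.CorrectionField(
            line=ZN, grid=VoxelGrid.isotropic(K.shape, 6.0), K=K
        )

    def test_identity_kernel_is_noop(self):
        K = np.random.default_rng(0).uniform(0, 2, (10, 1, 8))
        field = self._field(K)
        assert smooth_field(field, identity_kernel(6.0)) is field

    def test_constant_field_unchanged(self, pv_model):
        field = self._field(np.full((20, 1, 20), 1.7))
        kern = kernel_for_line(pv_model, 3.7, 6.0)
        assert np.allclose(smooth_field(field, kern).K, 1.7)

    def test_step_profile_matches_bruteforce(self, pv_model):
        """13-voxel Ca kernel on a step field vs a nested-loop weighted sum
        with border renormalization."""
        K = np.zeros((30, 1, 24))
        K[15:] = 2.0
        field = self._field(K)
        kern = kernel_for_line(pv_model, 3.7, 6.0)
        sm = smooth_field(field, kern)

        offsets, weights = kern.offsets, kern.weights
        for x, z in [(0, 0), (3, 11), (14, 12), (15, 5), (29, 23), (10, 0)]:
            num = den = 0.0
            for (dx, dz), w in zip(offsets, weights):
                xx, zz = x + dx, z + dz
                if 0 <= xx < 30 and 0 <= zz < 24:
                    num += w * K[xx, 0, zz]
                    den += w
            assert sm.K[x, 0, z] == pytest.approx(num / den, rel=1e-12)

    def test_3d_kernel_on_volume(self, pv_model):
        K = np.zeros((12, 12, 12))
        K[6:] = 1.0
        field = self._field(K)
        kern = kernel_for_line(pv_model, 14.2, 6.0, ndim=3)
        sm = smooth_field(field, kern)
        assert sm.K.shape == K.shape
        assert 0.0 < sm.K[6, 6, 6] < 1.0


class TestApplyCorrection:
    def _map(self, values, grid=None, **kw):
        grid = grid or VoxelGrid.isotropic(values.shape, 6.0)
        return IntensityMap(line=ZN, grid=grid, values=values, **kw)

    def test_zero_exponent_is_identity(self):
        v = np.random.default_rng(1).uniform(0, 50, (6, 1, 6))
        meas = self._map(v)
        field = co.CorrectionField(ZN, meas.grid, np.zeros_like(v))
        out = apply_correction(meas, field)
        assert np.allclose(out.values, v)

    def test_ln2_doubles_intensity(self):
        v = np.full((4, 1, 4), 10.0)
        meas = self._map(v)
        field = co.CorrectionField(ZN, meas.grid, np.full_like(v, np.log(2.0)))
        assert np.allclose(apply_correction(meas, field).values, 20.0)

    def test_masked_voxels_keep_measured_values(self):
        v = np.full((4, 1, 4), 10.0)
        meas = self._map(v)
        field = co.CorrectionField(ZN, meas.grid, np.full_like(v, 1.0))
        mask = np.zeros(v.shape, dtype=bool)
        mask[0, 0, 0] = True
        out = apply_correction(meas, field, mask)
        assert out.values[0, 0, 0] == pytest.approx(10.0 * np.e)
        assert out.values[1, 0, 1] == 10.0          # untouched, not zeroed
        assert not out.valid[1, 0, 1]
        assert np.isnan(out.masked_values()[1, 0, 1])

    def test_corrected_never_below_measured(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 100, (8, 1, 8))
        meas = self._map(v)
        field = co.CorrectionField(ZN, meas.grid, rng.uniform(0, 3, v.shape))
        assert np.all(apply_correction(meas, field).values >= v - 1e-12)

    def test_grid_mismatch_rejected(self):
        meas = self._map(np.zeros((4, 1, 4)))
        field = co.CorrectionField(
            ZN, VoxelGrid.isotropic((4, 1, 4), 7.0), np.zeros((4, 1, 4))
        )
        with pytest.raises(ValueError, match="grids differ"):
            apply_correction(meas, field)


class TestCountingMask:
    def _map_with_counts(self, counts):
        c = np.asarray(counts, dtype=float).reshape(1, 1, -1)
        grid = VoxelGrid.isotropic(c.shape, 6.0)
        return IntensityMap(ZN, grid, values=c / 10.0, counts=c, livetime_s=10.0)

    def test_poisson_cutoff_boundary(self):
        """N = 100 sits exactly on the 10% error bound and is excluded;
        N = 101 is included; N = 0 is excluded."""
        meas = self._map_with_counts([100, 101, 0, 5000])
        mask = counting_mask(meas)
        assert mask.ravel().tolist() == [False, True, False, True]

    def test_requires_counts(self):
        grid = VoxelGrid.isotropic((1, 1, 2), 6.0)
        meas = IntensityMap(ZN, grid, values=np.ones(grid.shape))
        with pytest.raises(ValueError, match="counts"):
            counting_mask(meas)


class TestRoiStatistics:
    def test_constant_map(self):
        grid = VoxelGrid.isotropic((6, 1, 6), 6.0)
        meas = IntensityMap(ZN, grid, values=np.full(grid.shape, 4.2))
        assert roi_mean(meas, (slice(1, 5), slice(0, 1), slice(1, 5))) == 4.2

    def test_half_masked_checkerboard(self):
        """4x4 checkerboard, mask keeps only the 'white' cells."""
        v = np.zeros((4, 1, 4))
        mask = np.zeros((4, 1, 4), dtype=bool)
        for i in range(4):
            for k in range(4):
                v[i, 0, k] = 10.0 if (i + k) % 2 == 0 else 99.0
                mask[i, 0, k] = (i + k) % 2 == 0
        grid = VoxelGrid.isotropic(v.shape, 6.0)
        meas = IntensityMap(ZN, grid, values=v)
        full = (slice(0, 4), slice(0, 1), slice(0, 4))
        assert roi_mean(meas, full, mask) == pytest.approx(10.0)

    def test_ramp_midpoint(self):
        v = np.tile(np.arange(8.0).reshape(1, 1, 8), (4, 1, 1))
        grid = VoxelGrid.isotropic(v.shape, 6.0)
        meas = IntensityMap(ZN, grid, values=v)
        assert roi_mean(meas, (slice(0, 4), slice(0, 1), slice(0, 8))) == 3.5

    def test_empty_valid_set_rejected(self):
        grid = VoxelGrid.isotropic((4, 1, 4), 6.0)
        meas = IntensityMap(ZN, grid, values=np.ones(grid.shape))
        with pytest.raises(ValueError, match="valid"):
            roi_mean(meas, (slice(0, 2), slice(0, 1), slice(0, 2)),
                     np.zeros(grid.shape, dtype=bool))


class TestOrientationDeviation:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1320.0, 1350.0, 1.1),   # Ca Ka corrected means
            (2.8, 2.8, 0.0),         # Zn Ka
            (730.0, 660.0, 5.0),     # Ba La
            (300.0, 250.0, 9.1),     # Yb La
        ],
    )
    def test_reported_deviations(self, a, b, expected):
        assert orientation_deviation(a, b) == pytest.approx(expected, abs=0.05)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            orientation_deviation(0.0, 0.0)


class TestHdf5IO:
    def test_roundtrip_with_invalid_voxels(self, tmp_path):
        grid = VoxelGrid.isotropic((5, 1, 4), 6.0)
        counts = np.random.default_rng(3).poisson(500.0, grid.shape)
        valid = counts > 480
        meas = IntensityMap(
            ZN, grid, values=counts / 20.0, counts=counts, livetime_s=20.0,
            valid=valid,
        )
        arr = np.ones(grid.shape, dtype=np.int64)
        labels = LabelVolume(grid, arr)
        path = tmp_path / "maps.h5"
        co.save_maps(path, {"Zn_Ka": meas}, labels=labels)
        back, lab = co.load_maps(path)
        assert set(back) == {"Zn_Ka"}
        m = back["Zn_Ka"]
        assert np.array_equal(m.valid, valid)
        assert np.allclose(m.values[valid], meas.values[valid])
        assert m.line.energy_keV == pytest.approx(ZN.energy_keV)
        assert np.array_equal(lab.labels, arr)
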