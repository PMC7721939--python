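"""Voxel dosimetry: calibration, cumulation, LDM, DPK, kernels."""

import numpy as np
import pytest

from y90dosim import (
    ActivityMap,
    CountImage,
    CumulatedActivityMap,
    DoseKernel,
    GridGeometry,
    PhysicsConstants,
    TreatmentRecord,
    build_default_kernel,
    calibrate_activity,
    cumulate,
    dpk_dose,
    ldm_dose,
    ldm_s_value,
    load_kernel,
    save_kernel,
)


def delta_kernel(side_mm: float, constants: PhysicsConstants) -> DoseKernel:
    s = np.zeros((3, 3, 3))
    s[1, 1, 1] = ldm_s_value(side_mm, constants)
    return DoseKernel(s_values=s, voxel_spacing_mm=side_mm)


def brute_force_convolution(cum: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent six-level-loop convolution oracle with zero padding."""
    nx, ny, nz = cum.shape
    kx, ky, kz = kernel.shape
    cx, cy, cz = kx // 2, ky // 2, kz // 2
    out = np.zeros_like(cum)
    for tx in range(nx):
        for ty in range(ny):
            for tz in range(nz):
                acc = 0.0
                for sx in range(nx):
                    for sy in range(ny):
                        for sz in range(nz):
                            ix, iy, iz = tx - sx + cx, ty - sy + cy, tz - sz + cz
                            if 0 <= ix < kx and 0 <= iy < ky and 0 <= iz < kz:
                                acc += cum[sx, sy, sz] * kernel[ix, iy, iz]
                out[tx, ty, tz] = acc
    return out


class TestCalibration:
    def test_hand_evaluated_voxel_activity(self):
        g = GridGeometry((2, 1, 1), (4.48,) * 3)
        counts = CountImage(geometry=g, values=np.array([[[100.0]], [[9900.0]]]))
        wl = np.ones(g.shape, dtype=bool)
        tr = TreatmentRecord(activity_Y90_GBq=2.0, lsf_percent=10.0)
        act = calibrate_activity(counts, wl, tr)
        assert act.values[0, 0, 0] == pytest.approx(
            100.0 * 0.9 * 2.0 / 10000.0, rel=1e-12
        )
        assert act.values[0, 0, 0] == pytest.approx(0.018)

    def test_activity_conservation_over_wl(self, rng):
        g = GridGeometry((8, 8, 8), (4.48,) * 3)
        counts = CountImage(geometry=g, values=rng.uniform(0, 50, g.shape))
        wl = np.zeros(g.shape, dtype=bool)
        wl[2:6, 2:6, 2:6] = True
        tr = TreatmentRecord(activity_Y90_GBq=1.7, lsf_percent=8.2)
        act = calibrate_activity(counts, wl, tr)
        assert act.values.sum() == pytest.approx(
            tr.liver_activity_GBq, rel=1e-12
        )
        assert np.all(act.values[~wl] == 0.0)

    def test_zero_liver_counts_error(self):
        g = GridGeometry((2, 2, 2), (4.48,) * 3)
        counts = CountImage(geometry=g, values=np.zeros(g.shape))
        with pytest.raises(ValueError):
            calibrate_activity(
                counts, np.ones(g.shape, bool), TreatmentRecord(1.0)
            )


class TestCumulation:
    def test_hand_evaluated_cumulated_activity(self):
        g = GridGeometry((1, 1, 1), (4.48,) * 3)
        act = ActivityMap(geometry=g, values=np.full(g.shape, 0.018))
        cum = cumulate(act)
        assert cum.values[0, 0, 0] == pytest.approx(6003.1, abs=0.05)

    def test_linearity_in_half_life(self):
        g = GridGeometry((1, 1, 1), (4.48,) * 3)
        act = ActivityMap(geometry=g, values=np.ones(g.shape))
        doubled = PhysicsConstants(half_life_h=2 * 64.2)
        assert cumulate(act, doubled).values[0, 0, 0] == pytest.approx(
            2 * cumulate(act).values[0, 0, 0], rel=1e-14
        )


class TestLdmSValue:
    def test_conventional_value_at_1_03(self):
        assert ldm_s_value(4.48) == pytest.approx(1.603, abs=5e-4)

    def test_unit_density_value(self):
        c = PhysicsConstants(voxel_density_g_per_mL=1.0)
        assert ldm_s_value(4.48, c) == pytest.approx(1.651, abs=5e-4)

    def test_inverse_volume_scaling(self):
        assert ldm_s_value(8.96) == pytest.approx(ldm_s_value(4.48) / 8, rel=1e-12)


class TestLdmDose:
    def test_scalar_multiply(self):
        g = GridGeometry((2, 2, 2), (4.48,) * 3)
        cum = CumulatedActivityMap(geometry=g, values=np.full(g.shape, 0.1))
        dose = ldm_dose(cum)
        assert dose.values[0, 0, 0] == pytest.approx(0.1 * ldm_s_value(4.48))
        assert dose.values[0, 0, 0] == pytest.approx(0.1603, abs=1e-4)

    def test_zero_in_zero_out(self):
        g = GridGeometry((3, 3, 3), (4.48,) * 3)
        cum = CumulatedActivityMap(geometry=g, values=np.zeros(g.shape))
        assert np.all(ldm_dose(cum).values == 0.0)

    def test_non_cubic_voxels_rejected(self):
        g = GridGeometry((2, 2, 2), (4.48, 4.48, 5.0))
        cum = CumulatedActivityMap(geometry=g, values=np.zeros(g.shape))
        with pytest.raises(ValueError, match="cubic"):
            ldm_dose(cum)

    def test_energy_conservation_over_wl(self, rng):
        """Sum(dose x voxel mass) equals the released beta energy."""
        c = PhysicsConstants()
        g = GridGeometry((6, 6, 6), (4.48,) * 3)
        counts = CountImage(geometry=g, values=rng.uniform(0, 10, g.shape))
        wl = np.ones(g.shape, bool)
        tr = TreatmentRecord(activity_Y90_GBq=1.2, lsf_percent=5.0)
        dose = ldm_dose(cumulate(calibrate_activity(counts, wl, tr), c), c)
        voxel_mass_kg = (
            g.voxel_volume_mL * c.effective_voxel_density_g_per_mL / 1000.0
        )
        energy_J = float(dose.values.sum()) * voxel_mass_kg
        expected = (
            c.energy_rate_J_per_GBq_s
            * c.cumulation_factor_s
            * tr.liver_activity_GBq
        )
        assert energy_J == pytest.approx(expected, rel=1e-12)


class TestDpk:
    def test_delta_kernel_reproduces_ldm(self, rng):
        c = PhysicsConstants()
        g = GridGeometry((5, 5, 5), (4.48,) * 3)
        cum = CumulatedActivityMap(geometry=g, values=rng.uniform(0, 1, g.shape))
        dpk = dpk_dose(cum, delta_kernel(4.48, c))
        ldm = ldm_dose(cum, c)
        np.testing.assert_allclose(dpk.values, ldm.values, rtol=1e-13)

    @pytest.mark.parametrize("shape,kshape", [((3, 3, 3), 3), ((6, 5, 4), 3),
                                              ((8, 8, 8), 5)])
    def test_matches_brute_force_oracle(self, rng, shape, kshape):
        g = GridGeometry(shape, (4.48,) * 3)
        cum_values = rng.uniform(0, 2, shape)
        kernel_values = rng.uniform(0, 0.5, (kshape,) * 3)
        kernel = DoseKernel(s_values=kernel_values, voxel_spacing_mm=4.48)
        got = dpk_dose(
            CumulatedActivityMap(geometry=g, values=cum_values), kernel
        ).values
        want = brute_force_convolution(cum_values, kernel_values)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_uniform_field_center_dose_is_activity_times_kernel_sum(self):
        c = PhysicsConstants()
        kernel = build_default_kernel(4.48, c, seed=3, n_samples=20000)
        r = kernel.s_values.shape[0] // 2
        n = 4 * r + 3  # interior voxel farther than the kernel reach
        g = GridGeometry((n, n, n), (4.48,) * 3)
        cum = CumulatedActivityMap(geometry=g, values=np.full((n, n, n), 0.2))
        dose = dpk_dose(cum, kernel)
        assert dose.values[n // 2, n // 2, n // 2] == pytest.approx(
            0.2 * kernel.s_values.sum(), rel=1e-12
        )

    def test_energy_conserved_on_padded_grid(self, rng):
        """With exact kernel closure, padding far enough loses nothing."""
        c = PhysicsConstants()
        kernel = build_default_kernel(4.48, c, seed=3, n_samples=20000)
        r = kernel.s_values.shape[0] // 2
        core = rng.uniform(0, 1, (4, 4, 4))
        padded = np.pad(core, r)
        g = GridGeometry(padded.shape, (4.48,) * 3)
        dose = dpk_dose(CumulatedActivityMap(geometry=g, values=padded), kernel)
        voxel_mass_kg = (
            g.voxel_volume_mL * c.effective_voxel_density_g_per_mL / 1000.0
        )
        energy = dose.values.sum() * voxel_mass_kg
        # total energy = total cumulated activity x energy rate
        expected = core.sum() * c.energy_rate_J_per_GBq_s
        assert energy == pytest.approx(expected, rel=1e-3)

    def test_spacing_mismatch_rejected(self):
        g = GridGeometry((3, 3, 3), (4.0,) * 3)
        cum = CumulatedActivityMap(geometry=g, values=np.zeros(g.shape))
        kernel = DoseKernel(s_values=np.zeros((3, 3, 3)), voxel_spacing_mm=4.48)
        with pytest.raises(ValueError, match="spacing"):
            dpk_dose(cum, kernel)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            DoseKernel(s_values=np.zeros((4, 3, 3)), voxel_spacing_mm=4.48)


class TestDefaultKernel:
    def test_energy_closure_exact(self):
        c = PhysicsConstants()
        kernel = build_default_kernel(4.48, c, seed=0, n_samples=20000)
        assert kernel.energy_closure_ratio(c) == pytest.approx(1.0, rel=1e-12)

    def test_center_below_local_deposition_s(self):
        c = PhysicsConstants()
        kernel = build_default_kernel(4.48, c, seed=0, n_samples=20000)
        assert kernel.center_value < ldm_s_value(4.48, c)

    def test_same_seed_bit_identical(self):
        a = build_default_kernel(4.48, seed=11, n_samples=20000)
        b = build_default_kernel(4.48, seed=11, n_samples=20000)
        assert np.array_equal(a.s_values, b.s_values)

    def test_covers_max_beta_range(self):
        kernel = build_default_kernel(4.48, seed=0, n_samples=1000)
        r = kernel.s_values.shape[0] // 2
        assert r * 4.48 >= 11.0 - 4.48

    def test_side_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_default_kernel(0.5)


class TestKernelIo:
    def test_round_trip_lossless(self, tmp_path):
        kernel = build_default_kernel(4.48, seed=5, n_samples=20000)
        path = tmp_path / "kernel.txt"
        save_kernel(kernel, path)
        loaded = load_kernel(path)
        assert loaded.voxel_spacing_mm == pytest.approx(
            kernel.voxel_spacing_mm, rel=1e-12
        )
        np.testing.assert_allclose(
            loaded.s_values, kernel.s_values, rtol=1e-12
        )

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("3 3 spacing\n")
        with pytest.raises(ValueError, match="line 1"):
            load_kernel(path)

    def test_payload_size_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("3 3 3 4.48\n1 2 3\n")
        with pytest.raises(ValueError, match="data lines"):
            load_kernel(path)

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        rows = "\n".join("0 0 0" for _ in range(9))
        path.write_text("3 3 3 4.48\n" + rows.replace("0 0 0", "-1 0 0", 1) + "\n")
        with pytest.raises(ValueError, match="non-negative"):
            load_kernel(path)
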