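"""MR dephasing Monte Carlo: anchors, monotonicity, oracles, prediction."""

import dataclasses

import numpy as np
import pytest

import oisbold as ob
from oisbold.containers import HaemodynamicField
from oisbold.mr_attenuation import (build_bold_lut, ev_delta_r2star,
                                    load_bold_lut, predict_bold,
                                    save_bold_lut, y0_sweep)


def static_dephasing_oracle(v, y, y0, radius_um, mr, seed, n_samples=40_000,
                            n_geoms=40):
    """No-diffusion oracle: numerical average of exp(i*phi(TE)) over
    random cylinder orientations and static proton positions, using the
    analytic inside/outside field of an infinite cylinder."""
    rng = np.random.default_rng(seed)
    gb0 = mr.gamma_rad_per_s_per_T * mr.b0_T
    box = 20.0 * radius_um

    def signal(dchi):
        acc = []
        for _ in range(n_geoms):
            local = np.random.default_rng(rng.integers(2**31))
            # cylinders to the requested volume (area-fraction estimate)
            centers, axes = [], []
            pts = local.uniform(0, box, size=(20_000, 3))
            inside = np.zeros(len(pts), bool)
            while inside.mean() < v:
                pc = local.uniform(0, box, 3)
                zc = local.uniform(-1, 1)
                ph = local.uniform(0, 2 * np.pi)
                s = np.sqrt(1 - zc * zc)
                u = np.array([s * np.cos(ph), s * np.sin(ph), zc])
                centers.append(pc)
                axes.append(u)
                d = pts - pc
                d -= box * np.round(d / box)
                proj = d @ u
                inside |= (d * d).sum(1) - proj**2 <= radius_um**2
            pos = local.uniform(0, box, size=(n_samples // n_geoms, 3))
            omega = np.zeros(len(pos))
            keep = np.ones(len(pos), bool)
            for pc, u in zip(centers, axes):
                d = pos - pc
                d -= box * np.round(d / box)
                proj = d @ u
                dp = d - proj[:, None] * u
                rho2 = (dp * dp).sum(1)
                inside_c = rho2 <= radius_um**2
                keep &= ~inside_c
                b = np.array([0.0, 0.0, 1.0]) - u[2] * u
                nb = np.linalg.norm(b)
                e1 = b / nb if nb > 1e-12 else np.array([1.0, 0.0, 0.0])
                e2 = np.cross(u, e1)
                a1 = dp @ e1
                a2 = dp @ e2
                with np.errstate(divide="ignore", invalid="ignore"):
                    w = 2 * np.pi * (1 - u[2]**2) * radius_um**2 / rho2 \
                        * (a1**2 - a2**2) / rho2
                omega += np.where(inside_c,
                                  (2 * np.pi / 3) * (3 * u[2]**2 - 1),
                                  np.nan_to_num(w))
            phi = gb0 * dchi * omega[keep] * mr.te_s
            acc.append(np.exp(1j * phi).mean())
        return abs(np.mean(acc))

    return -np.log(signal(mr.dchi(y)) / signal(mr.dchi(y0))) / mr.te_s


class TestDeltaR2star:
    def test_baseline_anchor_exact_zero(self, mr_small):
        assert ev_delta_r2star(mr_small.v0, mr_small.y0, 10.0, mr_small,
                               seed=3) == 0.0

    def test_more_deoxygenation_more_dephasing(self, mr_small):
        d = ev_delta_r2star(0.06, 0.4, 10.0, mr_small, seed=3)
        assert d > 0.0

    def test_gradient_echo_plateau_above_15um(self):
        mr = ob.MRSimConfig(n_protons=6000, n_geometries=12)
        d15 = ev_delta_r2star(0.06, 0.4, 15.0, mr, seed=21)
        d20 = ev_delta_r2star(0.06, 0.4, 20.0, mr, seed=22)
        assert d20 == pytest.approx(d15, rel=0.10)

    def test_large_radius_matches_static_dephasing_oracle(self):
        # r = 50 um: diffusion is negligible; compare against the
        # independent no-diffusion average (coded separately above)
        mr = ob.MRSimConfig(n_protons=8000, n_geometries=16,
                            d_water_m2_per_s=1e-16)
        mc = ev_delta_r2star(0.06, 0.4, 50.0, mr, seed=31)
        oracle = static_dephasing_oracle(0.06, 0.4, 0.5, 50.0, mr, seed=99)
        assert mc == pytest.approx(oracle, rel=0.15)

    def test_input_validation(self, mr_small):
        with pytest.raises(ValueError):
            ev_delta_r2star(0.5, 0.5, 10.0, mr_small)
        with pytest.raises(ValueError):
            ev_delta_r2star(0.06, 1.5, 10.0, mr_small)

    def test_few_protons_warns(self, mr_small):
        with pytest.warns(UserWarning, match="protons"):
            ev_delta_r2star(0.06, 0.4, 10.0, mr_small, seed=1, n_protons=50)

    def test_reflection_robustness(self):
        mr_on = ob.MRSimConfig(n_protons=6000, n_geometries=12, reflect=True)
        mr_off = dataclasses.replace(mr_on, reflect=False)
        a = ev_delta_r2star(0.06, 0.4, 10.0, mr_on, seed=13)
        b = ev_delta_r2star(0.06, 0.4, 10.0, mr_off, seed=13)
        # spins admitted into vessels see the strong intravascular field,
        # so the difference is real but stays modest at V = 0.06
        assert b == pytest.approx(a, rel=0.10)


class TestBoldLUT:
    def test_node_accessor_exact(self, bold_lut_small):
        lut = bold_lut_small
        iv, iy, ir = 3, 5, 1
        got = lut._interp(lut.v_grid[iv], lut.y_grid[iy], lut.r_grid[ir])
        assert got == pytest.approx(lut.r2star[iv, iy, ir], abs=1e-12)

    def test_baseline_delta_zero(self, bold_lut_small, mr_small):
        assert bold_lut_small.delta_r2star(mr_small.v0, mr_small.y0,
                                           10.0) == 0.0

    def test_monotone_in_deoxygenation(self, bold_lut_small):
        # decreasing Y at fixed V, r: dR2* non-decreasing
        for iv in (1, 4, 6):
            col = bold_lut_small.r2star[iv, :, 1]
            assert np.all(np.diff(col) <= 1e-9)   # y_grid ascending

    def test_monotone_in_volume_at_low_saturation(self, bold_lut_small):
        iy = 2                                     # Y ~ 0.3 < Y0
        col = bold_lut_small.r2star[:, iy, 1]
        assert np.all(np.diff(col) >= -1e-9)

    def test_linear_in_deoxy_content(self, bold_lut_small, mr_small):
        # dR2* approximately linear in (1-Y)*V over the physiological range
        lut = bold_lut_small
        vv, yy = np.meshgrid(lut.v_grid, lut.y_grid, indexing="ij")
        x = ((1 - yy) * vv).ravel()
        z = lut.r2star[:, :, 1].ravel()
        r = np.corrcoef(x, z)[0, 1]
        assert r**2 > 0.95

    def test_grid_must_cover_baseline(self, mr_small):
        with pytest.raises(ValueError):
            build_bold_lut(mr_small, v_grid=np.linspace(0.08, 0.12, 3))

    def test_roundtrip(self, tmp_path, bold_lut_small, mr_small):
        p = tmp_path / "bold.h5"
        save_bold_lut(p, bold_lut_small)
        back = load_bold_lut(p, mr_small)
        assert np.array_equal(back.r2star, bold_lut_small.r2star)
        assert back.config_hash == bold_lut_small.config_hash


class TestPredictBold:
    def test_zero_field_zero_prediction(self, baseline_hom, bold_lut_small,
                                        mr_small):
        f = HaemodynamicField.from_components(np.zeros((4, 3, 3)),
                                              np.zeros((4, 3, 3)))
        pred = predict_bold(f, baseline_hom, bold_lut_small, mr_small)
        assert np.all(pred.central == 0.0)
        assert np.all(pred.upper == 0.0) and np.all(pred.lower == 0.0)

    def test_surround_signature_negative_bold(self, baseline_hom,
                                              bold_lut_small, mr_small):
        # Hbr up with HbT down: the negative BOLD generator
        hbr = np.full((4, 2, 2), 2.5)
        hbo2 = np.full((4, 2, 2), -7.5)
        f = HaemodynamicField.from_components(hbo2, hbr)
        pred = predict_bold(f, baseline_hom, bold_lut_small, mr_small)
        assert np.all(pred.central < 0.0)

    def test_envelope_contains_intermediate_radius(self, baseline_hom,
                                                   bold_lut_small, mr_small):
        rng = np.random.default_rng(0)
        hbo2 = rng.uniform(-5, 10, size=(6, 4, 4))
        hbr = rng.uniform(-4, 2, size=(6, 4, 4))
        f = HaemodynamicField.from_components(hbo2, hbr)
        pred = predict_bold(f, baseline_hom, bold_lut_small, mr_small)
        assert np.all(pred.lower <= pred.central + 1e-12)
        assert np.all(pred.central <= pred.upper + 1e-12)
        hbt0 = baseline_hom.hbt0_uM[0]
        v = mr_small.v0 * (hbt0 + f.d_hbt) / hbt0
        y = np.clip((baseline_hom.hbo2_0_uM[0] + f.d_hbo2) / (hbt0 + f.d_hbt),
                    0, 1)
        mid = np.exp(-bold_lut_small.delta_r2star(v, y, 12.0)
                     * mr_small.te_s) - 1.0
        assert np.all(mid >= pred.lower - 1e-9)
        assert np.all(mid <= pred.upper + 1e-9)

    def test_saturation_clipping_flagged(self, baseline_hom, bold_lut_small,
                                         mr_small):
        hbo2 = np.full((2, 2, 2), 10.0)
        hbr = np.full((2, 2, 2), -60.0)       # pushes Y above 1
        f = HaemodynamicField.from_components(hbo2, hbr)
        pred = predict_bold(f, baseline_hom, bold_lut_small, mr_small)
        assert pred.clipped_fraction == 1.0


class TestY0Sweep:
    def test_single_element_grid(self, small_stack, light_lut_hom, tissue_hom,
                                 optics):
        mr = ob.MRSimConfig(n_protons=800, n_geometries=2)
        table, argmax = y0_sweep(small_stack, light_lut_hom, tissue_hom, mr,
                                 [0.5], optics=optics, seed=1, n_protons=800)
        assert argmax == 0.5
        assert len(table) == 1

    def test_empty_or_invalid_grid(self, small_stack, light_lut_hom,
                                   tissue_hom, optics):
        mr = ob.MRSimConfig(n_protons=800)
        with pytest.raises(ValueError):
            y0_sweep(small_stack, light_lut_hom, tissue_hom, mr, [],
                     optics=optics)
        with pytest.raises(ValueError):
            y0_sweep(small_stack, light_lut_hom, tissue_hom, mr, [0.0, 0.5],
                     optics=optics)
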