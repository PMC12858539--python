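"""Index panel: analytic oracles, bounds, identities, convergence order."""

import numpy as np
import pytest

from coroshear import (
    HemoConfig,
    StenosisSpec,
    ValidationError,
    compute_ctffr,
    compute_gon,
    compute_helicity,
    compute_osi,
    compute_rrt,
    compute_tawss,
    compute_vorticity,
    compute_wssg,
    make_flow_waveform,
    make_stenotic_vessel,
    make_volume_field_series,
    make_wall_field_series,
    solve_reduced_order,
)
from coroshear.hemofields import WallFieldSeries
from tests.conftest import MU, Q, R, TAU_POISEUILLE


def _synthetic_wall(geom, times, wss, inlet_p=1.0e4):
    nt = len(times)
    return WallFieldSeries(
        times=np.asarray(times, dtype=float),
        wss=wss,
        pressure=np.zeros((nt, len(geom.vertex_s))),
        vertex_s=geom.vertex_s,
        inlet_pressure=np.full(nt, inlet_p),
        geom=geom,
    )


class TestTawss:
    def test_constant_shear(self, uniform_tube):
        t = np.linspace(0, 0.8, 9)
        tang = uniform_tube.axial_tangents()
        wss = 2.0 * np.broadcast_to(tang, (9, *tang.shape)).copy()
        wall = _synthetic_wall(uniform_tube, t, wss)
        assert np.allclose(compute_tawss(wall), 2.0)

    def test_rectified_sinusoid_mean(self, uniform_tube):
        # |sin| averages to 2/pi; fine grid so trapezoid error is negligible
        t = np.linspace(0, 1.0, 20001)
        tang = uniform_tube.axial_tangents()
        tau = np.sin(2 * np.pi * t)[:, None, None] * tang[None, :, :]
        wall = _synthetic_wall(uniform_tube, t, tau)
        assert np.allclose(compute_tawss(wall), 2 / np.pi, rtol=1e-6)

    def test_steady_poiseuille_value(self, steady_wall):
        assert np.allclose(compute_tawss(steady_wall), TAU_POISEUILLE, rtol=1e-9)

    def test_nonuniform_grid_rejected(self, uniform_tube):
        t = np.array([0.0, 0.1, 0.5, 0.8])
        wss = np.zeros((4, len(uniform_tube.vertex_s), 3))
        wall = WallFieldSeries.__new__(WallFieldSeries)  # bypass ctor check
        wall.times = t
        wall.wss = wss
        wall.pressure = np.zeros((4, len(uniform_tube.vertex_s)))
        wall.vertex_s = uniform_tube.vertex_s
        wall.inlet_pressure = np.full(4, 1e4)
        wall.geom = uniform_tube
        with pytest.raises(ValidationError):
            compute_tawss(wall)


class TestOsi:
    def test_unidirectional_pulsatile_is_zero(self, uniform_tube, pulsatile_waveform):
        wall = make_wall_field_series(uniform_tube, pulsatile_waveform, viscosity=MU)
        osi = compute_osi(wall)
        assert np.nanmax(osi) < 1e-12

    def test_zero_mean_sinusoid_is_half(self, uniform_tube, pulsatile_waveform):
        wall = make_wall_field_series(
            uniform_tube, pulsatile_waveform, mode="zero_mean_oscillatory"
        )
        osi = compute_osi(wall)
        assert np.nanmin(osi) == pytest.approx(0.5, abs=1e-9)

    def test_mixed_direction_matches_dense_quadrature(self):
        # tau(t) = e_x (1 + cos wt) + e_y sin wt on a 10^4-point grid vs a
        # direct quadrature oracle of the same closed form
        geom = make_stenotic_vessel(StenosisSpec(severity=0.0), 10, 8)
        T = 1.0
        n = 10_000
        td = np.linspace(0, T, n + 1)
        w = 2 * np.pi / T
        tau_dense = np.stack([1 + np.cos(w * td), np.sin(w * td)], axis=1)
        num = np.linalg.norm(np.trapezoid(tau_dense, td, axis=0))
        den = np.trapezoid(np.linalg.norm(tau_dense, axis=1), td)
        oracle = 0.5 * (1 - num / den)

        tang = geom.axial_tangents()
        circ = np.cross(geom.normals, tang)
        tau = (1 + np.cos(w * td))[:, None, None] * tang[None] + np.sin(w * td)[
            :, None, None
        ] * circ[None]
        wall = _synthetic_wall(geom, td, tau)
        osi = compute_osi(wall)
        assert np.allclose(osi, oracle, atol=1e-6)

    def test_zero_shear_flagged_nan(self, uniform_tube):
        t = np.linspace(0, 1, 5)
        wss = np.zeros((5, len(uniform_tube.vertex_s), 3))
        wall = _synthetic_wall(uniform_tube, t, wss)
        assert np.all(np.isnan(compute_osi(wall)))


class TestRrt:
    @pytest.mark.parametrize("osi,tawss,expected", [(0.0, 2.0, 0.5), (0.25, 1.0, 2.0)])
    def test_closed_form_values(self, osi, tawss, expected):
        rrt = compute_rrt(np.array([tawss]), np.array([osi]))
        assert rrt[0] == pytest.approx(expected, abs=1e-12)

    def test_identity_on_random_instances(self, uniform_tube):
        rng = np.random.default_rng(1234)
        tang = uniform_tube.axial_tangents()
        circ = np.cross(uniform_tube.normals, tang)
        for _ in range(100):
            nt = int(rng.integers(8, 32)) * 2 + 1
            t = np.linspace(0, 1, nt)
            a, b, c = rng.uniform(0.2, 2.0, 3)
            tau = (a + b * np.cos(2 * np.pi * t))[:, None, None] * tang[None] + (
                c * np.sin(2 * np.pi * t)
            )[:, None, None] * circ[None]
            wall = _synthetic_wall(uniform_tube, t, tau)
            tawss = compute_tawss(wall)
            osi = compute_osi(wall)
            rrt = compute_rrt(tawss, osi)
            finite = np.isfinite(rrt)
            prod = rrt[finite] * (1 - 2 * osi[finite]) * tawss[finite]
            assert np.allclose(prod, 1.0, atol=1e-9)

    def test_singular_inputs_flagged_infinite(self):
        rrt = compute_rrt(np.array([2.0, 0.0]), np.array([0.5, 0.1]))
        assert np.isinf(rrt[0]) and np.isinf(rrt[1])


class TestGradientIndices:
    def test_uniform_field_zero_wssg(self, uniform_tube):
        t = np.linspace(0, 1, 5)
        tang = uniform_tube.axial_tangents()
        wss = 1.5 * np.broadcast_to(tang, (5, *tang.shape)).copy()
        wall = _synthetic_wall(uniform_tube, t, wss)
        assert np.abs(compute_wssg(wall, uniform_tube)).max() < 1e-9

    def test_straight_tube_poiseuille_wssg_zero(self, steady_wall, uniform_tube):
        assert np.abs(compute_wssg(steady_wall, uniform_tube)).max() < 1e-6

    def test_linear_ramp_slope_recovered(self, uniform_tube):
        a = 3.0  # Pa/m
        t = np.linspace(0, 1, 5)
        tang = uniform_tube.axial_tangents()
        tau = (a * uniform_tube.vertex_s)[None, :, None] * tang[None] * np.ones(
            (5, 1, 1)
        )
        wall = _synthetic_wall(uniform_tube, t, tau)
        wssg = compute_wssg(wall, uniform_tube)
        assert np.abs(wssg - a).max() / a < 0.02

    def test_steady_flow_gon_zero(self, steady_wall, uniform_tube):
        gon = compute_gon(steady_wall, uniform_tube)
        ok = np.isfinite(gon)
        assert np.all(gon[ok] < 1e-9)

    def test_alternating_gradient_gon_one(self, uniform_tube):
        t = np.linspace(0, 1, 9)
        sign = np.where(np.arange(9) % 2 == 0, 1.0, -1.0)
        tang = uniform_tube.axial_tangents()
        tau = (2.0 * uniform_tube.vertex_s)[None, :, None] * tang[None] * sign[
            :, None, None
        ]
        wall = _synthetic_wall(uniform_tube, t, tau)
        gon = compute_gon(wall, uniform_tube)
        assert np.nanmax(np.abs(gon - 1.0)) < 1e-9

    def test_mixed_gradient_matches_quadrature_oracle(self, uniform_tube):
        # steady + oscillatory axial shear ramp: the gradient time course
        # A(t) = a + b cos changes sign (b > a), so GON is strictly between
        # 0 and 1; package value vs direct dense-grid quadrature of |A|
        a, b = 0.5, 1.2
        n = 10_000
        t = np.linspace(0, 1, n + 1)
        A = a + b * np.cos(2 * np.pi * t)
        oracle = 1 - abs(np.trapezoid(A, t)) / np.trapezoid(np.abs(A), t)
        assert 0.05 < oracle < 0.95  # genuinely mixed regime

        geom = make_stenotic_vessel(StenosisSpec(severity=0.0), 10, 8)
        tang = geom.axial_tangents()
        s = geom.vertex_s
        tau = A[:, None, None] * s[None, :, None] * tang[None]
        wall = _synthetic_wall(geom, t, tau)
        gon = compute_gon(wall, geom)
        assert np.allclose(gon[np.isfinite(gon)], oracle, atol=1e-6)


class TestVorticityHelicity:
    def test_uniform_translation_zero_vorticity(self, uniform_tube):
        wf = make_flow_waveform(pulsatility_amplitude=0.0)
        vol = make_volume_field_series(uniform_tube, wf, radial_samples=8)
        vol.velocity[:] = np.array([0.0, 0.0, 0.1])  # overwrite with plug flow
        assert np.abs(compute_vorticity(vol)).max() < 1e-9

    def test_rigid_rotation_gives_two_omega(self, uniform_tube):
        still = make_flow_waveform(mean_flow=1e-300, pulsatility_amplitude=0.0)
        vol = make_volume_field_series(uniform_tube, still, swirl_rate=1.0, radial_samples=16)
        vt = compute_vorticity(vol)
        assert np.allclose(vt, 2.0, rtol=1e-6)

    def test_poiseuille_midradius_vorticity(self, uniform_tube, steady_waveform):
        vol = make_volume_field_series(
            uniform_tube, steady_waveform, radial_samples=100
        )
        vt = compute_vorticity(vol)
        i = np.argmin(np.abs(vol.param_r - R / 2))
        target_r = vol.param_r[i]
        expected = 4.0 * Q * target_r / (np.pi * R**4)
        sel = vol.param_r == target_r
        assert np.allclose(vt[sel], expected, rtol=1e-6)

    def test_helicity_zero_without_swirl(self, uniform_tube, pulsatile_waveform):
        vol = make_volume_field_series(uniform_tube, pulsatile_waveform)
        assert np.abs(compute_helicity(vol)).max() < 1e-12

    def test_helicity_matches_analytic_composition(self, uniform_tube, steady_waveform):
        vol = make_volume_field_series(
            uniform_tube, steady_waveform, swirl_rate=20.0, radial_samples=30
        )
        h_fd = compute_helicity(vol)
        # closed form: u_z * 2 Omega + (Omega rho) * (4 Q rho / (pi R^4))
        rho = vol.param_r
        u_z = 2 * Q / (np.pi * R**2) * (1 - (rho / R) ** 2)
        h_exact = u_z * 2 * 20.0 + (20.0 * rho) * (4 * Q * rho / (np.pi * R**4))
        assert np.abs(h_fd - h_exact).max() <= 0.02 * np.abs(h_exact).max()

    def test_swirl_reversal_flips_sign(self, uniform_tube, steady_waveform):
        vp = make_volume_field_series(uniform_tube, steady_waveform, swirl_rate=15.0)
        vm = make_volume_field_series(uniform_tube, steady_waveform, swirl_rate=-15.0)
        assert np.allclose(compute_helicity(vp), -compute_helicity(vm), rtol=1e-9)

    def test_second_order_time_convergence(self, uniform_tube):
        """Halving the time step shrinks the TAWSS quadrature error ~4x.

        The oscillatory regime integrates |sin|, whose kinks keep trapezoid
        integration at its generic second order (smooth periodic integrands
        converge faster and give no rate to measure).
        """
        errs = []
        for n in (16, 32, 64):
            wf = make_flow_waveform(
                mean_flow=Q, pulsatility_amplitude=0.5, samples_per_cycle=n
            )
            wall = make_wall_field_series(
                uniform_tube, wf, viscosity=MU, mode="zero_mean_oscillatory"
            )
            tawss = compute_tawss(wall)[0]
            errs.append(abs(tawss - TAU_POISEUILLE * 2 / np.pi))
        rate1 = errs[0] / errs[1]
        rate2 = errs[1] / errs[2]
        assert 3.5 < rate1 < 4.5 and 3.5 < rate2 < 4.5


class TestCtffr:
    def test_zero_flow_gives_unity(self, uniform_tube, hemo_config):
        still = make_flow_waveform(mean_flow=1e-300, pulsatility_amplitude=0.0)
        wall, _ = solve_reduced_order(uniform_tube, still, hemo_config)
        assert compute_ctffr(wall, uniform_tube, 0.01, hemo_config)["ctffr"] == pytest.approx(1.0)

    def test_constructed_ratio(self, uniform_tube):
        t = np.linspace(0, 1, 5)
        nv = len(uniform_tube.vertex_s)
        pressure = np.full((5, nv), 0.8e4)
        wall = WallFieldSeries(
            times=t,
            wss=np.zeros((5, nv, 3)),
            pressure=pressure,
            vertex_s=uniform_tube.vertex_s,
            inlet_pressure=np.full(5, 1e4),
            geom=uniform_tube,
        )
        assert compute_ctffr(wall, uniform_tube, 0.01)["ctffr"] == pytest.approx(0.8)

    def test_uniform_tube_closed_form(self, uniform_tube, steady_waveform, hemo_config):
        wall, _ = solve_reduced_order(uniform_tube, steady_waveform, hemo_config)
        res = compute_ctffr(wall, uniform_tube, lesion_distal_s=0.01, cfg=hemo_config)
        L = res["s_measure"]
        expected = 1 - 8 * MU * L * Q / (np.pi * R**4 * hemo_config.inlet_pressure_pa)
        assert res["ctffr"] == pytest.approx(expected, abs=1e-9)
        assert not res["clamped"]

    def test_distal_point_clamped_to_vessel_end(self, uniform_tube, steady_waveform, hemo_config):
        wall, _ = solve_reduced_order(uniform_tube, steady_waveform, hemo_config)
        res = compute_ctffr(wall, uniform_tube, lesion_distal_s=0.055, cfg=hemo_config)
        assert res["clamped"]
        assert res["s_measure"] == pytest.approx(uniform_tube.length)


def test_indices_invariant_under_rigid_rotation(stenotic_tube, pulsatile_waveform):
    """TAWSS/OSI/WSSG computed on a rotated copy match the original."""
    wall = make_wall_field_series(stenotic_tube, pulsatile_waveform, viscosity=MU, mode="mixed")
    th = 0.9
    Rm = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
    gt = stenotic_tube.transformed(Rm, np.array([0.01, 0.02, -0.03]))
    wall_rot = WallFieldSeries(
        times=wall.times,
        wss=wall.wss @ Rm.T,
        pressure=wall.pressure,
        vertex_s=wall.vertex_s,
        inlet_pressure=wall.inlet_pressure,
        geom=gt,
    )
    assert np.allclose(compute_tawss(wall_rot), compute_tawss(wall), rtol=1e-9)
    o1, o2 = compute_osi(wall), compute_osi(wall_rot)
    assert np.allclose(o1[np.isfinite(o1)], o2[np.isfinite(o2)], atol=1e-9)
    assert np.allclose(
        compute_wssg(wall_rot, gt), compute_wssg(wall, stenotic_tube), rtol=1e-6
    )
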