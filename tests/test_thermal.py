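"""Pennes bioheat solver and Arrhenius damage verification."""

import numpy as np
import pytest

from nanotherm.phantom import ProbeSet, make_phantom
from nanotherm.thermal import (
    ArrheniusParams,
    ThermalProps,
    arrhenius_damage,
    perfusion_heat,
    probe_timeseries,
    solve_bioheat,
)

from conftest import homogeneous_phantom


class TestPerfusionHeat:
    def test_zero_at_blood_temperature(self):
        props = ThermalProps()
        q = perfusion_heat(np.full((4, 4, 4), props.t_blood_C), props)
        assert np.all(q == 0.0)

    def test_zero_without_perfusion(self):
        props = ThermalProps(omega_b_per_s=0.0)
        q = perfusion_heat(np.full((4, 4, 4), 45.0), props)
        assert np.all(q == 0.0)

    def test_one_kelvin_excess_cools_at_profile_rate(self):
        # rho_b * C_b * omega_b = 1052 * 3800 * 0.01 = 39976 W/m3 per K
        props = ThermalProps()
        q = perfusion_heat(np.full((2, 2, 2), props.t_blood_C + 1.0), props)
        assert np.allclose(q, -39976.0)

    def test_as_printed_sign_flips(self):
        props = ThermalProps()
        t = np.full((2, 2, 2), 40.0)
        assert np.allclose(
            perfusion_heat(t, props, as_printed=True), -perfusion_heat(t, props)
        )


class TestSolveBioheat:
    def test_equilibrium_stays_constant(self):
        ph = homogeneous_phantom(10)
        props = ThermalProps(t_init_C=37.0, t_blood_C=37.0, t_amb_C=37.0)
        tf = solve_bioheat(ph, props, 0.0, duration_s=20.0, dt_s=1.0)
        assert np.allclose(tf.data_C[-1][ph.body_mask], 37.0, atol=1e-9)

    def test_perfusion_steady_state_closed_form(self):
        """Uniform heating of an insulated, perfused block: steady
        temperature rise equals Q_ext / (rho_b C_b omega_b)."""
        ph = homogeneous_phantom(8)
        props = ThermalProps()
        q = 4.0e4  # W/m3
        tf = solve_bioheat(ph, props, q, duration_s=1500.0, dt_s=5.0,
                           store_every_s=100.0, insulated=True)
        expected = props.t_init_C + q / (props.rho_b_kg_m3 * props.c_b_J_kgK * props.omega_b_per_s)
        assert np.allclose(tf.data_C[-1][ph.body_mask], expected, rtol=1e-5)

    def test_insulated_unperfused_block_conserves_energy(self):
        """With no losses, enthalpy gain equals injected energy."""
        ph = homogeneous_phantom(8)
        props = ThermalProps(omega_b_per_s=0.0, h_W_m2K=0.0)
        rng = np.random.default_rng(0)
        q = rng.uniform(0, 1e5, ph.shape)
        duration, dt = 30.0, 0.5
        tf = solve_bioheat(ph, props, q, duration_s=duration, dt_s=dt, insulated=True)
        vol = (ph.spacing_mm * 1e-3) ** 3
        enthalpy = (
            props.rho_kg_m3 * props.c_sp_J_kgK
            * np.sum(tf.data_C[-1][ph.body_mask] - props.t_init_C) * vol
        )
        injected = np.sum(q) * vol * duration
        assert enthalpy == pytest.approx(injected, rel=0.01)

    def test_implicit_matches_explicit_oracle(self):
        """Backward Euler (dt = 0.5 s) vs a brute-force forward-Euler
        integration at CFL-limited dt on a 16^3 block over 60 s."""
        ph = homogeneous_phantom(16)
        props = ThermalProps()
        # smooth localised source
        idx = np.indices(ph.shape)
        r2 = sum((idx[a] - 8.0) ** 2 for a in range(3))
        q = 2.0e5 * np.exp(-r2 / 18.0)

        tf = solve_bioheat(ph, props, q, duration_s=60.0, dt_s=0.5, store_every_s=60.0)

        # independent explicit stepper
        h = ph.spacing_mm * 1e-3
        rho_c = props.rho_kg_m3 * props.c_sp_J_kgK
        perf = props.rho_b_kg_m3 * props.c_b_J_kgK * props.omega_b_per_s
        u_face = 1.0 / (1.0 / props.h_W_m2K + h / 2.0 / props.k_W_mK)
        dt = 0.05  # CFL limit ~ rho C h^2 / (6k) = 1.2 s
        t = np.full(ph.shape, props.t_init_C)
        n_steps = int(60.0 / dt)
        k = props.k_W_mK
        for _ in range(n_steps):
            lap = np.zeros(ph.shape)
            bdry = np.zeros(ph.shape)
            for ax in range(3):
                t_m = np.roll(t, 1, axis=ax)
                t_p = np.roll(t, -1, axis=ax)
                lap += k * (t_m + t_p - 2 * t) / h**2
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[ax], hi[ax] = 0, -1
                # cancel the wrapped neighbour, add Robin loss instead
                lap[tuple(lo)] -= k * (t_m[tuple(lo)] - t[tuple(lo)]) / h**2
                lap[tuple(hi)] -= k * (t_p[tuple(hi)] - t[tuple(hi)]) / h**2
                bdry[tuple(lo)] += u_face * (props.t_amb_C - t[tuple(lo)]) / h
                bdry[tuple(hi)] += u_face * (props.t_amb_C - t[tuple(hi)]) / h
            t = t + dt / rho_c * (lap + perf * (props.t_blood_C - t) + q + bdry)
        diff = np.abs(tf.data_C[-1][ph.body_mask] - t.ravel())
        assert diff.max() < 0.05

    def test_nonpositive_dt_rejected(self):
        ph = homogeneous_phantom(8)
        with pytest.raises(ValueError):
            solve_bioheat(ph, ThermalProps(), 0.0, duration_s=1.0, dt_s=0.0)


class TestArrhenius:
    def test_constant_temperature_closed_form(self):
        ph = homogeneous_phantom(6)
        props = ThermalProps(t_init_C=50.0, t_blood_C=50.0, t_amb_C=50.0)
        tf = solve_bioheat(ph, props, 0.0, duration_s=100.0, dt_s=1.0, store_every_s=10.0)
        params = ArrheniusParams()
        df = arrhenius_damage(tf, params)
        expected = params.a_per_s * 100.0 * np.exp(
            -params.ea_J_mol / (params.r_gas * (50.0 + 273.15))
        )
        assert np.allclose(df.omega[-1][ph.body_mask], expected, rtol=1e-9)

    def test_damage_non_negative_and_non_decreasing(self):
        ph = homogeneous_phantom(6)
        props = ThermalProps(t_init_C=45.0)
        tf = solve_bioheat(ph, props, 5e5, duration_s=30.0, dt_s=1.0, store_every_s=2.0)
        df = arrhenius_damage(tf)
        omega = df.omega[:, ph.body_mask]
        assert np.all(omega >= 0.0)
        assert np.all(np.diff(omega, axis=0) >= 0.0)

    def test_accumulation_matches_independent_trapezoid(self):
        """Per-voxel streaming accumulation vs scipy's cumulative_trapezoid
        on a temperature ramp."""
        from scipy.integrate import cumulative_trapezoid

        from nanotherm.thermal import TemperatureField

        times = np.linspace(0.0, 300.0, 301)
        ramp = 37.0 + 17.0 * times / 300.0
        mask = np.ones((2, 2, 2), dtype=bool)
        data = np.tile(ramp[:, None, None, None], (1, 2, 2, 2)).astype(np.float32)
        tf = TemperatureField(times_s=times, data_C=data, mask=mask)
        params = ArrheniusParams()
        df = arrhenius_damage(tf, params)
        rate = params.rate(data[:, 0, 0, 0].astype(float))
        oracle = cumulative_trapezoid(rate, times, initial=0.0)
        assert np.allclose(df.omega[:, 0, 0, 0], oracle, rtol=1e-6)

    def test_quadrature_refinement_consistency(self):
        """Trapezoid damage on a fine grid converges: 10x refinement of a
        linear ramp changes the integral by < 0.1%."""
        from nanotherm.thermal import TemperatureField

        def omega_final(n):
            times = np.linspace(0.0, 300.0, n)
            ramp = (37.0 + 17.0 * times / 300.0).astype(np.float32)
            mask = np.ones((1, 1, 1), dtype=bool)
            data = ramp[:, None, None, None].copy()
            tf = TemperatureField(times_s=times, data_C=data, mask=mask)
            return arrhenius_damage(tf).omega[-1, 0, 0, 0]

        assert omega_final(301) == pytest.approx(omega_final(3001), rel=1e-3)

    def test_as_printed_parameters_underflow_to_zero(self):
        """The tabulated (A, Ea) pair as printed makes the damage integrand
        exactly zero at any physiological temperature."""
        params = ArrheniusParams.as_printed()
        assert np.all(params.rate(np.array([37.0, 60.0, 100.0])) == 0.0)


class TestProbeTimeseries:
    def make_linear_field(self):
        from nanotherm.thermal import TemperatureField

        ph = homogeneous_phantom(8, spacing_mm=2.0)
        idx = np.indices(ph.shape, dtype=float)
        lin = 30.0 + idx[0] + 2 * idx[1] + 3 * idx[2]  # linear in voxel coords
        data = np.stack([lin, lin + 1.0]).astype(np.float32)
        tf = TemperatureField(times_s=np.array([0.0, 1.0]), data_C=data, mask=ph.body_mask)
        return ph, tf, lin

    def test_grid_node_returns_nodal_value(self):
        ph, tf, lin = self.make_linear_field()
        pt = ph.voxel_to_mm(np.array([3, 4, 5]))[0]
        out = probe_timeseries(tf, ProbeSet({"p": pt}), ph)
        assert out["T_p"].iloc[0] == pytest.approx(lin[3, 4, 5], rel=1e-6)

    def test_midpoint_is_arithmetic_mean(self):
        ph, tf, lin = self.make_linear_field()
        pt = ph.voxel_to_mm(np.array([3.5, 4.0, 5.0]))[0]
        out = probe_timeseries(tf, ProbeSet({"p": pt}), ph)
        expected = 0.5 * (lin[3, 4, 5] + lin[4, 4, 5])
        assert out["T_p"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_constant_field_constant_series(self):
        from nanotherm.thermal import TemperatureField

        ph = homogeneous_phantom(8)
        data = np.full((3,) + ph.shape, 37.0, dtype=np.float32)
        tf = TemperatureField(times_s=np.array([0.0, 1.0, 2.0]), data_C=data, mask=ph.body_mask)
        out = probe_timeseries(tf, ProbeSet({"p": ph.voxel_to_mm(np.array([2.2, 3.7, 4.1]))[0]}), ph)
        assert np.allclose(out["T_p"], 37.0)

    def test_probe_outside_body_rejected(self):
        ph = make_phantom(scenario="laser_only", seed=0)
        from nanotherm.thermal import TemperatureField

        data = np.full((1,) + ph.shape, np.nan, dtype=np.float32)
        data[0][ph.body_mask] = 37.0
        tf = TemperatureField(times_s=np.array([0.0]), data_C=data, mask=ph.body_mask)
        corner = ph.voxel_to_mm(np.array([1, 1, 1]))[0]  # grid corner, outside body
        with pytest.raises(ValueError):
            probe_timeseries(tf, ProbeSet({"x": corner}), ph)
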