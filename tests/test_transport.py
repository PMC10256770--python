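"""Kedem-Katchalsky fluxes and Krogh-cylinder perfusion simulation."""

import numpy as np
import pytest

from cryobank.protocol import build_protocol, vmp_loading_protocol
from cryobank.transport import (
    R_GAS,
    KroghGeometry,
    MembraneParams,
    TransportError,
    compare_protocols,
    equilibration_time,
    kk_fluxes,
    simulate_perfusion,
)

T_LOAD = 277.0  # 4 degC in K


def hold(c, minutes, pressure=1e-6):
    return build_protocol(
        [{"kind": "hold", "c_start": c, "c_end": c, "duration": minutes,
          "pressure_setpoint": pressure, "temperature": 3.85}],
        name=f"hold{c}",
    )


class TestKKFluxes:
    def test_zero_gradients_zero_fluxes(self):
        Jv, Js = kk_fluxes(0.0, 500.0, 500.0, 300.0, 300.0, MembraneParams(), 277.0)
        assert Jv == pytest.approx(0.0, abs=1e-20)
        assert Js == pytest.approx(0.0, abs=1e-12)

    def test_pure_osmotic_water_flux(self):
        # sigma = 1, omega = 0: no solute flux; Jv = -Lp R T dc
        m = MembraneParams(Lp=1.5e-14, omega=0.0, sigma=1.0)
        Jv, Js = kk_fluxes(0.0, 1000.0, 0.0, 0.0, 0.0, m, T_LOAD)
        assert Js == 0.0
        assert Jv == pytest.approx(-1.5e-14 * R_GAS * T_LOAD * 1000.0, rel=1e-12)
        assert Jv == pytest.approx(-3.45e-8, rel=2e-3)

    def test_solute_flux_with_published_coefficients(self):
        m = MembraneParams()  # Lp 1.5e-14, omega 7e-13, sigma 0.1
        Jv, Js = kk_fluxes(0.0, 1000.0, 0.0, 0.0, 0.0, m, T_LOAD)
        diffusive = 7.0e-13 * R_GAS * T_LOAD * 1000.0
        convective = (1 - 0.1) * 500.0 * Jv
        assert diffusive == pytest.approx(1.61e-6, rel=2e-3)
        assert Js == pytest.approx(diffusive + convective, rel=1e-12)

    def test_hydrostatic_term(self):
        m = MembraneParams()
        Jv, _ = kk_fluxes(1000.0, 0.0, 0.0, 0.0, 0.0, m, T_LOAD)
        assert Jv == pytest.approx(m.Lp * 1000.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(TransportError):
            kk_fluxes(0.0, -1.0, 0.0, 0.0, 0.0, MembraneParams(), 277.0)


def test_euler_oracle_equivalence():
    """Single-unit, single-segment run vs an independent explicit-Euler
    integrator at 100x finer steps: trajectories agree within 0.5% sup-norm."""
    g = KroghGeometry(n_axial=1, n_units=1)
    m = MembraneParams(area_scale=100.0)
    c_in, minutes, flow = 2000.0, 30.0, 1e-6
    p = hold(c_in, minutes, pressure=40.0)
    h = simulate_perfusion(p, g, m, flow=flow, dt=0.25, c_imp_vasc=300.0,
                           c_imp_extra0=300.0)

    # brute-force explicit Euler on the same physics, coded independently
    A = 2 * np.pi * g.capillary_radius * g.unit_length * m.area_scale
    V_vasc = np.pi * g.capillary_radius**2 * g.unit_length
    V0 = np.pi * (g.tissue_radius**2 - g.capillary_radius**2) * g.unit_length
    Q0 = flow * 1e-6 / 60.0
    rt = R_GAS * (3.85 + 273.15)
    dp = 40.0 * 133.322387415
    dt_s = 0.25 * 60.0 / 100.0
    n_imp = 300.0 * V0
    cv = 0.0
    n_e = 0.0
    V = V0
    t = 0.0
    times, ces = [0.0], [0.0]
    while t < minutes * 60.0 - 1e-9:
        ce = n_e / V
        Jv = m.Lp * (dp - m.sigma * rt * (cv - ce) - rt * (300.0 - n_imp / V))
        Js = m.omega * rt * (cv - ce) + (1 - m.sigma) * 0.5 * (cv + ce) * Jv
        Qout = max(Q0 - Jv * A, 0.0)
        cv += dt_s * (Q0 * c_in - Qout * cv - Js * A) / V_vasc
        n_e += dt_s * Js * A
        V += dt_s * Jv * A
        t += dt_s
        times.append(t)
        ces.append(n_e / V)
    ce_oracle = np.interp(h.time_min * 60.0, times, ces)
    sup = np.max(np.abs(h.c_extra[:, 0] - ce_oracle)) / c_in
    assert sup < 0.005


def test_boyle_vant_hoff_equilibrium():
    """sigma = 1, omega = 0, impermeant-only tissue: equilibrium volume is
    inversely proportional to external osmolality."""
    g = KroghGeometry(n_axial=1)
    m = MembraneParams(omega=0.0, sigma=1.0, area_scale=100.0)
    for c_ext, c_imp0 in [(1000.0, 300.0), (600.0, 300.0)]:
        p = hold(c_ext, 3000.0)
        h = simulate_perfusion(p, g, m, flow=1.0, dt=50.0, c_imp_vasc=0.0,
                               c_imp_extra0=c_imp0)
        v_eq = h.v_extra_rel[-1, 0]
        assert v_eq == pytest.approx(c_imp0 / c_ext, rel=1e-3)
        assert h.c_extra[-1, 0] == pytest.approx(0.0, abs=1e-9)


def test_equilibration_limit():
    """Constant inlet concentration, long horizon: tissue approaches the
    inlet concentration within 1% in every axial segment."""
    g = KroghGeometry(n_axial=3)
    m = MembraneParams(area_scale=500.0)
    h = simulate_perfusion(hold(5000.0, 2000.0, pressure=40.0), g, m,
                           flow=1.0, dt=25.0)
    assert np.all(h.c_extra[-1] > 0.99 * 5000.0)
    assert np.all(h.c_extra[-1] < 1.01 * 5000.0)


def test_mass_conservation_full_protocol(loading_protocol):
    h = simulate_perfusion(loading_protocol, KroghGeometry(),
                           MembraneParams(area_scale=50.0), flow=1.0, dt=1.0)
    assert h.mass_balance_residual() < 1e-6


def test_no_spontaneous_upconcentration():
    """With no hydrostatic drive the tissue never exceeds the maximum inlet
    concentration seen so far."""
    p = build_protocol(
        [
            {"kind": "ramp", "c_start": 0, "c_end": 3000, "rate": 100,
             "pressure_setpoint": 1e-6},
            {"kind": "ramp", "c_start": 3000, "c_end": 500, "rate": -100,
             "pressure_setpoint": 1e-6},
        ],
        name="updown",
    )
    h = simulate_perfusion(p, KroghGeometry(n_axial=3),
                           MembraneParams(area_scale=200.0), flow=1.0, dt=0.5)
    running_max = np.maximum.accumulate(h.c_inlet)
    assert np.all(h.c_extra.max(axis=1) <= running_max * (1 + 1e-6) + 1e-6)


def test_halving_omega_halves_initial_uptake():
    """sigma = 0, no pressure: Js is pure permeation, linear in omega.

    A single well-supplied unit (n_units = 1) keeps the capillary at the
    inlet concentration so the uptake slope isolates the membrane term."""
    g = KroghGeometry(n_axial=1, n_units=1)
    slopes = []
    for omega in (7.0e-13, 3.5e-13):
        m = MembraneParams(omega=omega, sigma=0.0, area_scale=100.0)
        h = simulate_perfusion(hold(1000.0, 0.2), g, m, flow=1.0, dt=0.05,
                               c_imp_vasc=300.0, c_imp_extra0=300.0)
        # initial uptake slope, before back-diffusion matters
        slopes.append((h.c_extra[-1, 0] - h.c_extra[0, 0]) / h.time_min[-1])
    assert slopes[0] == pytest.approx(2 * slopes[1], rel=0.02)


def test_dt_refinement_convergence(loading_protocol):
    m = MembraneParams(area_scale=50.0)
    h1 = simulate_perfusion(loading_protocol, KroghGeometry(n_axial=3), m,
                            flow=1.0, dt=2.0)
    h2 = simulate_perfusion(loading_protocol, KroghGeometry(n_axial=3), m,
                            flow=1.0, dt=1.0)
    a = h1.final_mean_tissue_concentration
    b = h2.final_mean_tissue_concentration
    assert abs(a - b) / b < 1e-3


class TestEquilibrationTime:
    def test_already_at_plateau(self):
        g = KroghGeometry(n_axial=1)
        m = MembraneParams(area_scale=500.0)
        h = simulate_perfusion(hold(1000.0, 3000.0), g, m, flow=1.0, dt=25.0)
        h2_start = equilibration_time(h, 1e-6)
        assert h2_start == pytest.approx(h.time_min[0], abs=h.time_min[1])

    def test_exponential_time_constant(self):
        """sigma = 0, balanced impermeants, fixed volume: tissue loading is a
        single exponential with tau = V / (omega R T A); time to 63.2% of the
        plateau equals tau within 2%. n_units = 1 keeps the capillary at the
        inlet concentration (the closed-form assumes no vascular depletion)."""
        g = KroghGeometry(n_axial=1, n_units=1)
        m = MembraneParams(omega=7.0e-13, sigma=0.0, Lp=1e-20, area_scale=100.0)
        A = 2 * np.pi * g.capillary_radius * g.unit_length * m.area_scale
        V0 = np.pi * (g.tissue_radius**2 - g.capillary_radius**2) * g.unit_length
        tau_min = V0 / (m.omega * R_GAS * (3.85 + 273.15) * A) / 60.0
        h = simulate_perfusion(hold(1000.0, 6 * tau_min), g, m, flow=1.0,
                               dt=tau_min / 200.0, c_imp_vasc=300.0,
                               c_imp_extra0=300.0)
        t63 = equilibration_time(h, 1.0 - np.exp(-1.0))
        assert t63 == pytest.approx(tau_min, rel=0.02)

    def test_unreachable_fraction_gives_inf(self):
        p = build_protocol(
            [{"kind": "ramp", "c_start": 0, "c_end": 5000, "rate": 500,
              "pressure_setpoint": 1e-6}], name="ramp-only")
        h = simulate_perfusion(p, KroghGeometry(n_axial=1), MembraneParams(),
                               flow=1.0, dt=0.5)
        assert equilibration_time(h, 1.0) == float("inf")

    def test_invalid_fraction(self):
        g = KroghGeometry(n_axial=1)
        h = simulate_perfusion(hold(100.0, 1.0), g, MembraneParams(), flow=1.0,
                               dt=0.5)
        with pytest.raises(TransportError):
            equilibration_time(h, 0.0)
        with pytest.raises(TransportError):
            equilibration_time(h, 1.5)


class TestCompareProtocols:
    def test_identical_protocols_identical_report(self, loading_protocol):
        g = KroghGeometry(n_axial=2)
        m = MembraneParams(area_scale=50.0)
        rep = compare_protocols(loading_protocol, loading_protocol, g, m,
                                thresholds=(4000.0,), dt=1.0)
        assert rep.reports["a"]["final_tissue_mM"] == pytest.approx(
            rep.reports["b"]["final_tissue_mM"]
        )
        assert rep.reports["a"]["exposure"] == rep.reports["b"]["exposure"]

    def test_hold_increases_final_tissue_concentration(self):
        with_hold = build_protocol(
            [
                {"kind": "ramp", "c_start": 0, "c_end": 5000, "rate": 50},
                {"kind": "hold", "c_start": 5000, "c_end": 5000, "duration": 10},
            ],
            name="with-hold",
        )
        without = build_protocol(
            [{"kind": "ramp", "c_start": 0, "c_end": 5000, "rate": 50}],
            name="no-hold",
        )
        g = KroghGeometry(n_axial=2)
        m = MembraneParams(area_scale=50.0)
        rep = compare_protocols(with_hold, without, g, m, dt=1.0)
        assert rep.reports["a"]["final_tissue_mM"] >= rep.reports["b"]["final_tissue_mM"]

    def test_zero_duration_protocol(self):
        empty = build_protocol([], name="empty")
        g = KroghGeometry(n_axial=2)
        rep = compare_protocols(empty, empty, g, MembraneParams(),
                                thresholds=(100.0,))
        for key in ("a", "b"):
            assert rep.reports[key]["final_tissue_mM"] == 0.0
            assert rep.reports[key]["exposure"][100.0]["exposure_mM_min"] == 0.0
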