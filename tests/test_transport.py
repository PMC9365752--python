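"""Transport dynamics: flux balance, boundary conditions, conservation.

The small-mesh oracles here re-derive the flux balance by hand (plain loops
over Fick/upwind fluxes with a fixed-step explicit integrator) and must agree
with the sparse-operator BDF path.
"""

import math

import numpy as np
import pytest

from acinusim import discretize, make_toy_mesh
from acinusim.transport import (
    SimulationConfig,
    assemble_operator,
    initial_condition,
    rhs,
    simulate,
    total_tracer,
)


class TestInitialCondition:
    def test_total_tracer_volume(self, default_mesh):
        y0 = initial_condition(default_mesh)
        total = total_tracer(y0, default_mesh)
        assert total == pytest.approx(4.78e-5, rel=1e-2)

    def test_half_sine_shape(self, default_mesh):
        y0 = initial_condition(default_mesh)
        ch = np.flatnonzero(default_mesh.is_chamber)
        assert y0[ch].max() > 0.999           # peak 1 at the chamber centre
        assert y0[ch[0]] < 0.05 and y0[ch[-1]] < 0.05  # ~0 at both ends
        assert np.abs(y0[default_mesh.n_air:]).max() == 0.0

    def test_requires_a_chamber(self, constants):
        toy = make_toy_mesh(3, constants.a_m, 10e-4, constants=constants)
        with pytest.raises(ValueError, match="chamber"):
            initial_condition(toy)


class TestFluxBalance:
    def test_uniform_state_is_stationary_without_convection(self, constants):
        mesh = make_toy_mesh(4, constants.a_m, 10e-4, 2.0, constants=constants,
                             convection=False)
        y = np.ones(mesh.n_air + mesh.n_alv_states)
        dydt = rhs(y, mesh, diffusion_coefficient=0.3)
        # individual rate terms are O(D/dx^2) ~ 3e5 1/s; their cancellation
        # leaves only float round-off
        assert np.abs(dydt).max() < 1e-8

    def test_two_compartment_fick_flux(self, constants):
        d, dx = 0.3, 10e-4
        mesh = make_toy_mesh(2, constants.a_m, dx, constants=constants)
        dydt = rhs(np.array([1.0, 0.0]), mesh, diffusion_coefficient=d)
        expected = d * constants.a_m / (dx * mesh.V_k[0])
        assert dydt[0] == pytest.approx(-expected, rel=1e-12)
        assert dydt[1] == pytest.approx(+expected, rel=1e-12)

    def test_alveolar_filling_by_convection_only(self, constants):
        mesh = make_toy_mesh(1, constants.a_m, 10e-4, 1.0, constants=constants,
                             convection=True)
        dydt = rhs(np.array([1.0, 0.0]), mesh, diffusion_coefficient=0.0)
        # airway at chi=1, empty alveolus: uptake flow Q' carries chi=1
        assert dydt[1] == pytest.approx(
            constants.q_alv / mesh.V_alv0[0], rel=1e-12
        )

    def test_rejects_non_finite_state(self, constants):
        mesh = make_toy_mesh(2, constants.a_m, 10e-4, constants=constants)
        with pytest.raises(ValueError):
            rhs(np.array([np.nan, 0.0]), mesh)


class TestTwoBoxRelaxation:
    def test_closed_form_decay(self, constants):
        """chi1 - chi2 of a closed two-compartment diffusion cell decays as
        exp(-D A (1/V1 + 1/V2) t / dx)."""
        d, dx = 0.3, 10e-4
        mesh = make_toy_mesh(2, constants.a_m, dx, constants=constants)
        rate = d * constants.a_m / dx * (2.0 / mesh.V_k[0])
        t_end = 3.0 / rate
        config = SimulationConfig(t_end=t_end, n_output=61,
                                  diffusion_coefficient=d)
        traj = simulate(mesh, config, y0=np.array([1.0, 0.0]))
        diff = traj.chi[:, 0] - traj.chi[:, 1]
        expected = np.exp(-rate * traj.times)
        assert np.max(np.abs(diff - expected)) < 1e-3


def _explicit_oracle(mesh, d, y0, t_end, dt):
    """Fixed-step forward-Euler integration of the hand-written flux balance
    for a straight duct with a membrane inlet and a closed end."""
    n = mesh.n_air
    chi = y0[:n].copy()
    chi_alv = y0[n:].copy()
    carriers = np.flatnonzero(mesh.alv_idx >= 0)
    steps = int(round(t_end / dt))
    t = 0.0
    for _ in range(steps):
        dchi = np.zeros(n)
        for k in range(n):
            flux = 0.0  # molar in-flux of compartment k, ml/s units of chi*V
            if k > 0:
                flux += mesh.Q_in[k] * chi[k - 1]
                flux += d * mesh.A_in[k] * (chi[k - 1] - chi[k]) / mesh.dx
            if k < n - 1:
                flux -= mesh.Q_out[k] * chi[k]
                flux += d * mesh.A_out[k] * (chi[k + 1] - chi[k]) / mesh.dx
            flux -= mesh.Q_prime[k] * chi[k]
            a = mesh.alv_idx[k]
            if a >= 0:
                flux += d * mesh.A_prime[k] / mesh.r_k[k] * (chi_alv[a] - chi[k])
            dchi[k] = flux / mesh.V_k[k]
        dalv = np.zeros(chi_alv.size)
        for j, k in enumerate(carriers):
            v_alv = mesh.V_alv0[k] + mesh.Q_prime[k] * t
            gp = d * mesh.A_prime[k] / mesh.r_k[k]
            dalv[j] = (
                mesh.Q_prime[k] * chi[k]
                - gp * (chi_alv[j] - chi[k])
                - mesh.Q_prime[k] * chi_alv[j]
            ) / v_alv
        chi += dt * dchi
        chi_alv += dt * dalv
        t += dt
    return np.concatenate([chi, chi_alv])


class TestExplicitOracle:
    @pytest.mark.parametrize("convection", [False, True])
    def test_bdf_agrees_with_forward_euler(self, constants, convection):
        d, dx = 0.3, 10e-4
        mesh = make_toy_mesh(4, constants.a_m, dx, alveoli_per_compartment=5.0,
                             constants=constants, convection=convection)
        y0 = np.zeros(mesh.n_air + mesh.n_alv_states)
        y0[0] = 1.0
        t_end = 0.01
        oracle = _explicit_oracle(mesh, d, y0, t_end, dt=1e-7)
        config = SimulationConfig(t_end=t_end, n_output=11, rel_tol=1e-9,
                                  abs_tol=1e-12, diffusion_coefficient=d)
        traj = simulate(mesh, config, y0=y0)
        final = np.concatenate([traj.chi[-1], traj.chi_alv[-1]])
        scale = np.abs(oracle).max()
        assert np.max(np.abs(final - oracle)) / scale < 1e-4


@pytest.fixture(scope="module")
def short_config():
    return SimulationConfig(t_end=2.0, n_output=201)


class TestFullModelRuns:
    def test_tracer_conservation(self, default_mesh, short_config):
        traj = simulate(default_mesh, short_config)
        assert traj.conservation_drift < 1e-5

    def test_symmetric_daughters_fill_identically(self, default_mesh,
                                                  short_config):
        traj = simulate(default_mesh, short_config)
        from acinusim.kinetics import tracer_volume_per_unit

        df = tracer_volume_per_unit(traj)
        assert np.abs(df.V_g_BrU1 - df.V_g_BrU2).max() < 1e-9

    def test_mole_fractions_stay_physical(self, default_mesh, short_config):
        traj = simulate(default_mesh, short_config)
        assert traj.chi.min() > -1e-5
        assert traj.chi.max() < 1.0 + 1e-5

    def test_pure_diffusion_keeps_alveolar_volumes_frozen(self, asym_spec):
        from dataclasses import replace

        frozen = discretize(replace(asym_spec, convection_enabled=False))
        op = assemble_operator(frozen, 0.3)
        assert np.all(op.v_alv(10.0) == op.v_alv(0.0))
        assert (frozen.Q_in == 0).all() and (frozen.Q_prime == 0).all()
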