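"""Flux-balance transport: assembly and integration of the mole-fraction ODEs.

Every airway compartment k exchanges tracer with its axial neighbours by
upwind convection and Fickian diffusion, and with its paired alveolar
compartment k' by convective uptake and diffusion across the lateral surface:

    dchi_k/dt  = (1/V_k) [ Q_in chi_up - Q_out chi_k - Q' chi_k
                           + D ( A_in (chi_up - chi_k)/dx
                               + A_out (chi_down - chi_k)/dx
                               + A' (chi_k' - chi_k)/r_k ) ]
    dchi_k'/dt = (1/V_k'(t)) [ Q' chi_k - D A' (chi_k' - chi_k)/r_k
                               - (dV_k'/dt) chi_k' ]

with V_k'(t) = V_alv0 + Q' t (alveoli inflate at constant flow).  The inlet is
a semipermeable membrane: carrier gas convects in at chi = 0 and the tracer
diffusive flux through the inlet face is zero, so the total tracer volume
sum(chi V) is exactly conserved.  At the branch point the mother's outflow
splits in proportion to the daughters' input flows and each daughter face
carries its own interface area.  Terminal distal faces are closed.

The system is linear, dy/dt = J(t) y, with only the alveolar rows time
dependent; the integrator is a stiff BDF scheme fed the analytic sparse
Jacobian (diffusion across 10-um compartments makes the fast rates
~D/dx^2 ~ 3e5 1/s while the kinetics of interest live on seconds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .mesh import CompartmentMesh

__all__ = [
    "SimulationConfig",
    "TracerTrajectory",
    "TransportOperator",
    "assemble_operator",
    "initial_condition",
    "rhs",
    "total_tracer",
    "simulate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for one transport run.

    ``diffusion_coefficient`` of None means "use the model spec's D".  The
    default output grid is 3000 uniform intervals over [0, t_end], dense
    enough for the growth-constant fits.
    """

    t_end: float = 30.0
    n_output: int = 3001
    output_times: np.ndarray | None = None
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    diffusion_coefficient: float | None = None
    conservation_warn_factor: float = 1e3

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be positive")

    def grid(self) -> np.ndarray:
        if self.output_times is not None:
            return np.asarray(self.output_times, dtype=float)
        return np.linspace(0.0, self.t_end, self.n_output)


class TransportOperator:
    """The linear operator J(t) of dy/dt = J(t) y for one mesh and D.

    The state is [chi_airway (N), chi_alveolar (M)].  Airway rows are
    constant; alveolar rows are the constant molar-flux stencil divided by the
    current alveolar volume.
    """

    def __init__(self, mesh: CompartmentMesh, diffusion_coefficient: float):
        self.mesh = mesh
        self.D = float(diffusion_coefficient)
        n = mesh.n_air
        m = mesh.n_alv_states
        self.n_air = n
        self.n_alv = m
        carriers = np.flatnonzero(mesh.alv_idx >= 0)
        self.carriers = carriers
        self.v_alv0 = mesh.V_alv0[carriers]
        self.q_alv = mesh.Q_prime[carriers]
        rows, cols, vals = [], [], []

        def add(r: int, c: int, v: float) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        D = self.D
        for i in range(n):
            vi = mesh.V_k[i]
            u = int(mesh.upstream[i])
            if u >= 0:
                g = D * mesh.A_in[i] / mesh.dist_up[i]   # face conductance, ml/s
                add(i, u, g / vi)
                add(i, i, -g / vi)
                add(u, i, g / mesh.V_k[u])
                add(u, u, -g / mesh.V_k[u])
                q = mesh.Q_in[i]
                if q != 0.0:
                    add(i, u, q / vi)        # upwind inflow carries chi_up
                    add(u, u, -q / mesh.V_k[u])
            if mesh.Q_prime[i] != 0.0:
                add(i, i, -mesh.Q_prime[i] / vi)
            a = int(mesh.alv_idx[i])
            if a >= 0:
                gp = D * mesh.A_prime[i] / mesh.r_k[i]
                add(i, n + a, gp / vi)
                add(i, i, -gp / vi)
                # alveolar rows hold molar fluxes; divided by V_alv(t) later
                add(n + a, i, mesh.Q_prime[i] + gp)
                add(n + a, n + a, -(gp + mesh.Q_prime[i]))
        self.K = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n + m, n + m)
        )
        self._scale = np.ones(n + m)

    def v_alv(self, t: float) -> np.ndarray:
        """Alveolar compartment volumes at time t (ml)."""
        return self.v_alv0 + self.q_alv * t

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        out = self.K @ y
        if self.n_alv:
            out[self.n_air:] /= self.v_alv(t)
        return out

    def jac(self, t: float, y: np.ndarray) -> sp.csr_matrix:
        scale = self._scale.copy()
        if self.n_alv:
            scale[self.n_air:] = 1.0 / self.v_alv(t)
        return sp.diags(scale) @ self.K


def assemble_operator(
    mesh: CompartmentMesh, diffusion_coefficient: float | None = None
) -> TransportOperator:
    d = diffusion_coefficient if diffusion_coefficient is not None else mesh.d_default
    if d is None:
        raise ValueError("no diffusion coefficient given and none on the mesh")
    return TransportOperator(mesh, d)


def rhs(
    y: np.ndarray,
    mesh: CompartmentMesh,
    diffusion_coefficient: float | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """One-shot evaluation of the flux balance (convenience wrapper)."""
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains NaN/inf")
    return assemble_operator(mesh, diffusion_coefficient).rhs(t, y)


def initial_condition(mesh: CompartmentMesh) -> np.ndarray:
    """Half-sine tracer bolus in the chamber; carrier gas everywhere else.

    chi(x) = sin(pi x / L_chamber) at the compartment midpoints (peak mole
    fraction 1 at the chamber centre), zero in all other airway compartments
    and in every alveolus.
    """
    if not mesh.is_chamber.any():
        raise ValueError("mesh has no chamber to hold the tracer bolus")
    y = np.zeros(mesh.n_air + mesh.n_alv_states)
    ch = np.flatnonzero(mesh.is_chamber)
    l_ch = mesh.width[ch].sum()
    y[ch] = np.sin(np.pi * mesh.x[ch] / l_ch)
    return y


def total_tracer(y: np.ndarray, mesh: CompartmentMesh, t: float = 0.0) -> float:
    """Tracer volume sum(chi V) over airway plus alveolar compartments, ml."""
    n = mesh.n_air
    total = float(y[:n] @ mesh.V_k)
    carriers = np.flatnonzero(mesh.alv_idx >= 0)
    if carriers.size:
        v_alv = mesh.V_alv0[carriers] + mesh.Q_prime[carriers] * t
        total += float(y[n:] @ v_alv)
    return total


@dataclass
class TracerTrajectory:
    """Dense time history of one transport run."""

    mesh: CompartmentMesh
    config: SimulationConfig
    diffusion_coefficient: float
    times: np.ndarray        # s
    chi: np.ndarray          # (n_times, n_air) airway mole fractions
    chi_alv: np.ndarray      # (n_times, n_alv_states)
    total: np.ndarray = field(default=None)  # conservation monitor, ml

    @property
    def conservation_drift(self) -> float:
        """Max relative departure of the total tracer volume from its start."""
        return float(np.max(np.abs(self.total - self.total[0])) / self.total[0])

    def to_frame(self) -> pd.DataFrame:
        """Per-unit tracer volumes as a tidy table (see kinetics)."""
        from .kinetics import tracer_volume_per_unit

        return tracer_volume_per_unit(self)


def simulate(
    mesh: CompartmentMesh,
    config: SimulationConfig | None = None,
    y0: np.ndarray | None = None,
) -> TracerTrajectory:
    """Integrate the transport system from t = 0 to t_end.

    Uses adaptive BDF with the analytic sparse Jacobian; reports dense output
    on the configured grid and checks tracer conservation (the semipermeable
    inlet makes the system closed for the tracer).
    """
    if config is None:
        config = SimulationConfig()
    op = assemble_operator(mesh, config.diffusion_coefficient)
    if y0 is None:
        y0 = initial_condition(mesh)
    t_eval = config.grid()
    sol = solve_ivp(
        op.rhs,
        (float(t_eval[0]), float(t_eval[-1])),
        y0,
        method="BDF",
        jac=op.jac,
        rtol=config.rel_tol,
        atol=config.abs_tol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"transport integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("transport integration produced non-finite values")
    n = mesh.n_air
    chi = sol.y[:n].T.copy()
    chi_alv = sol.y[n:].T.copy()
    v_alv_t = op.v_alv0[None, :] + op.q_alv[None, :] * sol.t[:, None] \
        if op.n_alv else np.zeros((sol.t.size, 0))
    total = chi @ mesh.V_k + (chi_alv * v_alv_t).sum(axis=1)
    traj = TracerTrajectory(
        mesh=mesh,
        config=config,
        diffusion_coefficient=op.D,
        times=sol.t.copy(),
        chi=chi,
        chi_alv=chi_alv,
        total=total,
    )
    drift = traj.conservation_drift
    if drift > config.conservation_warn_factor * config.rel_tol:
        warnings.warn(
            f"tracer conservation drift {drift:.2e} exceeds "
            f"{config.conservation_warn_factor:g} x rel_tol",
            stacklevel=2,
        )
    return traj
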