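"""Axial discretisation of the acinar model into airway/alveolar compartments.

Each branch unit is cut into axial compartments of nominal width ``dx``
(default 10 um).  A segment (one BrE, the partial BrE, or the chamber) of
length L gets ``round_half_up(L/dx)`` compartments of uniform width ``L/n``;
using the exact width instead of forcing ``dx`` keeps every unit's airway
volume and alveolar budget identical to the closed-form laws instead of
perturbing them by up to half a compartment per segment.

Cross-sections are constant within a BrE (2**j airway areas merged); the face
shared by two adjacent BrEs — and each daughter face at the branch point —
carries the arithmetic mean of the two abutting areas, which removes the area
step from the diffusive flux while compartment volumes keep the per-BrE area.

Alveoli are spread uniformly over each BrE's length; a compartment's alveolar
uptake flow is ``n_alv * Q_Alv`` and the whole-unit sum reproduces the unit's
input flow exactly (global continuity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcinarModelSpec
from .morphometry import AcinarConstants, build_constants

__all__ = ["CompartmentMesh", "discretize", "face_areas", "alveolar_loading",
           "make_toy_mesh"]

DEFAULT_DX = 10e-4  # 10 um in cm


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CompartmentMesh:
    """Flat arrays describing the discretised model (one entry per compartment).

    ``unit`` is 0 for BrU0 (the chamber belongs to it), 1/2 for the daughters;
    ``upstream`` holds the index of the proximally adjacent compartment (-1 at
    the membrane inlet); the two daughters' first compartments both point to
    BrU0's distal compartment, which realises the branch point.
    """

    spec: AcinarModelSpec | None
    dx: float
    unit: np.ndarray          # int, 0|1|2
    is_chamber: np.ndarray    # bool
    gen: np.ndarray           # BrE generation j within the unit, -1 for chamber
    k: np.ndarray             # axial index within the unit
    x: np.ndarray             # compartment midpoint from the unit's proximal face, cm
    width: np.ndarray         # axial width, cm (~dx)
    A_seg: np.ndarray         # segment (BrE) cross-section, cm^2
    V_k: np.ndarray           # airway compartment volume, ml
    upstream: np.ndarray      # int, -1 at the inlet
    A_in: np.ndarray = field(default=None)    # proximal face area, cm^2
    A_out: np.ndarray = field(default=None)   # distal face area, cm^2
    dist_up: np.ndarray = field(default=None)  # midpoint distance to upstream, cm
    r_k: np.ndarray = field(default=None)     # merged-cylinder radius, cm
    A_prime: np.ndarray = field(default=None)  # airway-alveolus exchange surface, cm^2
    n_alv: np.ndarray = field(default=None)   # alveoli assigned (fractional)
    V_alv0: np.ndarray = field(default=None)  # alveolar base volume, ml
    Q_in: np.ndarray = field(default=None)    # convective inflow, ml/s
    Q_out: np.ndarray = field(default=None)   # convective outflow, ml/s
    Q_prime: np.ndarray = field(default=None)  # alveolar uptake flow, ml/s
    alv_idx: np.ndarray = field(default=None)  # alveolar state index, -1 if none
    convection_enabled: bool = True
    d_default: float | None = None            # D to use if the config gives none
    constants: AcinarConstants | None = None

    @property
    def n_air(self) -> int:
        return self.unit.size

    @property
    def n_alv_states(self) -> int:
        return int((self.alv_idx >= 0).sum())

    @property
    def chamber_length(self) -> float:
        return float(self.width[self.is_chamber].sum())

    def unit_airway_volume(self, unit: int, include_chamber: bool = True) -> float:
        mask = self.unit == unit
        if not include_chamber:
            mask &= ~self.is_chamber
        return float(self.V_k[mask].sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Mesh summary, one row per compartment (cm / ml / s units)."""
        return pd.DataFrame(
            {
                "unit": self.unit,
                "k": self.k,
                "x_cm": self.x,
                "is_chamber": self.is_chamber,
                "width_cm": self.width,
                "V_k_ml": self.V_k,
                "A_in_cm2": self.A_in,
                "A_out_cm2": self.A_out,
                "r_k_cm": self.r_k,
                "A_prime_cm2": self.A_prime,
                "Q_in_ml_s": self.Q_in,
                "Q_out_ml_s": self.Q_out,
                "Q_prime_ml_s": self.Q_prime,
                "n_alv": self.n_alv,
                "V_alv0_ml": self.V_alv0,
            }
        )


def _unit_segments(spec: AcinarModelSpec, unit: int) -> list[tuple[int, float, float]]:
    """(generation j, length, area) segments of one unit, proximal to distal.

    Generation -1 denotes the alveolus-free chamber (BrU0 only).
    """
    c = spec.constants
    if unit == 0:
        return [(-1, spec.chamber_length, c.a_m), (0, c.l_m, c.a_m)]
    u = spec.bru1 if unit == 1 else spec.bru2
    segs = [(j, c.l_m, 2.0**j * c.a_m) for j in range(u.s + 1)]
    if u.a > 0:
        segs.append((u.s + 1, u.a * c.l_m, 2.0 ** (u.s + 1) * c.a_m))
    return segs


def discretize(spec: AcinarModelSpec, dx: float = DEFAULT_DX) -> CompartmentMesh:
    """Discretise a model spec into a fully populated compartment mesh."""
    if dx <= 0:
        raise ValueError("dx must be positive")
    if dx >= spec.constants.l_m:
        raise ValueError(f"dx = {dx} cm must be smaller than l_M = "
                         f"{spec.constants.l_m} cm")
    unit_l, chamber_l, gen_l, k_l, x_l, w_l, area_l = [], [], [], [], [], [], []
    upstream: list[int] = []
    folded: dict[int, float] = {}  # unit -> alveoli folded into its last compartment
    branch_parent = -1

    for unit in (0, 1, 2):
        first_of_unit = True
        kk = 0
        x0 = 0.0
        for gen, length, area in _unit_segments(spec, unit):
            n = _round_half_up(length / dx)
            if n == 0:
                # partial BrE shorter than dx/2: no axial compartment, its
                # alveoli are folded into the unit's distal compartment so the
                # flow budget is preserved
                m_bar = spec.constants.m_bar_alv
                u = spec.bru1 if unit == 1 else spec.bru2
                folded[unit] = folded.get(unit, 0.0) + m_bar * u.a * 2.0 ** (u.s + 1)
                continue
            w = length / n
            for j in range(n):
                unit_l.append(unit)
                chamber_l.append(gen < 0)
                gen_l.append(gen)
                k_l.append(kk)
                x_l.append(x0 + (j + 0.5) * w)
                w_l.append(w)
                area_l.append(area)
                if first_of_unit:
                    upstream.append(branch_parent if unit else -1)
                    first_of_unit = False
                else:
                    upstream.append(len(unit_l) - 2)
                kk += 1
            x0 += length
        if unit == 0:
            branch_parent = len(unit_l) - 1

    mesh = CompartmentMesh(
        spec=spec,
        dx=dx,
        unit=np.array(unit_l, dtype=int),
        is_chamber=np.array(chamber_l, dtype=bool),
        gen=np.array(gen_l, dtype=int),
        k=np.array(k_l, dtype=int),
        x=np.array(x_l),
        width=np.array(w_l),
        A_seg=np.array(area_l),
        V_k=np.array(area_l) * np.array(w_l),
        upstream=np.array(upstream, dtype=int),
        convection_enabled=spec.convection_enabled,
        d_default=spec.diffusion_coefficient,
        constants=spec.constants,
    )
    mesh._folded_alveoli = folded
    face_areas(mesh)
    alveolar_loading(mesh)
    return mesh


def face_areas(mesh: CompartmentMesh) -> CompartmentMesh:
    """Populate proximal/distal face areas and upstream midpoint distances.

    Interior faces carry the BrE's own area; the face between two segments
    (including the daughter faces at the branch point) carries the arithmetic
    mean of the two abutting segment areas.
    """
    n = mesh.n_air
    a_in = mesh.A_seg.copy()
    a_out = mesh.A_seg.copy()
    dist = np.full(n, np.nan)
    for i in range(n):
        u = mesh.upstream[i]
        if u < 0:
            dist[i] = np.nan  # membrane inlet: no diffusive neighbour
            continue
        dist[i] = 0.5 * (mesh.width[i] + mesh.width[u])
        shared = 0.5 * (mesh.A_seg[i] + mesh.A_seg[u])
        a_in[i] = shared
        # the parent's distal face towards a same-unit child; at the branch
        # point BrU0 keeps its own area (each daughter face is the daughter's
        # proximal one)
        if mesh.unit[i] == mesh.unit[u]:
            a_out[u] = shared
    mesh.A_in = a_in
    mesh.A_out = a_out
    mesh.dist_up = dist
    return mesh


def alveolar_loading(mesh: CompartmentMesh) -> CompartmentMesh:
    """Distribute alveoli along the BrEs and derive flows and exchange surfaces.

    A compartment in generation j receives ``m_bar_Alv * 2**j * width/l_M``
    alveoli; unit totals are rescaled by one common factor (numerically ~1) so
    the summed uptake equals the unit's input flow exactly.  Convective face
    flows then follow from continuity, distally decreasing to zero.
    """
    spec = mesh.spec
    c = mesh.constants
    n = mesh.n_air
    n_alv = np.zeros(n)
    bre = ~mesh.is_chamber
    n_alv[bre] = c.m_bar_alv * 2.0 ** mesh.gen[bre].astype(float) * (
        mesh.width[bre] / c.l_m
    )
    units = {0: spec.bru0, 1: spec.bru1, 2: spec.bru2} if spec else None
    folded = getattr(mesh, "_folded_alveoli", {})
    for unit in np.unique(mesh.unit):
        mask = mesh.unit == unit
        last = np.flatnonzero(mask)[-1]
        n_alv[last] += folded.get(int(unit), 0.0)
        if units is not None:
            target = units[int(unit)].m_alv_total
            got = n_alv[mask].sum()
            if got <= 0 and target > 0:
                raise ValueError(f"unit {unit} has alveoli but no compartments "
                                 "to carry them")
            if got > 0:
                n_alv[mask] *= target / got
    mesh.n_alv = n_alv
    mesh.V_alv0 = n_alv * c.v_alv
    a_mid = 0.5 * (mesh.A_in + mesh.A_out)
    mesh.r_k = np.sqrt(a_mid / math.pi)
    mesh.A_prime = 2.0 * math.pi * mesh.r_k * mesh.width

    q_prime = n_alv * c.q_alv if mesh.convection_enabled else np.zeros(n)
    q_in = np.zeros(n)
    q_out = np.zeros(n)
    if mesh.convection_enabled:
        if units is not None:
            total = sum(u.q_in for u in units.values())
            unit_inflow = {0: total, 1: spec.bru1.q_in, 2: spec.bru2.q_in}
        else:
            unit_inflow = {0: float(q_prime.sum())}
        for i in range(n):
            u = mesh.upstream[i]
            if u < 0 or mesh.unit[i] != mesh.unit[u]:
                q_in[i] = unit_inflow[int(mesh.unit[i])]
            else:
                q_in[i] = q_out[u]
            q_out[i] = q_in[i] - q_prime[i]
        # terminal faces are closed; continuity makes the residual ~0
        for unit in np.unique(mesh.unit):
            last = np.flatnonzero(mesh.unit == unit)[-1]
            if mesh.unit[(mesh.upstream == last)].size == 0:  # no child below
                q_out[last] = 0.0
    mesh.Q_in = q_in
    mesh.Q_out = q_out
    mesh.Q_prime = q_prime

    alv_idx = np.full(n, -1, dtype=int)
    carriers = np.flatnonzero(n_alv > 0)
    alv_idx[carriers] = np.arange(carriers.size)
    mesh.alv_idx = alv_idx
    return mesh


def make_toy_mesh(
    n_compartments: int,
    area: float,
    dx: float,
    alveoli_per_compartment: float = 0.0,
    constants: AcinarConstants | None = None,
    convection: bool = False,
    diffusion_coefficient: float = 0.3,
) -> CompartmentMesh:
    """A single straight duct with uniform geometry (oracle-test fixture).

    No chamber and no branch point; a membrane closes the inlet.  With
    ``convection`` on, the inlet flow equals the summed alveolar uptake so the
    duct obeys the same continuity law as the real mesh.
    """
    if n_compartments < 1:
        raise ValueError("need at least one compartment")
    if constants is None:
        constants = build_constants()
    n = n_compartments
    mesh = CompartmentMesh(
        spec=None,
        dx=dx,
        unit=np.zeros(n, dtype=int),
        is_chamber=np.zeros(n, dtype=bool),
        gen=np.zeros(n, dtype=int),
        k=np.arange(n),
        x=(np.arange(n) + 0.5) * dx,
        width=np.full(n, dx),
        A_seg=np.full(n, area),
        V_k=np.full(n, area * dx),
        upstream=np.arange(-1, n - 1),
        convection_enabled=convection,
        d_default=diffusion_coefficient,
        constants=constants,
    )
    face_areas(mesh)
    n_alv = np.full(n, float(alveoli_per_compartment))
    mesh.n_alv = n_alv
    mesh.V_alv0 = n_alv * constants.v_alv
    a_mid = 0.5 * (mesh.A_in + mesh.A_out)
    mesh.r_k = np.sqrt(a_mid / math.pi)
    mesh.A_prime = 2.0 * math.pi * mesh.r_k * mesh.width
    q_prime = n_alv * constants.q_alv if convection else np.zeros(n)
    q_in = np.zeros(n)
    q_out = np.zeros(n)
    if convection:
        running = float(q_prime.sum())
        for i in range(n):
            q_in[i] = running
            running -= q_prime[i]
            q_out[i] = running
        q_out[-1] = 0.0
    mesh.Q_in, mesh.Q_out, mesh.Q_prime = q_in, q_out, q_prime
    alv_idx = np.full(n, -1, dtype=int)
    carriers = np.flatnonzero(n_alv > 0)
    alv_idx[carriers] = np.arange(carriers.size)
    mesh.alv_idx = alv_idx
    return mesh
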