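"""Branch-unit parameterisation: flows, lengths, alveolar counts, volumes.

A branch unit (BrU) is a dichotomously branching sub-tree of the acinus whose
generations are merged into serial branch elements (BrEs).  Its whole geometry
is encoded by one continuous structure parameter ``s_tilde = s + b``: the unit
consists of ``s + 1`` full BrEs of length ``l_M`` plus one partial BrE of
length ``a * l_M`` with ``a = 2**b - 1``.  The airway-count factor
``2**(s_tilde+1) - 1`` then fixes the input flow, total alveolar count and
volume of the unit:

    Q_BrU   = (2**(s_tilde+1) - 1) * m_bar_Alv * Q_Alv
    m_Alv   = (2**(s_tilde+1) - 1) * m_bar_Alv
    V_BrU(t)= (2**(s_tilde+1) - 1) * [A_M l_M + m_bar_Alv (V_Alv + Q_Alv t)]

so volume ratios between units are time independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

from .morphometry import AcinarConstants, build_constants

__all__ = [
    "BranchUnitSpec",
    "AcinarModelSpec",
    "stilde_from_flow",
    "flow_from_stilde",
    "stilde_from_volume",
    "split_stilde",
    "unit_length",
    "alveoli_count",
    "unit_volume",
    "unit_volume_sum",
    "airway_volume",
    "volume_ratio",
    "branch_unit",
    "build_model_spec",
    "spec_to_config",
    "write_config",
    "read_config",
    "spec_from_config",
]

#: Physically plausible binary-diffusion range in N2: SF6 (0.1) to He (0.6).
D_PHYSICAL_RANGE = (0.1, 0.6)


def _airway_factor(s_tilde: float) -> float:
    return 2.0 ** (s_tilde + 1.0) - 1.0


def stilde_from_flow(q_bru: float, constants: AcinarConstants) -> float:
    """Invert the flow law for the structure parameter.

    ``s_tilde = log2(0.5 ((Q_BrU/Q_Alv)/m_bar_Alv + 1))``; defined for flows at
    or above the single-BrE minimum ``m_bar_Alv * Q_Alv``.
    """
    q_min = constants.m_bar_alv * constants.q_alv
    if q_bru < q_min * (1.0 - 1e-12):
        raise ValueError(
            f"branch-unit flow {q_bru:.4g} ml/s below the single-BrE minimum "
            f"{q_min:.4g} ml/s (= m_bar_Alv * Q_Alv)"
        )
    return math.log2(0.5 * ((q_bru / constants.q_alv) / constants.m_bar_alv + 1.0))


def flow_from_stilde(s_tilde: float, constants: AcinarConstants) -> float:
    """Input flow of a unit with structure parameter ``s_tilde`` (ml/s)."""
    if s_tilde < 0:
        raise ValueError("structure parameter must be non-negative")
    return _airway_factor(s_tilde) * constants.m_bar_alv * constants.q_alv


def stilde_from_volume(v_bru0: float, constants: AcinarConstants) -> float:
    """Invert the t=0 volume law for the structure parameter (closed form)."""
    base = one_bre_volume(constants)
    if v_bru0 < base * (1.0 - 1e-12):
        raise ValueError(
            f"branch-unit volume {v_bru0:.4g} ml below the single-BrE minimum "
            f"{base:.4g} ml"
        )
    return math.log2(v_bru0 / base + 1.0) - 1.0


def split_stilde(s_tilde: float) -> tuple[int, float, float]:
    """Split ``s_tilde`` into (s, a, b) with s = floor, a = 2**b - 1.

    An exactly integer ``s_tilde`` gives a = b = 0; a = 1 never occurs (it is
    normalised into the next full BrE by the floor).
    """
    if s_tilde < 0:
        raise ValueError("structure parameter must be non-negative")
    s = math.floor(s_tilde)
    b = s_tilde - s
    a = 2.0**b - 1.0
    return s, a, b


def unit_length(s: int, a: float, l_m: float) -> float:
    """Total axial length (s + a + 1) * l_M of a unit, cm."""
    if s < 0 or not 0.0 <= a <= 1.0:
        raise ValueError("need s >= 0 and 0 <= a <= 1")
    return (s + a + 1.0) * l_m


def alveoli_count(s_tilde: float, m_bar_alv: float) -> float:
    """Total alveoli (2**(s_tilde+1) - 1) * m_bar_Alv of a unit."""
    if s_tilde < 0:
        raise ValueError("structure parameter must be non-negative")
    return _airway_factor(s_tilde) * m_bar_alv


def one_bre_volume(constants: AcinarConstants, t: float = 0.0) -> float:
    """Volume of a single BrE with its alveoli at time t (ml)."""
    return (
        constants.a_m * constants.l_m
        + constants.m_bar_alv * (constants.v_alv + constants.q_alv * t)
    )


def unit_volume(s_tilde: float, t: float, constants: AcinarConstants) -> float:
    """Closed-form unit volume: airway tubes plus inflating alveoli (ml)."""
    if s_tilde < 0 or t < 0:
        raise ValueError("need s_tilde >= 0 and t >= 0")
    return _airway_factor(s_tilde) * one_bre_volume(constants, t)


def unit_volume_sum(
    s: int, a: float, t: float, constants: AcinarConstants
) -> float:
    """Unit volume as the explicit per-BrE sum (cross-check of the closed form).

    Sums 2**j over the full BrEs j = 0..s plus the partial BrE's fraction
    a * 2**(s+1); equals :func:`unit_volume` at s_tilde = s + log2(1 + a).
    """
    factor = sum(2.0**j for j in range(s + 1)) + a * 2.0 ** (s + 1)
    return factor * one_bre_volume(constants, t)


def airway_volume(s_tilde: float, constants: AcinarConstants) -> float:
    """Time-constant airway (tube) part of the unit volume, ml."""
    return _airway_factor(s_tilde) * constants.a_m * constants.l_m


@dataclass(frozen=True)
class BranchUnitSpec:
    """Fully derived parameterisation of one branch unit."""

    name: str                 # "BrU0" | "BrU1" | "BrU2"
    s_tilde: float            # structure parameter
    s: int                    # number of full BrEs minus one
    a: float                  # partial-BrE length fraction, in [0, 1)
    b: float                  # fractional exponent, a = 2**b - 1
    q_in: float               # input volume flow, ml/s
    length: float             # total axial length, cm
    n_airways_factor: float   # 2**(s_tilde+1) - 1
    m_alv_total: float        # alveoli in the unit
    v0: float                 # volume at t = 0, ml


def branch_unit(
    name: str,
    constants: AcinarConstants,
    *,
    volume: float | None = None,
    flow: float | None = None,
    s_tilde: float | None = None,
) -> BranchUnitSpec:
    """Build a unit from exactly one of its t=0 volume, input flow or s_tilde.

    When both volume and flow are supplied they must agree (implied flow within
    0.5% of the given one); this guards against inconsistent study tables.
    """
    given = [x is not None for x in (volume, flow, s_tilde)]
    if not any(given):
        raise ValueError(f"{name}: give a volume, a flow, or s_tilde")
    if s_tilde is None:
        if volume is not None:
            s_tilde = stilde_from_volume(volume, constants)
            if flow is not None:
                implied = flow_from_stilde(s_tilde, constants)
                if abs(implied - flow) > 5e-3 * flow:
                    raise ValueError(
                        f"{name}: volume {volume:.4g} ml implies flow "
                        f"{implied:.4g} ml/s, inconsistent with supplied "
                        f"{flow:.4g} ml/s (>0.5%)"
                    )
        else:
            s_tilde = stilde_from_flow(flow, constants)
    s, a, b = split_stilde(s_tilde)
    return BranchUnitSpec(
        name=name,
        s_tilde=s_tilde,
        s=s,
        a=a,
        b=b,
        q_in=flow_from_stilde(s_tilde, constants),
        length=unit_length(s, a, constants.l_m),
        n_airways_factor=_airway_factor(s_tilde),
        m_alv_total=alveoli_count(s_tilde, constants.m_bar_alv),
        v0=unit_volume(s_tilde, 0.0, constants),
    )


@dataclass(frozen=True)
class AcinarModelSpec:
    """A complete single-branch-point acinar model.

    The mother unit BrU0 is always one BrE (s_tilde = 0, 18 alveoli) extended
    proximally by an alveolus-free chamber of length l_M/2 that holds the
    initial tracer bolus.  BrU1/BrU2 are the parallel daughters.
    """

    constants: AcinarConstants
    bru0: BranchUnitSpec
    bru1: BranchUnitSpec
    bru2: BranchUnitSpec
    diffusion_coefficient: float   # D, cm^2/s
    convection_enabled: bool
    f: float                       # V_BrU1 / V_BrU2 (time independent)
    f_sym: float                   # V_BrU1 / V_ref

    @property
    def chamber_length(self) -> float:
        return self.constants.l_m / 2.0

    @property
    def chamber_volume(self) -> float:
        return self.constants.a_m * self.chamber_length

    @property
    def bru0_volume_with_chamber(self) -> float:
        """BrU0 plus chamber volume at t = 0 (the paperwork constant ~3.3e-4 ml)."""
        return self.bru0.v0 + self.chamber_volume

    def total_volume(self, t: float = 0.0) -> float:
        """Whole-model volume (chamber + all three units) at time t, ml.

        Alveoli inflate only when convection is enabled.
        """
        tt = t if self.convection_enabled else 0.0
        units = (self.bru0, self.bru1, self.bru2)
        return self.chamber_volume + sum(
            unit_volume(u.s_tilde, tt, self.constants) for u in units
        )


def volume_ratio(spec: AcinarModelSpec) -> tuple[float, float]:
    """(f, f_sym): daughter volume ratio and ratio of BrU1 to the reference."""
    f = spec.bru1.n_airways_factor / spec.bru2.n_airways_factor
    f_sym = spec.bru1.n_airways_factor / _airway_factor(
        spec.constants.s_tilde_ref
    )
    return f, f_sym


def build_model_spec(
    constants: AcinarConstants | None = None,
    *,
    v_bru1: float | None = None,
    q_bru1: float | None = None,
    v_bru2: float | None = None,
    q_bru2: float | None = None,
    diffusion_coefficient: float = 0.3,
    convection_enabled: bool = True,
) -> AcinarModelSpec:
    """Assemble a model spec from daughter volumes and/or flows.

    Each daughter takes either a t=0 volume (inverted to s_tilde through the
    volume law) or an input flow; BrU0 is fixed at one BrE.  A diffusion
    coefficient outside the physical SF6..He range [0.1, 0.6] cm^2/s is
    accepted with a warning.
    """
    if constants is None:
        constants = build_constants()
    lo, hi = D_PHYSICAL_RANGE
    if not lo <= diffusion_coefficient <= hi:
        import warnings

        warnings.warn(
            f"D = {diffusion_coefficient} cm^2/s is outside the physical "
            f"tracer range [{lo}, {hi}] cm^2/s",
            stacklevel=2,
        )
    bru0 = branch_unit("BrU0", constants, s_tilde=0.0)
    bru1 = branch_unit("BrU1", constants, volume=v_bru1, flow=q_bru1)
    bru2 = branch_unit("BrU2", constants, volume=v_bru2, flow=q_bru2)
    f = bru1.n_airways_factor / bru2.n_airways_factor
    f_sym = bru1.n_airways_factor / _airway_factor(constants.s_tilde_ref)
    return AcinarModelSpec(
        constants=constants,
        bru0=bru0,
        bru1=bru1,
        bru2=bru2,
        diffusion_coefficient=diffusion_coefficient,
        convection_enabled=convection_enabled,
        f=f,
        f_sym=f_sym,
    )


# ---------------------------------------------------------------------------
# flat key=value config round-trip

_CONFIG_KEYS = ("V_BrU1", "V_BrU2", "Q_BrU1", "Q_BrU2", "D", "convection",
                "dx", "t_end")


def spec_to_config(
    spec: AcinarModelSpec, dx: float = 10e-4, t_end: float = 30.0
) -> dict[str, float | bool]:
    return {
        "V_BrU1": spec.bru1.v0,
        "V_BrU2": spec.bru2.v0,
        "Q_BrU1": spec.bru1.q_in,
        "Q_BrU2": spec.bru2.q_in,
        "D": spec.diffusion_coefficient,
        "convection": spec.convection_enabled,
        "dx": dx,
        "t_end": t_end,
    }


def write_config(config: dict, path: str | Path | TextIO) -> None:
    """Write a flat ``key = value`` text config (cm / ml / s units)."""
    lines = [f"{k} = {config[k]!r}" for k in config]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_config(path: str | Path | TextIO) -> dict:
    """Read a flat ``key = value`` config written by :func:`write_config`."""
    text = path.read() if hasattr(path, "read") else Path(path).read_text()
    out: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if value in ("True", "False"):
            out[key] = value == "True"
        else:
            out[key] = float(value)
    unknown = set(out) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return out


def spec_from_config(
    config: dict, constants: AcinarConstants | None = None
) -> tuple[AcinarModelSpec, float, float]:
    """Build (spec, dx, t_end) from a config dict as read by :func:`read_config`."""
    spec = build_model_spec(
        constants,
        v_bru1=config.get("V_BrU1"),
        q_bru1=config.get("Q_BrU1"),
        v_bru2=config.get("V_BrU2"),
        q_bru2=config.get("Q_BrU2"),
        diffusion_coefficient=float(config.get("D", 0.3)),
        convection_enabled=bool(config.get("convection", True)),
    )
    return spec, float(config.get("dx", 10e-4)), float(config.get("t_end", 30.0))
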