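"""Weibel morphometry of the acinus (generations 17-23) and derived constants.

The acinar model is built from Weibel's symmetric-dichotomy lung morphometry.
Generations 17-23 (respiratory bronchioles through alveolar sacs) are averaged
into a single representative bronchiole with mean diameter ``d_M``, mean length
``l_M`` and mean flow velocity ``u_M``.  Together with the tracheal resting
flow ``Q_T`` and the total alveolar count these define every scalar constant
the geometry, mesh and transport layers consume.

Units are CGS-derived throughout: lengths in cm, areas in cm^2, volumes in
ml (= cm^3), flows in ml/s, velocities in cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

__all__ = [
    "WeibelGenerationRecord",
    "AcinarConstants",
    "load_weibel_table",
    "average_morphometry",
    "flow_velocity",
    "mean_alveoli_per_airway",
    "alveolus_geometry",
    "build_constants",
]

#: Acinar rows of Weibel's anatomical table: generation index, bronchiole
#: count 2^z, alveoli per bronchiole, diameter (cm), length (cm) and the
#: tabulated flow velocity (cm/s) at a tracheal flow of 250 ml/s.
_WEIBEL_ROWS: tuple[tuple[int, int, int, float, float, float], ...] = (
    (17, 131_072, 5, 0.0543, 0.14, 0.80),
    (18, 262_144, 8, 0.0504, 0.12, 0.50),
    (19, 524_288, 12, 0.0474, 0.10, 0.30),
    (20, 1_048_576, 20, 0.0451, 0.08, 0.10),
    (21, 2_097_152, 20, 0.0434, 0.07, 0.10),
    (22, 4_194_304, 20, 0.0424, 0.06, 0.04),
    (23, 8_388_608, 17, 0.0419, 0.05, 0.02),
)

ACINAR_GENERATIONS = tuple(range(17, 24))


@dataclass(frozen=True)
class WeibelGenerationRecord:
    """One generation of the acinar morphometry table.

    Attributes
    ----------
    z : generation index (17..23)
    m_br : number of bronchioles in the generation (2**z, symmetric branching)
    m_alv : alveoli per single bronchiole
    d : bronchiole diameter, cm
    l : bronchiole length, cm
    u_printed : tabulated flow velocity, cm/s (kept verbatim; see Notes)

    Notes
    -----
    For generations 18-21 the tabulated velocities are not exactly those given
    by the symmetric-branching formula (:func:`flow_velocity`) with the
    tabulated diameters.  The table values are stored verbatim because the
    mean flow ``Q_M`` downstream is only consistent with their mean; the
    formula remains available separately.
    """

    z: int
    m_br: int
    m_alv: int
    d: float
    l: float
    u_printed: float

    def __post_init__(self) -> None:
        if self.d <= 0 or self.l <= 0:
            raise ValueError("bronchiole diameter and length must be positive")


def load_weibel_table() -> list[WeibelGenerationRecord]:
    """Return the seven acinar generation records (z = 17..23)."""
    return [WeibelGenerationRecord(*row) for row in _WEIBEL_ROWS]


def _require_full_table(records: Sequence[WeibelGenerationRecord]) -> None:
    zs = sorted(r.z for r in records)
    if zs != list(ACINAR_GENERATIONS):
        missing = set(ACINAR_GENERATIONS) - set(zs)
        raise ValueError(
            f"need exactly one record per generation 17..23; missing/extra: "
            f"{sorted(missing) or zs}"
        )


def average_morphometry(
    records: Sequence[WeibelGenerationRecord],
) -> tuple[float, float, float]:
    """Unweighted arithmetic means (d_M, l_M, u_M) over generations 17-23.

    These are the raw column means; :func:`build_constants` rounds them to the
    precision at which the averaged values are tabulated (4/3/2 decimals),
    which is the form all downstream constants are derived from.
    """
    _require_full_table(records)
    n = len(records)
    d_m = sum(r.d for r in records) / n
    l_m = sum(r.l for r in records) / n
    u_m = sum(r.u_printed for r in records) / n
    return d_m, l_m, u_m


def flow_velocity(z: int, d: float, q_t: float) -> float:
    """Flow velocity u(z) = Q_T / (2^z * (pi/4) d^2) under symmetric branching.

    Parameters are the generation index, the bronchiole diameter in cm and the
    tracheal volume flow in ml/s; the result is in cm/s.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if z < 0:
        raise ValueError("generation index must be non-negative")
    return q_t / (2**z * (math.pi / 4.0) * d * d)


def mean_alveoli_per_airway(
    records: Iterable[WeibelGenerationRecord],
) -> tuple[float, int]:
    """Bronchiole-count-weighted mean alveoli per airway, raw and rounded.

    Returns ``(m_bar, round(m_bar))``.  The rounded integer (18 for the full
    table) is what the volume and flow laws use; the raw value is retained for
    diagnostics.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one generation record")
    total_br = sum(r.m_br for r in records)
    m_bar = sum(r.m_alv * r.m_br for r in records) / total_br
    return m_bar, round(m_bar)


def alveolus_geometry(lung_rest_volume: float) -> tuple[float, float]:
    """Alveolus diameter and spherical base volume from the resting lung volume.

    ``d_Alv = 1.54e-3 * V_rest^(1/3)`` with ``V_rest`` in ml (3 litres of
    resting volume -> 3000 ml -> d_Alv = 222 um), and ``V_Alv = pi/6 d_Alv^3``.
    """
    if lung_rest_volume <= 0:
        raise ValueError("lung resting volume must be positive (ml)")
    d_alv = 1.54e-3 * lung_rest_volume ** (1.0 / 3.0)
    v_alv = math.pi / 6.0 * d_alv**3
    return d_alv, v_alv


@dataclass(frozen=True)
class AcinarConstants:
    """All scalar constants of the averaged acinar model.

    ``d_M``/``l_M``/``u_M`` are the averaged bronchiole dimensions at the
    tabulated precision; ``A_M`` the mean cross-section; ``Q_M`` the mean
    branch-unit input flow; ``Q_Alv`` the per-alveolus filling flow;
    ``s_tilde_ref``/``V_ref`` the reference structure parameter and volume of
    a branch unit driven by ``Q_M``.
    """

    q_t: float                  # tracheal volume flow, ml/s
    d_m: float                  # mean bronchiole diameter, cm
    l_m: float                  # mean bronchiole length, cm
    u_m: float                  # mean flow velocity, cm/s
    a_m: float                  # mean cross-section pi/4 d_M^2, cm^2
    q_m: float                  # mean flow A_M * u_M, ml/s
    m_bar_alv_raw: float        # weighted mean alveoli per airway, unrounded
    m_bar_alv: int              # rounded mean alveoli per airway
    n_alv_total: float          # total alveoli in the lung
    q_alv: float                # per-alveolus volume flow Q_T / N_Alv, ml/s
    lung_rest_volume: float     # resting lung volume, ml
    d_alv: float                # alveolus diameter, cm
    v_alv: float                # alveolus base volume, ml
    s_tilde_ref: float          # reference structure parameter (from Q_M)
    v_ref: float                # reference branch-unit volume at t=0, ml

    def as_dict(self) -> dict[str, float]:
        """Flat key-value dump (for config export / run manifests)."""
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_constants(
    q_t: float = 250.0,
    n_alv_total: float = 300e6,
    lung_rest_volume: float = 3000.0,
) -> AcinarConstants:
    """Assemble every derived constant of the averaged acinar model.

    Defaults are resting breathing: 250 ml/s tracheal flow (500 ml tidal
    volume at 15 breaths/min), 3e8 alveoli, 3 l resting lung volume.
    """
    if q_t <= 0 or n_alv_total <= 0 or lung_rest_volume <= 0:
        raise ValueError("all model constants must be positive")
    records = load_weibel_table()
    d_raw, l_raw, u_raw = average_morphometry(records)
    # canonical constants are the tabulated averaged values (printed precision)
    d_m = round(d_raw, 4)
    l_m = round(l_raw, 3)
    u_m = round(u_raw, 2)
    a_m = math.pi / 4.0 * d_m * d_m
    q_m = a_m * u_m
    m_bar_raw, m_bar = mean_alveoli_per_airway(records)
    q_alv = q_t / n_alv_total
    d_alv, v_alv = alveolus_geometry(lung_rest_volume)

    from . import geometry  # late import: geometry consumes constants

    partial = AcinarConstants(
        q_t=q_t, d_m=d_m, l_m=l_m, u_m=u_m, a_m=a_m, q_m=q_m,
        m_bar_alv_raw=m_bar_raw, m_bar_alv=m_bar, n_alv_total=n_alv_total,
        q_alv=q_alv, lung_rest_volume=lung_rest_volume, d_alv=d_alv,
        v_alv=v_alv, s_tilde_ref=float("nan"), v_ref=float("nan"),
    )
    s_ref = geometry.stilde_from_flow(q_m, partial)
    v_ref = geometry.unit_volume(s_ref, 0.0, partial)
    return AcinarConstants(
        q_t=q_t, d_m=d_m, l_m=l_m, u_m=u_m, a_m=a_m, q_m=q_m,
        m_bar_alv_raw=m_bar_raw, m_bar_alv=m_bar, n_alv_total=n_alv_total,
        q_alv=q_alv, lung_rest_volume=lung_rest_volume, d_alv=d_alv,
        v_alv=v_alv, s_tilde_ref=s_ref, v_ref=v_ref,
    )
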