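"""Analysis of tracer-volume kinetics: phases, exponential fits, trend lines.

The simulated mole fractions are reduced to per-unit tracer volumes
V_g,BrUi(t) (Eq. sum chi V over the unit's airway and alveolar compartments,
with the chamber counted as part of BrU0).  Under asymmetric geometry the
filling of the daughters shows two phases of diffusive Pendelluft: both
daughters first fill from the mother; once the smaller daughter peaks (at
t_p1) it starts feeding the larger one.  Each phase is summarised by a
monoexponential growth law

    V(t) = V_end + (V_start - V_end) * exp(-lambda * (t - t_start))

fitted by Levenberg-Marquardt; the growth constant lambda captures the
dynamics, V_end the (quasi-)steady distribution.  Across many runs, lambda of
the mother unit rises approximately linearly with the total branch-point flow
above a threshold, and the slope of that trend line quantifies how sensitive
a tracer gas is to convective flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import AcinarModelSpec, unit_volume
from .transport import TracerTrajectory

__all__ = [
    "GrowthFit",
    "PhaseSplit",
    "TrendLine",
    "tracer_volume_per_unit",
    "steady_state_prediction",
    "detect_phase_transition",
    "fit_growth",
    "fit_unit_phases",
    "trendline",
]

UNIT_COLUMNS = ("V_g_BrU0", "V_g_BrU1", "V_g_BrU2")


def tracer_volume_per_unit(traj: TracerTrajectory) -> pd.DataFrame:
    """Per-unit tracer volumes over time (ml), chamber counted with BrU0.

    Columns: t_s, V_g_BrU0, V_g_BrU1, V_g_BrU2, total_ml.  The alveolar part
    uses the time-dependent alveolar volumes when convection inflates them.
    """
    mesh = traj.mesh
    t = traj.times
    carriers = np.flatnonzero(mesh.alv_idx >= 0)
    out = {"t_s": t}
    for unit, col in enumerate(UNIT_COLUMNS):
        air = mesh.unit == unit
        v = traj.chi[:, air] @ mesh.V_k[air]
        in_unit = mesh.unit[carriers] == unit
        if in_unit.any():
            cols = mesh.alv_idx[carriers[in_unit]]
            base = traj.chi_alv[:, cols] @ mesh.V_alv0[carriers[in_unit]]
            grow = traj.chi_alv[:, cols] @ mesh.Q_prime[carriers[in_unit]]
            v = v + base + grow * t
        out[col] = v
    df = pd.DataFrame(out)
    df["total_ml"] = df[list(UNIT_COLUMNS)].sum(axis=1)
    return df


def steady_state_prediction(
    spec: AcinarModelSpec, t: float = 0.0, v_g_tr: float | None = None
) -> dict[str, float]:
    """Equilibrium tracer volume of each unit: its share of the model volume.

    At steady state the mole fraction is uniform, so each unit holds
    V_unit(t)/V_tot(t) of the total tracer volume ``v_g_tr`` (default: the
    analytic half-sine bolus integral 2/pi * A_M * l_M/2).
    """
    c = spec.constants
    if v_g_tr is None:
        v_g_tr = (2.0 / np.pi) * c.a_m * spec.chamber_length
    tt = t if spec.convection_enabled else 0.0
    v_tot = spec.total_volume(tt)
    vols = {
        "V_g_BrU0": unit_volume(spec.bru0.s_tilde, tt, c) + spec.chamber_volume,
        "V_g_BrU1": unit_volume(spec.bru1.s_tilde, tt, c),
        "V_g_BrU2": unit_volume(spec.bru2.s_tilde, tt, c),
    }
    return {k: v / v_tot * v_g_tr for k, v in vols.items()}


@dataclass(frozen=True)
class PhaseSplit:
    """Phase boundary of a daughter filling curve.

    ``has_second_phase`` is False for symmetric geometry (or any monotone
    non-decreasing series), in which case t_p1 equals the end of the record.
    """

    t_p1: float
    has_second_phase: bool


def detect_phase_transition(
    times: np.ndarray, series: np.ndarray, rel_tol: float = 1e-9
) -> PhaseSplit:
    """Find t_p1, the peak of the smaller unit's tracer volume.

    The first phase ends when the series attains its maximum; a maximum at
    (or numerically indistinguishable from) the final sample means the net
    inflow never reversed and there is no second phase.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    i_max = int(np.argmax(series))
    peak = series[i_max]
    if i_max == series.size - 1 or peak - series[-1] <= rel_tol * max(abs(peak), 1e-300):
        return PhaseSplit(t_p1=float(times[-1]), has_second_phase=False)
    return PhaseSplit(t_p1=float(times[i_max]), has_second_phase=True)


@dataclass(frozen=True)
class GrowthFit:
    """One monoexponential growth-law fit over a phase window."""

    unit: str
    phase: int
    t_start: float
    t_end: float
    v_start: float        # fitted value at t_start, ml
    v_end: float          # fitted asymptote/end value, ml
    lam: float            # growth constant, 1/s
    r2: float
    rmse: float           # ml
    ok: bool = True       # False when lambda is unidentifiable (flat series)


def _growth_model(tau: np.ndarray, v_start: float, v_end: float, lam: float):
    return v_end + (v_start - v_end) * np.exp(-lam * tau)


def fit_growth(
    times: np.ndarray,
    values: np.ndarray,
    t_start: float,
    t_end: float,
    unit: str = "",
    phase: int = 1,
    trim_plateau: bool = False,
) -> GrowthFit:
    """Levenberg-Marquardt fit of the monoexponential growth law on a window.

    Three free parameters (V_start, V_end, lambda) with initial guesses
    (first sample, last sample, 5/window).  The time origin is the window
    start, the only reading under which the fitted V_start is the value at
    t_start.  ``trim_plateau`` optionally drops the initial transport-delay
    plateau (samples before the curve first moves by 1% of its range); by
    default the whole phase is fitted, misfit showing up in R2/RMSE.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (times >= t_start) & (times <= t_end)
    t = times[sel]
    y = values[sel]
    if t.size < 10:
        raise ValueError(f"need >= 10 samples in [{t_start}, {t_end}], "
                         f"got {t.size}")
    if trim_plateau:
        span = np.ptp(y)
        if span > 0:
            moved = np.abs(y - y[0]) > 0.01 * span
            if moved.any():
                first = int(np.argmax(moved))
                keep = max(first - 1, 0)
                if t.size - keep >= 10:
                    t, y = t[keep:], y[keep:]
    tau = t - t[0]
    span = np.ptp(y)
    scale = max(abs(y).max(), 1e-300)
    if span <= 1e-9 * scale:
        # flat series: the growth constant is unidentifiable
        return GrowthFit(unit=unit, phase=phase, t_start=float(t[0]),
                         t_end=float(t[-1]), v_start=float(y[0]),
                         v_end=float(y[0]), lam=float("nan"), r2=float("nan"),
                         rmse=0.0, ok=False)
    lam0 = 5.0 / (t[-1] - t[0])
    best = None
    last_err: Exception | None = None
    for factor in (1.0, 0.3, 3.0, 10.0, 0.1):
        try:
            popt, _ = curve_fit(
                _growth_model, tau, y,
                p0=(y[0], y[-1], lam0 * factor),
                method="lm", maxfev=20000,
            )
        except RuntimeError as err:  # no convergence for this start
            last_err = err
            continue
        resid = y - _growth_model(tau, *popt)
        ss_res = float(resid @ resid)
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
        if ss_res <= (1e-6 * span) ** 2 * t.size:
            break
    if best is None:
        raise RuntimeError(
            f"growth fit did not converge on [{t_start}, {t_end}]"
        ) from last_err
    popt, ss_res = best
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return GrowthFit(
        unit=unit, phase=phase, t_start=float(t[0]), t_end=float(t[-1]),
        v_start=float(popt[0]), v_end=float(popt[1]), lam=abs(float(popt[2])),
        r2=r2, rmse=float(np.sqrt(ss_res / t.size)), ok=True,
    )


def fit_unit_phases(
    df: pd.DataFrame,
    spec: AcinarModelSpec | None = None,
    trim_plateau: bool = False,
) -> list[GrowthFit]:
    """Fit the growth law per unit and phase for one run's V_g table.

    BrU0 always gets a single full-window fit (it only empties).  The phase
    boundary t_p1 is the peak of the daughter with the smaller volume at t=0;
    both daughters are then fitted per phase.  Symmetric runs (equal t=0
    volumes or monotone series) have a single phase.
    """
    t = df["t_s"].to_numpy()
    fits = [fit_growth(t, df["V_g_BrU0"].to_numpy(), t[0], t[-1],
                       unit="BrU0", phase=1, trim_plateau=trim_plateau)]
    v1, v2 = df["V_g_BrU1"].to_numpy(), df["V_g_BrU2"].to_numpy()
    # the smaller unit is the one with less volume at t=0 (ties -> symmetric,
    # no second phase); without a spec, the series' final values are an
    # equivalent proxy since equilibrium shares are proportional to volume
    small = None
    if spec is not None:
        if not np.isclose(spec.bru1.v0, spec.bru2.v0, rtol=1e-12):
            small = v1 if spec.bru1.v0 < spec.bru2.v0 else v2
    elif not np.isclose(v1[-1], v2[-1], rtol=1e-9):
        small = v1 if v1[-1] < v2[-1] else v2
    split = (detect_phase_transition(t, small)
             if small is not None else PhaseSplit(float(t[-1]), False))
    for name, series in (("BrU1", v1), ("BrU2", v2)):
        if split.has_second_phase:
            # a phase-1 window shorter than 10 output samples (a tiny daughter
            # peaking almost immediately) cannot support a 3-parameter fit and
            # is skipped
            if np.count_nonzero(t <= split.t_p1) >= 10:
                fits.append(fit_growth(t, series, t[0], split.t_p1, unit=name,
                                       phase=1, trim_plateau=trim_plateau))
            fits.append(fit_growth(t, series, split.t_p1, t[-1], unit=name,
                                   phase=2, trim_plateau=trim_plateau))
        else:
            fits.append(fit_growth(t, series, t[0], t[-1], unit=name,
                                   phase=1, trim_plateau=trim_plateau))
    return fits


@dataclass(frozen=True)
class TrendLine:
    """OLS line of the mother unit's growth constant vs total flow."""

    diffusion_coefficient: float   # cm^2/s
    flows_ul_s: np.ndarray         # total branch-point flows used, ul/s
    lambdas: np.ndarray            # fitted growth constants, 1/s
    flow_threshold: float          # ml/s, points at or below are excluded
    slope: float                   # 1/(s ul)
    intercept: float               # 1/s
    r2: float

    @property
    def n_points(self) -> int:
        return int(self.flows_ul_s.size)


def trendline(
    flows: np.ndarray,
    lambdas: np.ndarray,
    diffusion_coefficient: float,
    threshold: float = 5e-4,
) -> TrendLine:
    """Regress lambda_BrU0 on total branch-point flow above the threshold.

    ``flows`` are Q_BrU1 + Q_BrU2 in ml/s; the slope is reported per
    microlitre (1/(s*ul)), the scale on which the flow sensitivity of
    different tracer gases is compared.
    """
    flows = np.asarray(flows, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    keep = flows > threshold
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 points with total flow above {threshold} ml/s, "
            f"got {int(keep.sum())}"
        )
    q_ul = flows[keep] * 1e3  # ml/s -> ul/s
    lam = lambdas[keep]
    slope, intercept = np.polyfit(q_ul, lam, 1)
    pred = slope * q_ul + intercept
    ss_res = float(((lam - pred) ** 2).sum())
    ss_tot = float(((lam - lam.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return TrendLine(
        diffusion_coefficient=diffusion_coefficient,
        flows_ul_s=q_ul,
        lambdas=lam,
        flow_threshold=threshold,
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
    )
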