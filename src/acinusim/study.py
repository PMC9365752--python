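"""The packaged three-part parameter study and its one-command runner.

Part 1 varies the (symmetric) daughter volume over six values, each run once
with pure diffusion and once with added convection.  Part 2 varies only BrU1
while BrU2 stays at the reference volume.  Part 3 fixes an asymmetric
geometry (BrU1 half of BrU2) and sweeps the diffusion coefficient over the
SF6..He range.  The sensitivity study reruns Parts 1+2 with convection at
D = 0.1/0.3/0.6 cm^2/s and regresses the mother unit's growth constant on the
total branch-point flow.

All numbers are deterministic; rerunning a study reproduces its CSVs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, kinetics, transport
from .mesh import DEFAULT_DX, discretize
from .morphometry import AcinarConstants, build_constants

__all__ = ["SimulationCase", "StudyDefinition", "table3_configs", "run_study",
           "run_case"]

# (sim, f_sym, V_BrU1, V_BrU2, Q_BrU1, Q_BrU2) for the symmetric study;
# volumes in ml at t=0, flows in ml/s as tabulated
_PART1 = (
    (1, 0.074, 5.76e-4, 5.76e-4, 3.41e-5, 3.41e-5),
    (2, 0.796, 6.19e-3, 6.19e-3, 3.67e-4, 3.67e-4),
    (3, 1.000, 7.76e-3, 7.76e-3, 4.60e-4, 4.60e-4),
    (4, 1.519, 1.18e-2, 1.18e-2, 6.99e-4, 6.99e-4),
    (5, 2.241, 1.74e-2, 1.74e-2, 1.03e-3, 1.03e-3),
    (6, 2.963, 2.30e-2, 2.30e-2, 1.36e-3, 1.36e-3),
)
# (sim, f, V_BrU1, V_BrU2, Q_BrU1, Q_BrU2): BrU2 fixed at the reference
_PART2 = (
    (1, 0.074, 5.76e-4, 7.76e-3, 3.41e-5, 4.60e-4),
    (2, 0.796, 6.19e-3, 7.76e-3, 3.67e-4, 4.60e-4),
    (3, 1.000, 7.76e-3, 7.76e-3, 4.60e-4, 4.60e-4),
    (4, 1.519, 1.18e-2, 7.76e-3, 6.99e-4, 4.60e-4),
    (5, 2.241, 1.74e-2, 7.76e-3, 1.03e-3, 4.60e-4),
    (6, 2.963, 2.30e-2, 7.76e-3, 1.36e-3, 4.60e-4),
)
_PART3_GEOMETRY = (3.88e-3, 7.76e-3, 2.3e-4, 4.6e-4)  # V1, V2, Q1, Q2
_PART3_D_GRID = (0.1, 0.225, 0.35, 0.475, 0.6)
_SENSITIVITY_D_GRID = (0.1, 0.3, 0.6)
_DEFAULT_D = 0.3


@dataclass(frozen=True)
class SimulationCase:
    """One row of the study table: a geometry, flows, D and transport mode."""

    part: str            # "1" | "2" | "3" | "sensitivity"
    sim: int
    convection: bool
    v_bru1: float        # ml at t=0
    v_bru2: float        # ml at t=0
    q_bru1: float        # tabulated input flow, ml/s
    q_bru2: float        # ml/s
    diffusion_coefficient: float  # cm^2/s

    @property
    def label(self) -> str:
        mode = "conv" if self.convection else "diff"
        return (f"part{self.part}_sim{self.sim}_{mode}_"
                f"D{self.diffusion_coefficient:g}")

    @property
    def total_flow(self) -> float:
        """Total branch-point flow Q_BrU1 + Q_BrU2, ml/s."""
        return self.q_bru1 + self.q_bru2

    def build_spec(
        self, constants: AcinarConstants | None = None
    ) -> geometry.AcinarModelSpec:
        """Model spec from the tabulated t=0 volumes (flows follow exactly)."""
        return geometry.build_model_spec(
            constants,
            v_bru1=self.v_bru1,
            v_bru2=self.v_bru2,
            diffusion_coefficient=self.diffusion_coefficient,
            convection_enabled=self.convection,
        )


@dataclass(frozen=True)
class StudyDefinition:
    part: str
    cases: tuple[SimulationCase, ...]


def _cases_from_rows(part, rows, convection_modes, d_values):
    cases = []
    for conv in convection_modes:
        for d in d_values:
            for sim, _f, v1, v2, q1, q2 in rows:
                cases.append(SimulationCase(
                    part=part, sim=sim, convection=conv, v_bru1=v1, v_bru2=v2,
                    q_bru1=q1, q_bru2=q2, diffusion_coefficient=d,
                ))
    return cases


def table3_configs(part: str | int) -> StudyDefinition:
    """The tabulated study configurations for one part.

    Part "1"/"2": six volume pairs x {pure diffusion, +convection} at the test
    tracer's D = 0.3 cm^2/s.  Part "3": the fixed asymmetric geometry x five
    diffusion coefficients x both modes.  "sensitivity": the Part 1+2
    convection runs at D = 0.1, 0.3 and 0.6 cm^2/s.
    """
    part = str(part)
    if part == "1":
        cases = _cases_from_rows("1", _PART1, (False, True), (_DEFAULT_D,))
    elif part == "2":
        cases = _cases_from_rows("2", _PART2, (False, True), (_DEFAULT_D,))
    elif part == "3":
        v1, v2, q1, q2 = _PART3_GEOMETRY
        cases = [
            SimulationCase(part="3", sim=i + 1, convection=conv, v_bru1=v1,
                           v_bru2=v2, q_bru1=q1, q_bru2=q2,
                           diffusion_coefficient=d)
            for conv in (False, True)
            for i, d in enumerate(_PART3_D_GRID)
        ]
    elif part == "sensitivity":
        cases = []
        for d in _SENSITIVITY_D_GRID:
            for rows, p in ((_PART1, "1"), (_PART2, "2")):
                for sim, _f, v1, v2, q1, q2 in rows:
                    cases.append(SimulationCase(
                        part="sensitivity", sim=sim, convection=True,
                        v_bru1=v1, v_bru2=v2, q_bru1=q1, q_bru2=q2,
                        diffusion_coefficient=d,
                    ))
    else:
        raise ValueError(f"unknown study part {part!r}; "
                         "use 1, 2, 3 or 'sensitivity'")
    return StudyDefinition(part=part, cases=tuple(cases))


def run_case(
    case: SimulationCase,
    constants: AcinarConstants | None = None,
    dx: float = DEFAULT_DX,
    config: transport.SimulationConfig | None = None,
):
    """Run one study case end to end.

    Returns (spec, trajectory, V_g table, growth fits).
    """
    if config is None:
        config = transport.SimulationConfig()
    spec = case.build_spec(constants)
    config = replace(config, diffusion_coefficient=case.diffusion_coefficient)
    mesh = discretize(spec, dx)
    traj = transport.simulate(mesh, config)
    df = kinetics.tracer_volume_per_unit(traj)
    fits = kinetics.fit_unit_phases(df, spec)
    return spec, traj, df, fits


def _fits_frame(label: str, fits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case": label, "unit": f.unit, "phase": f.phase,
                "t_start_s": f.t_start, "t_end_s": f.t_end,
                "V_start_ml": f.v_start, "V_end_ml": f.v_end,
                "lambda_1_s": f.lam, "R2": f.r2, "RMSE_ml": f.rmse,
            }
            for f in fits
        ]
    )


def run_study(
    definition: StudyDefinition,
    out_dir: str | Path,
    dx: float = DEFAULT_DX,
    t_end: float = 30.0,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
    n_output: int = 3001,
) -> dict:
    """Run every case of a study and write the result bundle to ``out_dir``.

    Per case: a trajectory CSV (t, per-unit V_g, total) and a fits row; per
    study: fits.csv, steady_state.csv (simulated end values vs the equilibrium
    prediction) and a manifest of every constant and setting.  The sensitivity
    study additionally writes trendlines.csv (slope per D).  On a failing
    case, results already written are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    constants = build_constants()
    config = transport.SimulationConfig(
        t_end=t_end, n_output=n_output, rel_tol=rel_tol, abs_tol=abs_tol
    )
    all_fits, steady_rows = [], []
    lambda_bru0: dict[float, list[tuple[float, float]]] = {}
    results: dict = {"part": definition.part, "cases": {}}
    for case in definition.cases:
        spec, traj, df, fits = run_case(case, constants, dx, config)
        df.to_csv(out / f"trajectory_{case.label}.csv", index=False)
        all_fits.append(_fits_frame(case.label, fits))
        pred = kinetics.steady_state_prediction(
            spec, t=traj.times[-1],
            v_g_tr=transport.total_tracer(
                transport.initial_condition(traj.mesh), traj.mesh
            ),
        )
        for col in kinetics.UNIT_COLUMNS:
            steady_rows.append({
                "case": case.label, "unit": col.removeprefix("V_g_"),
                "simulated_ml": float(df[col].iloc[-1]),
                "predicted_ml": pred[col],
            })
        if case.convection:
            lam0 = next(f.lam for f in fits if f.unit == "BrU0")
            lambda_bru0.setdefault(
                case.diffusion_coefficient, []
            ).append((case.total_flow, lam0))
        results["cases"][case.label] = {
            "conservation_drift": traj.conservation_drift,
            "fits": fits,
        }
    fits_df = pd.concat(all_fits, ignore_index=True)
    fits_df.to_csv(out / "fits.csv", index=False)
    steady_df = pd.DataFrame(steady_rows)
    steady_df.to_csv(out / "steady_state.csv", index=False)
    results["fits"] = fits_df
    results["steady_state"] = steady_df
    if definition.part == "sensitivity":
        trend_rows = []
        results["trendlines"] = {}
        for d, pts in sorted(lambda_bru0.items()):
            flows = np.array([p[0] for p in pts])
            lams = np.array([p[1] for p in pts])
            tl = kinetics.trendline(flows, lams, d)
            results["trendlines"][d] = tl
            trend_rows.append({
                "D_cm2_s": d, "slope_1_s_ul": tl.slope,
                "intercept_1_s": tl.intercept, "R2": tl.r2,
                "n_points": tl.n_points,
                "flow_threshold_ml_s": tl.flow_threshold,
            })
        pd.DataFrame(trend_rows).to_csv(out / "trendlines.csv", index=False)
    _write_manifest(out / "manifest.txt", definition, constants, dx, config)
    return results


def _write_manifest(path, definition, constants, dx, config) -> None:
    lines = [f"study_part = {definition.part}", f"dx_cm = {dx!r}",
             f"t_end_s = {config.t_end!r}", f"n_output = {config.n_output}",
             f"rel_tol = {config.rel_tol!r}", f"abs_tol = {config.abs_tol!r}",
             "solver = BDF (analytic sparse Jacobian)"]
    lines += [f"const.{k} = {v!r}" for k, v in constants.as_dict().items()]
    lines += [f"case.{c.label} = V1={c.v_bru1!r} V2={c.v_bru2!r} "
              f"Q1={c.q_bru1!r} Q2={c.q_bru2!r} D={c.diffusion_coefficient!r}"
              for c in definition.cases]
    Path(path).write_text("\n".join(lines) + "\n")
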