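# Methods

## Model

`acinusim` simulates inert tracer-gas transport in a single-branch-point
model of the pulmonary acinus. The geometry is built from Weibel's
symmetric-dichotomy morphometry of generations 17–23: the per-generation
diameters, lengths and flow velocities are averaged into one representative
bronchiole, so the whole acinar subtree of a branch unit can be collapsed
into a chain of cylindrical *branch elements* (BrEs), the j-th having
cross-section `2^j · A_M` (the merged area of its `2^j` parallel airways) and
length `l_M`. The model has three branch units: a mother BrU0 (one BrE plus
an alveolus-free chamber of length `l_M/2` holding the initial bolus) and two
parallel daughters BrU1/BrU2 whose sizes are free parameters.

A unit's size is encoded by the continuous structure parameter `s̃ = s + b`:
`s + 1` full BrEs plus a partial BrE of length `a·l_M`, `a = 2^b − 1`. All of
its extensive properties carry the same airway-count factor `2^(s̃+1) − 1`:
input flow, alveolar count `(2^(s̃+1)−1)·m̄_Alv`, and volume. Because of
this common factor, the volume ratio of two units is constant in time even
while the alveoli inflate — which is what makes a single ratio `f =
V_BrU1/V_BrU2` a meaningful study axis.

Assumptions inherited from the model class: identical averaged bronchioles
within a unit (no per-generation heterogeneity), uniform alveolar compliance
(every alveolus fills at the same constant `Q_Alv`), inspiration only (flows
non-negative), no Taylor dispersion, no gas exchange with blood, no mucosal
ad-/absorption.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `Q_T` | 250 ml/s | tracheal flow at resting breathing (500 ml, 15/min) |
| `N_Alv` | 3·10⁸ | total alveoli; gives `Q_Alv = 8.33·10⁻⁷ ml/s` |
| lung resting volume | 3000 ml | sets `d_Alv = 1.54·10⁻³·V^{1/3} = 222 µm` |
| `d_M, l_M, u_M` | 0.0464 cm, 0.089 cm, 0.27 cm/s | averaged bronchiole |
| `m̄_Alv` | 18 | rounded weighted mean alveoli per airway (17.93 raw) |
| `D` | 0.3 cm²/s | tracer diffusion coefficient; physical range 0.1 (SF₆ in N₂) to 0.6 (He in N₂) |
| `Δx` | 10 µm | axial compartment width |
| `t_end` | 30 s | horizon; long enough to reach the diffusive steady state |

The canonical averaged dimensions are the *tabulated* (rounded) values, not
the raw column means: every downstream constant of the model family
(`Q_M = A_M·u_M = 4.57·10⁻⁴ ml/s`, the 89-compartment BrE, the reference
volume `V_ref = 7.72·10⁻³ ml`, the mother-plus-chamber volume
`3.29·10⁻⁴ ml`) is consistent with that choice. The raw means remain
available from `average_morphometry` for diagnostics. The tabulated
velocities for generations 18–21 are not exactly reproduced by the
symmetric-branching formula with the tabulated diameters; both are exposed
(`u_printed` vs `flow_velocity`) and no reconciliation is attempted.

## Discretisation

Each segment (full BrE, partial BrE, chamber) of length `L` is divided into
`round_half_up(L/Δx)` compartments of uniform width `L/n ≈ Δx`. Using the
exact width rather than forcing `Δx` makes the discretised airway volume and
the alveolar budget of every unit *identical* to the closed-form laws (to
float precision); plain count-rounding would perturb them by up to half a
compartment per segment. With the default `Δx` a full BrE has 89 compartments
and the chamber 45. A partial BrE shorter than `Δx/2` contributes no axial
compartment; its alveoli are folded into the unit's distal compartment so the
flow budget is preserved (its sub-nanolitre airway volume is dropped — the
only case where volume exactness is relaxed, and one that does not occur in
the packaged studies).

Compartment volumes use the segment's own area; only the *faces* between
segments (and the two daughter faces at the branch point) carry the
arithmetic mean of the abutting areas, which removes the area step from the
diffusive flux without touching volumes. Alveoli are spread uniformly over
each BrE's surface; each compartment's alveolar uptake is `n_alv·Q_Alv`, and
one common per-unit rescale (numerically ≈1) pins the summed uptake to the
unit's input flow, so convective face flows decrease distally to exactly zero
at the closed terminal faces. The airway–alveolus exchange uses the merged
cylinder's radius `r_k = √(A_mid/π)` as diffusion distance and lateral
surface `A' = 2π r_k Δx`; the alternative per-airway radius (larger surface
by √2^j) is a known open choice and is not implemented.

## Transport and numerics

The mole-fraction balance (upwind convection + Fickian diffusion, see
README) yields a linear system `dy/dt = J(t)·y` in which only the alveolar
rows depend on time (through `V_alv(t) = V_alv0 + Q'·t`). The inlet membrane
is realised as: convective inflow carries `χ = 0` and the diffusive tracer
flux through the inlet face is zero — the tracer is exactly conserved, which
the integrator monitors (warning above 10³·rtol; observed drift ≲ 10⁻⁵).

Integration uses `scipy.integrate.solve_ivp` with the BDF method and the
analytic sparse Jacobian. The diffusive rate scale `D/Δx² ≈ 3·10⁵ s⁻¹`
against kinetics of interest on seconds makes the system stiff, so an
explicit scheme of the original model class would need ~10⁶ steps where BDF
takes thousands. Defaults: `rtol = 10⁻⁶`, `atol = 10⁻⁹`, 3000 uniform output
intervals over the horizon (dense enough for the fits). Correctness of the
assembled operator is checked against hand-written flux loops integrated by
fixed-step forward Euler (dt = 10⁻⁷ s) on small ducts, and against the
closed-form two-compartment relaxation
`χ₁−χ₂ ∝ exp(−D·A(1/V₁+1/V₂)t/Δx)`.

## Kinetics analysis

Per-unit tracer volumes `V_g,BrUi(t) = Σ χ V` (chamber counted with BrU0)
are fitted with the shifted monoexponential `V(t) = V_end +
(V_start−V_end)·e^{−λ(t−t_start)}` — the time origin is the window start,
the only reading under which the fitted `V_start` is the value at `t_start`.
Fits use Levenberg–Marquardt with initial guesses (first sample, last
sample, 5/window) and a small deterministic ladder of λ restarts. The
early transport-delay plateau is *included* in the fit window by default
(misfit shows up in R²/RMSE); an optional `trim_plateau` flag drops it. Flat
series are flagged as λ-unidentifiable rather than fitted. The phase
boundary `t_p1` is the peak of the daughter with the smaller t=0 volume;
monotone series (symmetric geometry) have a single phase, and a phase-1
window shorter than 10 output samples is skipped as unfittable.

The flow-sensitivity trend line regresses the mother unit's λ on the total
branch-point flow `Q_BrU1+Q_BrU2` over the convection runs of study Parts
1+2, restricted to flows above 5·10⁻⁴ ml/s, with the slope reported per
microlitre. The threshold follows the body-text value of the model family's
description (an alternative figure-caption value of 5 ml/s exceeds every
flow in the study by orders of magnitude and is discarded).

## Packaged study

`table3_configs` embeds the study table: Part 1 — six symmetric daughter
volumes from 5.76·10⁻⁴ to 2.30·10⁻² ml, each run with pure diffusion and
with convection at D = 0.3 cm²/s; Part 2 — the same BrU1 sweep against a
fixed reference BrU2 (7.76·10⁻³ ml, 4.60·10⁻⁴ ml/s); Part 3 — fixed
asymmetric geometry (BrU1 half of BrU2) across D ∈ {0.1, 0.225, 0.35, 0.475,
0.6} cm²/s, both modes; sensitivity — Parts 1+2 with convection at D ∈
{0.1, 0.3, 0.6}. Geometries are specified by their t = 0 volumes; input
flows follow exactly from the volume law (and agree with the tabulated flows
to <0.5%, the tabulated values being rounded).

## Design choices made where the design was open

- **Canonical constants from tabulated precision** (see above); the raw-mean
  alternative shifts every derived constant by ~0.5–2% and breaks the
  half-integer chamber/BrE compartment counts.
- **Exact-width compartments** instead of fixed-`Δx` with rounded counts
  (volume and flow budgets become exact; all reference counts unchanged).
- **Taper by mean-area faces only**; how the original model "adjusted
  diameters at transitions" is not specified beyond linearity, and this
  choice is the minimal one preserving volumes.
- **Branch-point convection split** proportional to the daughters' input
  flows; diffusion through per-daughter interface faces with the daughters'
  own face areas.
- **Steady-state acceptance run** uses D = 0.3 cm²/s, the canonical test
  tracer of the model family.

## Known limitations

- The monoexponential law is an acknowledged simplification: early plateaus
  and the branch-point geometry leave structured residuals (R² ≈ 0.93–0.99),
  and fitted λ of fast phases depend mildly on the output sampling density.
- Tracer volumes at equilibrium differ from tabulated reference values by the
  ~0.5% internal rounding of those references themselves.
- No expiration, no full breathing cycles, no whole-lung washout curves at
  the mouth: the model isolates intra-acinar mixing.
- Alveolar inflation is strictly linear in time (constant `Q_Alv`); a
  time-varying alveolar flow would need only a different `V_alv(t)` but is
  not exposed.
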