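# acinusim

A compartmental finite-difference simulator of inert tracer-gas transport in
the pulmonary acinus, and the two-phase monoexponential analysis of its
tracer-volume kinetics.

## The problem

Ventilation inhomogeneity — uneven gas distribution between parallel lung
units — is an early functional marker of obstructive lung disease, probed
clinically with inert-gas washout tests (SF₆, He, N₂). In the acinus
(Weibel generations 17–23) gas transport is dominated by molecular diffusion
with a small convective component, and mixing between unequal parallel units
produces diffusive *Pendelluft*: gas first flows from the mother airway into
both daughters, then from the smaller daughter into the larger one.

`acinusim` models a single acinar branch point. Weibel's morphometry is
averaged into a representative bronchiole (diameter `d_M = 0.0464 cm`, length
`l_M = 0.089 cm`), and each branch unit (BrU) — a dichotomous subtree whose
generations are merged into serial branch elements — is encoded by one
continuous structure parameter `s̃`:

```
Q_BrU    = (2^(s̃+1) − 1) · m̄_Alv · Q_Alv            input flow
V_BrU(t) = (2^(s̃+1) − 1) · [A_M l_M + m̄_Alv (V_Alv + Q_Alv t)]   volume
```

with `m̄_Alv = 18` alveoli per airway and `Q_Alv = Q_T / N_Alv = 8.3·10⁻⁷
ml/s` the per-alveolus filling flow at resting breathing (`Q_T = 250 ml/s`).
The tree (mother BrU0 + chamber, daughters BrU1/BrU2) is discretised into
10 µm axial compartments, each paired with an inflating alveolar compartment,
and the mole-fraction balance

```
dχ_k/dt = (1/V_k)[ Q_in χ_up − Q_out χ_k − Q' χ_k
                   + D (A_in (χ_up−χ_k)/Δx + A_out (χ_down−χ_k)/Δx
                        + A' (χ_k'−χ_k)/r_k) ]
```

is integrated with a stiff BDF scheme and an analytic sparse Jacobian. A
half-sine tracer bolus starts in a chamber behind a semipermeable inlet
(carrier gas in, no tracer out), so the total tracer volume
`V_g = Σ χ·V ≈ 4.79·10⁻⁵ ml` is conserved. Per-unit tracer volumes
`V_g,BrUi(t)` are then fitted per phase with

```
V(t) = V_end + (V_start − V_end) · e^(−λ (t − t_start))
```

giving a growth constant λ (dynamics) and an end value (the equilibrium
distribution, equal to each unit's volume share of the bolus).

## Worked example

```
$ python examples/02_pendelluft_phases.py
smaller daughter BrU1 peaks at t_p1 = 0.360 s; after that its net tracer
inflow reverses and it feeds the larger daughter

 unit phase  lambda 1/s    V_end ml       R2
 BrU0     1      14.456   1.179e-06   0.9929
 BrU1     1      17.700   2.188e-05   0.9974
 BrU1     2       0.612   1.497e-05   0.9997
 BrU2     1      15.910   2.321e-05   0.9949
 BrU2     2       0.655   3.178e-05   0.9998
```

The asymmetric geometry (BrU1 half the volume of BrU2, D = 0.3 cm²/s, with
convection) fills in two phases: a fast first phase (λ ≈ 15–18 1/s, the
bolus spreading out of the short mother unit) and a slow second phase
(λ ≈ 0.6 1/s) in which ~7·10⁻⁶ ml of tracer moves from the smaller to the
larger daughter — the Pendelluft flow. The other examples print the derived
constants, the pure-diffusion equilibrium shares, and the flow-sensitivity
trend line.

The packaged parameter study (symmetric volume sweep, asymmetric sweep,
diffusion-coefficient sweep) is available from Python
(`acinusim.table3_configs`, `acinusim.run_study`) or the CLI:

```
acinusim constants
acinusim study part3 --out results/part3
acinusim simulate model.cfg --out traj.csv
```

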