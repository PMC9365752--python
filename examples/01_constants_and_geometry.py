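"""Derived acinar constants and the structure parameterisation of a model.

Builds the averaged Weibel morphometry (generations 17-23), prints the
constants every other layer consumes, then assembles an asymmetric model in
which daughter BrU1 has half the volume of daughter BrU2.
"""

from acinusim import build_constants, build_model_spec

c = build_constants()
print("Averaged morphometry and derived constants")
print(f"  d_M  = {c.d_m} cm        mean bronchiole diameter")
print(f"  l_M  = {c.l_m} cm        mean bronchiole length")
print(f"  u_M  = {c.u_m} cm/s      mean flow velocity")
print(f"  Q_M  = {c.q_m:.4g} ml/s  mean branch-unit input flow")
print(f"  Q_Alv= {c.q_alv:.4g} ml/s  per-alveolus filling flow")
print(f"  m_Alv= {c.m_bar_alv} ({c.m_bar_alv_raw:.2f} unrounded) alveoli per airway")
print(f"  s_ref= {c.s_tilde_ref:.4f}  reference structure parameter")
print(f"  V_ref= {c.v_ref:.4g} ml    reference branch-unit volume")

spec = build_model_spec(c, v_bru1=3.88e-3, v_bru2=7.76e-3,
                        diffusion_coefficient=0.3, convection_enabled=True)
print("\nAsymmetric model (BrU1 = half of BrU2)")
for u in (spec.bru0, spec.bru1, spec.bru2):
    print(f"  {u.name}: s_tilde={u.s_tilde:.4f}  length={u.length:.4f} cm  "
          f"Q_in={u.q_in:.3e} ml/s  V0={u.v0:.3e} ml  "
          f"alveoli={u.m_alv_total:.1f}")
print(f"  volume ratio f = V_BrU1/V_BrU2 = {spec.f:.3f} "
      "(time independent: both volumes inflate at the same relative rate)")
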