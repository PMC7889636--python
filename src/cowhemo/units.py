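"""Unit conventions and conversion constants.

Internal working units throughout the package:

==============  ==================  ====================================
quantity        unit                notes
==============  ==================  ====================================
length          mm
area            mm^2                orthogonal lumen cross-section
velocity        mm/s internally     user-facing velocities are cm/s
volumetric Q    mm^3/s
mass flow       mg/s                reported unit for Q_i
pressure        mmHg                reference node grounded at 0
resistance      mmHg*s/g            reported unit for R_ij
density         g/mm^3              1.05e-3 g/mm^3 == 1.05 g/cm^3
kin. viscosity  mm^2/s              1 mm^2/s == 1 cSt
dyn. viscosity  g/(mm*s)            numerically equal to Pa*s
==============  ==================  ====================================

With these choices a pressure computed as force balance in
g/(mm*s^2) is numerically a pascal, so only a single Pa<->mmHg
constant is needed.
"""

PA_PER_MMHG = 133.322387415

MM_PER_CM = 10.0


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def cm_s_to_mm_s(v: float) -> float:
    return v * MM_PER_CM


def mm_s_to_cm_s(v: float) -> float:
    return v / MM_PER_CM
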