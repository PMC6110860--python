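"""Unit conversions used at API boundaries.

Public interfaces speak domain units (mmHg, um, mN/m, pA, mV, nS, pS);
internal arithmetic is SI.  The mmHg conversion is fixed at
1 mmHg = 133.322 Pa.
"""

MMHG_TO_PA = 133.322
UM_TO_M = 1e-6
NM_PER_M_TO_MN_PER_M = 1e3  # N/m -> mN/m
NS_TO_PS = 1e3


def mmhg_to_pa(pressure_mmhg):
    """Convert pressure from mmHg to Pa (scalar or array)."""
    return pressure_mmhg * MMHG_TO_PA


def pa_to_mmhg(pressure_pa):
    """Convert pressure from Pa to mmHg (scalar or array)."""
    return pressure_pa / MMHG_TO_PA
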