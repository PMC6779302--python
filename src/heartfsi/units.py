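"""Unit conversions.

Internally everything runs in CGS (cm, g, s, dyn); pressures cross the module
boundaries in the units practitioners use (kPa for tissue moduli, mmHg for
haemodynamic pressures, mL and mL/s for volumes and flows).
"""

KPA = 1.0e4  # dyn/cm^2 per kPa
MMHG = 1333.22387415  # dyn/cm^2 per mmHg


def kpa_to_cgs(p_kpa: float) -> float:
    return p_kpa * KPA


def mmhg_to_cgs(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def cgs_to_mmhg(p_cgs: float) -> float:
    return p_cgs / MMHG


def cgs_to_kpa(p_cgs: float) -> float:
    return p_cgs / KPA
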