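"""Unit conversions between SI (used internally) and clinical units.

Everything inside the package is SI: metres, pascals, Pa·s, m³/s, m³.
Clinical I/O uses millimetres, mmHg, ml/s and ml.
"""

MMHG_TO_PA = 133.322  # Pa per mmHg
MM_TO_M = 1e-3
M3S_TO_MLS = 1e6  # m³/s -> ml/s
M3_TO_ML = 1e6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def pa_to_kpa(p_pa: float) -> float:
    return p_pa * 1e-3


def mm_to_m(x_mm: float) -> float:
    return x_mm * MM_TO_M


def m_to_mm(x_m: float) -> float:
    return x_m / MM_TO_M


def m3s_to_mls(q: float) -> float:
    return q * M3S_TO_MLS


def mls_to_m3s(q: float) -> float:
    return q / M3S_TO_MLS


def m3_to_ml(v: float) -> float:
    return v * M3_TO_ML
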