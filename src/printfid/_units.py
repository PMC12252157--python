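"""Unit conversions between printer-native units and SI.

The public API speaks the units a BIO X-style extrusion printer exposes
(mm, mm/s, kPa); the Hagen-Poiseuille arithmetic is done in SI. Every
conversion lives here so no factor is duplicated elsewhere.
"""

MM_PER_M = 1000.0
PA_PER_KPA = 1000.0


def mm_to_m(x: float) -> float:
    return x / MM_PER_M


def m_to_mm(x: float) -> float:
    return x * MM_PER_M


def mm_s_to_m_s(x: float) -> float:
    return x / MM_PER_M


def kpa_to_pa(x: float) -> float:
    return x * PA_PER_KPA


def pa_to_kpa(x: float) -> float:
    return x / PA_PER_KPA
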