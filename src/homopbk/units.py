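"""Package-wide unit conventions and conversion helpers.

Internal convention: amounts in µg, volumes in mL, time in h,
concentrations in ng/mL (= µg/L = µg per 1000 mL; note 1 µg/mL = 1000 ng/mL),
permeabilities entered in cm/min and converted to cm/h internally,
clearances entered in L/h and converted to mL/h.
"""

ML_PER_L = 1000.0
UG_PER_MG = 1000.0
UG_PER_G = 1.0e6
NG_PER_UG = 1000.0
MIN_PER_H = 60.0

#: fraction of plasma volume that is water (standard value)
PLASMA_WATER_FRACTION = 0.96


def cm_per_min_to_cm_per_h(p: float) -> float:
    return p * MIN_PER_H


def l_per_h_to_ml_per_h(cl: float) -> float:
    return cl * ML_PER_L


def ug_per_ml_to_ng_per_ml(c: float) -> float:
    return c * NG_PER_UG
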