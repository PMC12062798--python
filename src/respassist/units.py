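"""Unit conversions used at module boundaries.

Airway pressures are carried in cmH2O, actuator supply pressures in kPa,
forces in N, volumes in L and flows in L/s. The force-to-lung-pressure
coefficient delta is the one quantity that crosses the pressure-unit
boundary, so it is stored with an explicit unit tag and converted here.
"""

CMH2O_PER_KPA: float = 10.1972

KPA_PER_CMH2O: float = 1.0 / CMH2O_PER_KPA


def kpa_to_cmh2o(p_kpa: float) -> float:
    return p_kpa * CMH2O_PER_KPA


def cmh2o_to_kpa(p_cmh2o: float) -> float:
    return p_cmh2o * KPA_PER_CMH2O
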