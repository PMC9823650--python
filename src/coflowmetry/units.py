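"""Unit conversions.

All internal computation is SI (m, s, Pa·s, m³/s, m³/Pa).  The I/O layer
accepts the bench units the instrument community uses — mL/h for pump flow
rates, cP for viscosity, µm for channel dimensions — and converts exactly.
"""

#: 1 mL/h in m³/s (exact: 1e-6 m³ per 3600 s)
ML_PER_H = 1e-6 / 3600.0

#: 1 centipoise in Pa·s
CP = 1e-3

#: 1 micrometre in m
UM = 1e-6

#: 1 millimetre in m
MM = 1e-3

#: 1 millilitre in m³
ML = 1e-6

#: Standard atmosphere in Pa, the ambient pressure used to linearize a
#: trapped air cavity into an equivalent compliance.
ATM = 101325.0


def ml_per_h_to_si(q: float) -> float:
    """Convert a flow rate from mL/h to m³/s."""
    return q * ML_PER_H


def si_to_ml_per_h(q: float) -> float:
    """Convert a flow rate from m³/s to mL/h."""
    return q / ML_PER_H


def cp_to_si(mu: float) -> float:
    """Convert a viscosity from cP to Pa·s."""
    return mu * CP


def si_to_cp(mu: float) -> float:
    """Convert a viscosity from Pa·s to cP."""
    return mu / CP
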