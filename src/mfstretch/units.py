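"""Unit conversions at the interface boundary.

Everything inside the package is SI (m, s, N, Pa, N m^-1).  The lab-facing
units are micrometres for lengths, nN um^-1 for cantilever spring constants
and Pa for stresses; conversion happens only here and in the CLI layer.
"""

UM_PER_M = 1e6
M_PER_UM = 1e-6

#: 1 nN um^-1 expressed in N m^-1 (1e-9 N / 1e-6 m).
N_PER_M_PER_NN_PER_UM = 1e-3


def um_to_m(value_um: float) -> float:
    return value_um * M_PER_UM


def m_to_um(value_m: float) -> float:
    return value_m * UM_PER_M


def nn_per_um_to_n_per_m(k: float) -> float:
    """Convert a spring constant from nN um^-1 to N m^-1."""
    return k * N_PER_M_PER_NN_PER_UM


def n_per_m_to_nn_per_um(k: float) -> float:
    """Convert a spring constant from N m^-1 to nN um^-1."""
    return k / N_PER_M_PER_NN_PER_UM
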