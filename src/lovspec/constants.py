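"""Physical constants and default parameter tables."""

#: Conversion from electronvolt to wavenumber (cm^-1).
EV_TO_CM = 8065.544

#: Boltzmann constant in cm^-1 per kelvin.
KB_CM = 0.695034800

#: Speed of light in cm per femtosecond (turns cm^-1 into rad/fs via 2*pi*C_CM_FS).
C_CM_FS = 2.99792458e-5

#: Bondi van der Waals radii (angstrom) for the elements that occur in
#: flavin-pocket heavy-atom fragments.  Overridable via a user radius table.
BONDI_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "H": 1.20,
}

#: Heavy-atom distance below which a pocket side chain counts as *in* (angstrom).
DEFAULT_IN_MAX = 4.0

#: Heavy-atom distance above which a pocket side chain counts as *out* (angstrom).
DEFAULT_OUT_MIN = 5.0
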