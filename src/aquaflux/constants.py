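"""Physical constants used throughout the permeability calculations.

All permeability arithmetic is done in cgs units internally: volumes in
cm^3, areas in cm^2, permeabilities in cm/s, osmolarities converted from
osmol/L to mol/cm^3 at the point of use.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Molar volume of water and the gas constant.

    Attributes
    ----------
    Vw : float
        Molar volume of water, cm^3/mol.
    R_kcal : float
        Gas constant, kcal/(mol*K). Used for Arrhenius activation
        energies expressed in kcal/mol.
    """

    Vw: float = 18.05
    R_kcal: float = 1.9872e-3

    def __post_init__(self) -> None:
        if self.Vw <= 0 or self.R_kcal <= 0:
            raise ValueError("physical constants must be strictly positive")


#: Module-level default constants; immutable, safe to share.
DEFAULT_CONSTANTS = PhysicalConstants()

#: Conversion factor from osmol/L to mol/cm^3.
OSM_PER_L_TO_MOL_PER_CM3 = 1e-3

#: Conversion factor from micrometres to centimetres.
UM_TO_CM = 1e-4

#: Absolute zero offset for Celsius -> Kelvin conversion.
CELSIUS_OFFSET = 273.15
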