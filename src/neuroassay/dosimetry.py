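"""Physiological ethanol dosimetry conversions.

Converts an ethanol exposure between the compartments used to justify
"physiologically relevant" in-vitro doses: brain tissue concentration (mM),
serum concentration (mM and mg/dL), whole-blood concentration (mg/dL), and
blood alcohol concentration (%BAC, grams ethanol per 100 mL blood, w/v).

The chain uses two empirical factors from human magnetic-resonance
spectroscopy work: the average serum-to-brain concentration ratio (~1.67)
and the serum-to-blood conversion factor (~1.24), together with the molar
mass of ethanol (46.07 g/mol):

    serum_mM       = brain_mM * serum_to_brain_ratio
    serum_mg_per_dL = serum_mM * M_ethanol / 10
    blood_mg_per_dL = serum_mg_per_dL / serum_to_blood_factor
    bac_percent     = blood_mg_per_dL / 1000

Every conversion is linear (homogeneous of degree 1), so a DoseSpec can be
reconstructed from any single populated field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConversionConstants",
    "DoseSpec",
    "from_brain_mM",
    "from_serum_mM",
    "from_bac_percent",
    "tissue_g_per_L_to_mM",
    "round_trip",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Empirical factors and physical constants for the conversion chain.

    Attributes
    ----------
    serum_to_brain_ratio : float
        Average serum:brain ethanol concentration ratio (dimensionless).
    serum_to_blood_factor : float
        Serum:whole-blood concentration factor (dimensionless).
    ethanol_molar_mass : float
        Molar mass of ethanol in g/mol.
    brain_water_factor : float
        Factor applied when normalizing a tissue g/L concentration to
        brain water content before molar conversion. Default 1.0 (no
        adjustment), which already reproduces the published ~14.8 mM for
        0.68 g/L cortex.
    """

    serum_to_brain_ratio: float = 1.67
    serum_to_blood_factor: float = 1.24
    ethanol_molar_mass: float = 46.07
    brain_water_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("serum_to_brain_ratio", "serum_to_blood_factor",
                     "ethanol_molar_mass", "brain_water_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class DoseSpec:
    """One ethanol exposure expressed simultaneously in every compartment.

    ``provenance`` records which field was the user-supplied input; all
    other fields are derived through the conversion chain. Values are kept
    at full floating-point precision; rounding happens only at display.
    """

    brain_mM: float
    serum_mM: float
    serum_mg_per_dL: float
    blood_mg_per_dL: float
    bac_percent: float
    provenance: str = "brain_mM"
    constants: ConversionConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def as_dict(self) -> dict:
        return {
            "brain_mM": self.brain_mM,
            "serum_mM": self.serum_mM,
            "serum_mg_per_dL": self.serum_mg_per_dL,
            "blood_mg_per_dL": self.blood_mg_per_dL,
            "bac_percent": self.bac_percent,
            "provenance": self.provenance,
        }


def _populate(brain_mM: float, provenance: str,
              constants: ConversionConstants) -> DoseSpec:
    serum_mM = brain_mM * constants.serum_to_brain_ratio
    serum_mg_per_dL = serum_mM * constants.ethanol_molar_mass / 10.0
    blood_mg_per_dL = serum_mg_per_dL / constants.serum_to_blood_factor
    bac_percent = blood_mg_per_dL / 1000.0
    return DoseSpec(brain_mM, serum_mM, serum_mg_per_dL, blood_mg_per_dL,
                    bac_percent, provenance, constants)


def from_brain_mM(brain_mM: float,
                  constants: ConversionConstants = DEFAULT_CONSTANTS) -> DoseSpec:
    """Populate a full DoseSpec from a brain-tissue concentration in mM.

    Examples
    --------
    >>> spec = from_brain_mM(35.0)
    >>> round(spec.serum_mM, 2), round(spec.bac_percent, 2)
    (58.45, 0.22)
    """
    if brain_mM < 0:
        raise ValueError("brain concentration must be nonnegative")
    return _populate(brain_mM, "brain_mM", constants)


def from_serum_mM(serum_mM: float,
                  constants: ConversionConstants = DEFAULT_CONSTANTS) -> DoseSpec:
    """Populate a full DoseSpec from a serum concentration in mM."""
    if serum_mM < 0:
        raise ValueError("serum concentration must be nonnegative")
    spec = _populate(serum_mM / constants.serum_to_brain_ratio, "serum_mM",
                     constants)
    return spec


def from_bac_percent(bac_percent: float,
                     constants: ConversionConstants = DEFAULT_CONSTANTS) -> DoseSpec:
    """Populate a full DoseSpec from a blood alcohol concentration (% w/v)."""
    if bac_percent < 0:
        raise ValueError("BAC must be nonnegative")
    blood_mg_per_dL = bac_percent * 1000.0
    serum_mg_per_dL = blood_mg_per_dL * constants.serum_to_blood_factor
    serum_mM = serum_mg_per_dL * 10.0 / constants.ethanol_molar_mass
    brain_mM = serum_mM / constants.serum_to_brain_ratio
    return _populate(brain_mM, "bac_percent", constants)


def tissue_g_per_L_to_mM(g_per_L: float,
                         constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a tissue mass concentration (g/L) to molarity (mM).

    ``constants.brain_water_factor`` scales the result when a brain-water
    normalization is wanted; the default of 1.0 reproduces the published
    ~14.8 mM equivalent of 0.68 g/L frontal cortex.
    """
    if g_per_L < 0:
        raise ValueError("concentration must be nonnegative")
    return 1000.0 * g_per_L / constants.ethanol_molar_mass * constants.brain_water_factor


def round_trip(spec: DoseSpec) -> DoseSpec:
    """Rebuild the full DoseSpec from its provenance field alone.

    Because every step of the chain is linear, re-deriving from any single
    field reproduces all others to floating-point precision; this function
    exists so that consistency is checkable rather than assumed.
    """
    constants = spec.constants
    if spec.provenance == "serum_mM":
        return from_serum_mM(spec.serum_mM, constants)
    if spec.provenance == "bac_percent":
        return from_bac_percent(spec.bac_percent, constants)
    return from_brain_mM(spec.brain_mM, constants)
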