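"""Physical constants and unit conversions for headspace HCN quantification.

All gas-phase arithmetic uses the ideal-gas molar volume at STP (22.4 L/mol):
a mixing ratio of 1 ppm (v/v) in a chamber of volume ``V`` litres corresponds
to ``V / 22.4`` micromoles of HCN per million moles of air, i.e.

    micromoles HCN = ppm * V / 22.4

No temperature or pressure correction is applied; field protocols treat the
chamber as being at standard conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "MOLAR_VOLUME_L",
    "HCN_MOLAR_MASS",
    "AMYGDALIN_MOLAR_MASS",
    "ChamberMethod",
    "ChamberSpec",
    "CyanogenStandard",
    "CalibrationFactor",
    "AMYGDALIN",
    "ppm_to_micromol",
    "micromol_per_gram",
    "standard_hcn_mass",
    "theoretical_ppm",
    "apply_calibration",
]

#: Ideal-gas molar volume at STP, litres per mole.
MOLAR_VOLUME_L = 22.4
#: Molar mass of hydrogen cyanide, g/mol.
HCN_MOLAR_MASS = 27.03
#: Molar mass of amygdalin, g/mol.
AMYGDALIN_MOLAR_MASS = 457.4


class ChamberMethod(str, Enum):
    """The three reaction-chamber apparatus variants."""

    CUP = "cup"
    MORTAR_PESTLE = "mortar_pestle"
    JAR = "jar"


#: Default chamber volumes in litres for each apparatus.
DEFAULT_CHAMBER_VOLUMES_L = {
    ChamberMethod.CUP: 0.143,
    ChamberMethod.MORTAR_PESTLE: 0.052,
    ChamberMethod.JAR: 9.6,
}


@dataclass(frozen=True)
class ChamberSpec:
    """A reaction vessel: the apparatus type and its headspace volume.

    The volume is the denominator context of every ppm conversion.
    """

    method: ChamberMethod
    volume_l: float

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError(f"chamber volume must be positive, got {self.volume_l}")

    @classmethod
    def cup(cls, volume_l: float | None = None) -> "ChamberSpec":
        return cls(ChamberMethod.CUP, volume_l or DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.CUP])

    @classmethod
    def mortar_pestle(cls, volume_l: float | None = None) -> "ChamberSpec":
        return cls(
            ChamberMethod.MORTAR_PESTLE,
            volume_l or DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.MORTAR_PESTLE],
        )

    @classmethod
    def jar(cls, volume_l: float | None = None) -> "ChamberSpec":
        return cls(ChamberMethod.JAR, volume_l or DEFAULT_CHAMBER_VOLUMES_L[ChamberMethod.JAR])

    @classmethod
    def for_method(cls, method: str | ChamberMethod, volume_l: float | None = None) -> "ChamberSpec":
        method = ChamberMethod(method)
        return cls(method, volume_l or DEFAULT_CHAMBER_VOLUMES_L[method])


@dataclass(frozen=True)
class CyanogenStandard:
    """A cyanogenic glycoside standard and its HCN stoichiometry.

    ``hcn_stoichiometry`` is moles of HCN liberated per mole of cyanogen on
    complete hydrolysis (1 for the monoglycoside cyanohydrins such as
    amygdalin, prunasin, dhurrin and lotaustralin).
    """

    name: str
    molecular_mass: float  # g/mol
    hcn_stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.molecular_mass <= self.hcn_stoichiometry * HCN_MOLAR_MASS:
            raise ValueError(
                "cyanogen molecular mass must exceed the mass of its releasable HCN"
            )


#: Amygdalin (457.4 g/mol, one HCN per molecule): the commercial standard.
AMYGDALIN = CyanogenStandard("amygdalin", AMYGDALIN_MOLAR_MASS, 1.0)


@dataclass(frozen=True)
class CalibrationFactor:
    """Empirical multiplier mapping open-protocol totals onto closed-chamber truth.

    The cup evacuation protocol systematically under-recovers chamber HCN;
    comparison against a fully closed desiccator jar yields the default 10.2.
    """

    value: float = 10.2
    source: str = "cup-vs-jar fixed-ratio calibration"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration factor must be positive")


def ppm_to_micromol(ppm: float, chamber: ChamberSpec) -> float:
    """Convert a headspace mixing ratio (ppm v/v) to micromoles of HCN.

    ``micromol = ppm * chamber.volume_l / 22.4``; linear in both arguments.
    """
    if ppm < 0:
        raise ValueError(f"ppm must be non-negative, got {ppm}")
    return ppm * chamber.volume_l / MOLAR_VOLUME_L


def micromol_per_gram(total_micromol: float, mass_g: float) -> float:
    """Per-gram fresh-weight HCN concentration (μmol/g)."""
    if mass_g <= 0:
        raise ValueError(f"tissue mass must be positive, got {mass_g}")
    return total_micromol / mass_g


def standard_hcn_mass(standard_mass_mg: float, standard: CyanogenStandard = AMYGDALIN) -> float:
    """Micrograms of HCN releasable from ``standard_mass_mg`` mg of a cyanogen.

    1.0 mg of amygdalin (457.4 g/mol, one HCN) contains 59.09 μg HCN.
    """
    if standard_mass_mg < 0:
        raise ValueError(f"standard mass must be non-negative, got {standard_mass_mg}")
    return (
        standard_mass_mg
        * 1000.0
        * standard.hcn_stoichiometry
        * HCN_MOLAR_MASS
        / standard.molecular_mass
    )


def theoretical_ppm(hcn_mass_ug: float, chamber: ChamberSpec) -> float:
    """Ideal headspace ppm produced by ``hcn_mass_ug`` μg HCN fully volatilised.

    Exact inverse of :func:`ppm_to_micromol` composed with mass→moles.
    """
    if hcn_mass_ug < 0:
        raise ValueError(f"HCN mass must be non-negative, got {hcn_mass_ug}")
    return (hcn_mass_ug / HCN_MOLAR_MASS) * MOLAR_VOLUME_L / chamber.volume_l


def apply_calibration(value: float, factor: CalibrationFactor | float = CalibrationFactor()) -> float:
    """Multiply a concentration or amount by the empirical calibration factor."""
    f = factor.value if isinstance(factor, CalibrationFactor) else float(factor)
    if f <= 0:
        raise ValueError("calibration factor must be positive")
    return value * f
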