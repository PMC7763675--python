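"""Formulation and polymer-characterisation arithmetic.

Single-point intrinsic viscosity by the Solomon-Ciuta equation,

    [eta] = sqrt(2 (t/t0 - ln(t/t0) - 1)) / c,

the Mark-Houwink-Sakurada viscosity-average molecular weight
Mv = ([eta]/k)^(1/a), gravimetric weight loss, and the three standard
nanoparticle formulation percentages (yield, drug loading, entrapment
efficiency).

Note on units: with [eta] in dL/g and k in dL/g, Mv is in g/mol (the
molar-mass unit conventional for MHS work); sources occasionally print
it with a concentration-like unit, which is a typographical slip that
does not affect the number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "ViscometryRecord",
    "MHSConstants",
    "MassPair",
    "FormulationWeights",
    "intrinsic_viscosity",
    "mhs_molecular_weight",
    "weight_loss_percent",
    "nanoparticle_yield",
    "drug_loading",
    "entrapment_efficiency",
]


@dataclass(frozen=True)
class ViscometryRecord:
    """One capillary-viscometer measurement.

    ``flow_time_solution`` (t) and ``flow_time_solvent`` (t0) in
    seconds, concentration c in g/dL.  t == t0 is admitted as the
    infinite-dilution limit (zero intrinsic viscosity).
    """

    flow_time_solution: float
    flow_time_solvent: float
    concentration: float

    def __post_init__(self) -> None:
        if not self.flow_time_solvent > 0:
            raise ValidationError("solvent flow time must be > 0")
        if self.flow_time_solution < self.flow_time_solvent:
            raise ValidationError(
                "solution flow time must be >= solvent flow time "
                f"({self.flow_time_solution} < {self.flow_time_solvent})"
            )
        if not self.concentration > 0:
            raise ValidationError("concentration must be > 0 g/dL")


@dataclass(frozen=True)
class MHSConstants:
    """Mark-Houwink-Sakurada constants for one polymer/solvent/temperature system."""

    k: float  # dL/g
    a: float  # dimensionless

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError("MHS k must be > 0")
        if not (0 < self.a < 2):
            raise ValidationError(f"MHS exponent a must be in (0, 2), got {self.a}")


#: Constants for mPEG-PCL in chloroform at 25 degC.
MPEG_PCL_CHLOROFORM = MHSConstants(k=1.09e-3, a=0.6021)


@dataclass(frozen=True)
class MassPair:
    """Specimen mass before (W0) and after (Wr) a degradation interval, mg."""

    before: float
    after: float

    def __post_init__(self) -> None:
        if not (self.before > 0 and self.after > 0):
            raise ValidationError("both masses must be > 0 mg")


@dataclass(frozen=True)
class FormulationWeights:
    """Weighings entering the yield / loading / entrapment percentages (mg)."""

    nanoparticle_mass: float
    initial_polymer_plus_drug_mass: float
    drug_in_nanoparticles_mass: float
    initial_drug_mass: float

    def __post_init__(self) -> None:
        for name in (
            "nanoparticle_mass",
            "initial_polymer_plus_drug_mass",
            "drug_in_nanoparticles_mass",
            "initial_drug_mass",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 mg")
        if self.drug_in_nanoparticles_mass > self.nanoparticle_mass:
            raise ValidationError(
                "drug mass inside nanoparticles cannot exceed the nanoparticle mass"
            )


def intrinsic_viscosity(rec: ViscometryRecord) -> float:
    """Single-point intrinsic viscosity [eta] in dL/g (Solomon-Ciuta).

    Strictly increasing in the flow-time ratio t/t0 and scaling as 1/c;
    returns exactly 0 at t == t0.
    """
    ratio = rec.flow_time_solution / rec.flow_time_solvent
    if ratio == 1.0:
        return 0.0
    arg = 2.0 * (ratio - math.log(ratio) - 1.0)
    # ratio > 1 makes arg > 0 analytically; guard rounding at ratio ~ 1
    return math.sqrt(max(arg, 0.0)) / rec.concentration


def mhs_molecular_weight(intrinsic_visc: float, constants: MHSConstants) -> float:
    """Viscosity-average molecular weight Mv = ([eta]/k)^(1/a), g/mol."""
    if not intrinsic_visc > 0:
        raise ValidationError("intrinsic viscosity must be > 0 dL/g")
    return (intrinsic_visc / constants.k) ** (1.0 / constants.a)


def weight_loss_percent(pair: MassPair) -> float:
    """Gravimetric weight loss 100 (W0 - Wr) / W0, percent."""
    return 100.0 * (pair.before - pair.after) / pair.before


def nanoparticle_yield(w: FormulationWeights) -> float:
    """Percent of the initial polymer + drug mass recovered as nanoparticles."""
    if not w.initial_polymer_plus_drug_mass > 0:
        raise ValidationError("initial polymer + drug mass must be > 0 mg")
    return 100.0 * w.nanoparticle_mass / w.initial_polymer_plus_drug_mass


def drug_loading(w: FormulationWeights) -> float:
    """Drug mass as a percent of the nanoparticle mass."""
    if not w.nanoparticle_mass > 0:
        raise ValidationError("nanoparticle mass must be > 0 mg")
    return 100.0 * w.drug_in_nanoparticles_mass / w.nanoparticle_mass


def entrapment_efficiency(w: FormulationWeights) -> float:
    """Percent of the initially added drug recovered inside the nanoparticles."""
    if not w.initial_drug_mass > 0:
        raise ValidationError("initial drug mass must be > 0 mg")
    return 100.0 * w.drug_in_nanoparticles_mass / w.initial_drug_mass
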