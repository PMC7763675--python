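"""Pore-window passage screening for ellipsoidal guests in MOF cages.

A rigid guest is idealised as a triaxial ellipsoid with full principal
axes a1 <= a2 <= a3 (Angstrom); a pore window as a circular aperture of
diameter d.  Translating the guest along its longest axis presents an
elliptical a1 x a2 cross-section, which clears a circular window iff
a2 <= d.  A tiered verdict encodes how far from that ideal a given pair
sits:

    PASSES_FREELY       a2 <= d           cross-section fits at any roll angle
    PASSES_ORIENTED     a1 <= d < a2      fits only for suitable orientations
    MARGINALLY_BLOCKED  d < a1 <= d + tol smallest axis misses by <= tol
    BLOCKED             a1 > d + tol

These are geometric heuristics for rigid translation: guest flexibility,
tilted "moving sofa" trajectories and guest-host energetics are outside
their scope.  The default marginal tolerance is 1.0 Angstrom.

Built-in dimensions for the Fe-BTC / MIL-100(Fe) cage system and the
paclitaxel (Taxol) guest are provided for convenience.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "Ellipsoid",
    "PoreWindow",
    "Cavity",
    "PassageCategory",
    "PassageVerdict",
    "classify_passage",
    "fits_in_cavity",
    "TAXOL",
    "FE_BTC_WINDOWS",
    "FE_BTC_CAVITIES",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Triaxial ellipsoid guest; full principal-axis lengths in Angstrom.

    Axes are stored sorted ascending regardless of input order.
    """

    axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.axes) != 3:
            raise ValidationError("an ellipsoid needs exactly three axes")
        if any(not a > 0 for a in self.axes):
            raise ValidationError(f"all axes must be > 0 Angstrom, got {self.axes}")
        object.__setattr__(self, "axes", tuple(sorted(float(a) for a in self.axes)))

    @property
    def a1(self) -> float:
        return self.axes[0]

    @property
    def a2(self) -> float:
        return self.axes[1]

    @property
    def a3(self) -> float:
        return self.axes[2]


@dataclass(frozen=True)
class PoreWindow:
    """Circular pore-window aperture, diameter in Angstrom."""

    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValidationError("window diameter must be > 0 Angstrom")


@dataclass(frozen=True)
class Cavity:
    """Spherical cage cavity, diameter in Angstrom."""

    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValidationError("cavity diameter must be > 0 Angstrom")


class PassageCategory(enum.Enum):
    PASSES_FREELY = "PASSES_FREELY"
    PASSES_ORIENTED = "PASSES_ORIENTED"
    MARGINALLY_BLOCKED = "MARGINALLY_BLOCKED"
    BLOCKED = "BLOCKED"


@dataclass(frozen=True)
class PassageVerdict:
    """Classification of one guest/window pair.

    ``clearance`` is window diameter minus the guest's smallest axis
    (negative when even the most favourable orientation does not fit).
    """

    category: PassageCategory
    clearance: float


def classify_passage(
    guest: Ellipsoid, window: PoreWindow, marginal_tol: float = 1.0
) -> PassageVerdict:
    """Classify rigid translation of an ellipsoidal guest through a window.

    The four categories partition every (guest, window, tolerance)
    triple exactly once; enlarging the window or shrinking any guest
    axis never worsens the verdict.
    """
    if marginal_tol < 0:
        raise ValidationError("marginal tolerance must be >= 0 Angstrom")
    d = window.diameter
    if guest.a2 <= d:
        category = PassageCategory.PASSES_FREELY
    elif guest.a1 <= d:
        category = PassageCategory.PASSES_ORIENTED
    elif guest.a1 <= d + marginal_tol:
        category = PassageCategory.MARGINALLY_BLOCKED
    else:
        category = PassageCategory.BLOCKED
    return PassageVerdict(category=category, clearance=d - guest.a1)


def fits_in_cavity(guest: Ellipsoid, cavity: Cavity) -> bool:
    """True iff the guest's longest axis fits within the cavity diameter."""
    return guest.a3 <= cavity.diameter


#: Paclitaxel (Taxol) as a triaxial ellipsoid, full axes in Angstrom.
TAXOL = Ellipsoid(axes=(7.9, 15.2, 18.2))

#: Pore windows of the Fe-BTC / MIL-100(Fe) cage system (Angstrom).
FE_BTC_WINDOWS = {
    "5-membered": PoreWindow(diameter=7.3, label="5-membered window (s- and l-cage)"),
    "6-membered": PoreWindow(diameter=10.8, label="6-membered window (l-cage only)"),
}

#: Cage cavities of the same system (Angstrom).
FE_BTC_CAVITIES = {
    "s-cage": Cavity(diameter=24.6, label="s-cage cavity (overall size ~46 A)"),
    "l-cage": Cavity(diameter=30.1, label="l-cage cavity (overall size ~52 A)"),
}
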