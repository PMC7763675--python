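"""Core observables: cumulative release curves and spherical carriers.

Time is expressed in days throughout the public interface (rate constants
are reported in d^-1 in this field); particle radii are SI metres.  The
86,400 s/day factor is applied only inside the rate<->diffusivity
conversions in :mod:`relkin.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SECONDS_PER_DAY = 86_400.0

#: Cumulative release is a percentage of total drug load; small over-100
#: excursions are routine measurement artefacts, so values up to this
#: ceiling are accepted.
RELEASE_CEILING = 110.0


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ReleaseCurve:
    """An ordered cumulative release profile.

    Parameters
    ----------
    times
        Sampling times in days, strictly increasing, all >= 0.
    release
        Cumulative release at each time, percent of total drug load.
        Values must lie in [0, 110]; the allowance above 100 tolerates
        the over-100 excursions real dissolution assays produce.
    """

    times: np.ndarray
    release: np.ndarray

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        release = _as_float_array(self.release, "release")
        if times.size != release.size:
            raise ValidationError(
                f"times and release differ in length ({times.size} vs {release.size})"
            )
        if np.any(times < 0):
            raise ValidationError("times must all be >= 0")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(release < 0) or np.any(release > RELEASE_CEILING):
            raise ValidationError(
                f"release values must lie in [0, {RELEASE_CEILING}] percent"
            )
        times.flags.writeable = False
        release.flags.writeable = False
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "release", release)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_points(self) -> int:
        return len(self)


@dataclass(frozen=True)
class SphericalCarrier:
    """A spherical nanoparticle characterised by its radius in metres.

    By convention the radius is half the DLS-reported average particle
    size; this convention reproduces the published diffusivities from
    the published rate constants.
    """

    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius > 0 and np.isfinite(self.radius)):
            raise ValidationError(f"carrier radius must be > 0, got {self.radius}")


def carrier_from_diameter_nm(diameter_nm: float, label: str = "") -> SphericalCarrier:
    """Build a carrier from a DLS average size (a diameter) given in nm."""
    if not diameter_nm > 0:
        raise ValidationError(f"diameter must be > 0 nm, got {diameter_nm}")
    return SphericalCarrier(radius=diameter_nm * 1e-9 / 2.0, label=label)
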