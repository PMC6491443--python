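"""Spectral-shift arithmetic for retinal-protein absorption maxima.

A mutant's colour change is quantified on an energy scale: the shift between
two absorption maxima is expressed in wavenumbers (cm^-1), where a red-shift
(longer wavelength) is a *negative* wavenumber change because the photon
energy decreases. Shifts of independent mutations are approximately additive
on this scale, which is the basis of the additivity analysis. The C=C
stretching frequency of the retinal chromophore is linearly anti-correlated
with lambda_max; :func:`predict_cc_downshift` applies that empirical line
(about 70 cm^-1 of downshift per 270 nm of red-shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .constants import HC_NA_KCAL_NM, NM_CM_FACTOR
from .errors import ConsistencyError, DomainError

__all__ = [
    "SpectralBand",
    "SpectralShift",
    "AdditivityReport",
    "CCStretchModel",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "nm_to_kcalmol",
    "compute_shift",
    "additivity",
    "predict_cc_downshift",
    "round_half_away",
]


def _check_positive(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise DomainError(f"{what} must be positive and finite, got {value!r}")
    return value


def nm_to_wavenumber(lam: float) -> float:
    """Convert a wavelength in nm to a wavenumber in cm^-1 (1e7 / lambda)."""
    return NM_CM_FACTOR / _check_positive(lam, "wavelength (nm)")


def wavenumber_to_nm(nu: float) -> float:
    """Convert a wavenumber in cm^-1 to a wavelength in nm."""
    return NM_CM_FACTOR / _check_positive(nu, "wavenumber (cm^-1)")


def nm_to_kcalmol(lam: float) -> float:
    """Photon energy in kcal/mol for a wavelength in nm (hcN_A / lambda)."""
    return HC_NA_KCAL_NM / _check_positive(lam, "wavelength (nm)")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (-1348.5 -> -1349)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SpectralBand:
    """An absorption maximum: a label and lambda_max in nm."""

    label: str
    lambda_max: float

    def __post_init__(self) -> None:
        _check_positive(self.lambda_max, "lambda_max (nm)")

    @property
    def wavenumber(self) -> float:
        return nm_to_wavenumber(self.lambda_max)

    @property
    def energy_kcalmol(self) -> float:
        return nm_to_kcalmol(self.lambda_max)


@dataclass(frozen=True)
class SpectralShift:
    """Variant-minus-reference spectral shift.

    ``delta_nm`` is in nm; ``delta_wavenumber`` is in cm^-1 on the photon
    energy scale, so a red-shift (positive ``delta_nm``) has a negative
    ``delta_wavenumber``.
    """

    reference_label: str
    variant_label: str
    delta_nm: float
    delta_wavenumber: float

    def __post_init__(self) -> None:
        if self.delta_nm != 0.0 and self.delta_wavenumber != 0.0:
            if math.copysign(1, self.delta_nm) == math.copysign(1, self.delta_wavenumber):
                raise DomainError(
                    "delta_nm and delta_wavenumber must have opposite signs"
                )

    @property
    def delta_wavenumber_int(self) -> int:
        """Printed-style integer shift (half away from zero)."""
        return round_half_away(self.delta_wavenumber)


BandLike = Union[SpectralBand, float]


def _as_band(x: BandLike, default_label: str) -> SpectralBand:
    if isinstance(x, SpectralBand):
        return x
    return SpectralBand(default_label, float(x))


def compute_shift(reference: BandLike, variant: BandLike) -> SpectralShift:
    """Shift of ``variant`` relative to ``reference`` in nm and cm^-1."""
    ref = _as_band(reference, "reference")
    var = _as_band(variant, "variant")
    return SpectralShift(
        reference_label=ref.label,
        variant_label=var.label,
        delta_nm=var.lambda_max - ref.lambda_max,
        delta_wavenumber=var.wavenumber - ref.wavenumber,
    )


@dataclass(frozen=True)
class AdditivityReport:
    """Sum of single-mutation shifts versus the combined mutant's shift.

    ``deviation`` (cm^-1) is the non-additive part: combined minus the exact
    sum of the components.
    """

    component_shifts: tuple
    combined_shift: SpectralShift
    predicted_sum: float
    deviation: float

    @property
    def predicted_sum_int(self) -> int:
        return round_half_away(self.predicted_sum)

    @property
    def deviation_int(self) -> int:
        return round_half_away(self.deviation)


def additivity(
    components: Sequence[SpectralShift], combined: SpectralShift
) -> AdditivityReport:
    """Test whether independent mutations shift the spectrum additively."""
    if len(components) < 2:
        raise ConsistencyError("additivity needs at least two component shifts")
    refs = {s.reference_label for s in components} | {combined.reference_label}
    if len(refs) != 1:
        raise ConsistencyError(f"shifts do not share a reference: {sorted(refs)}")
    predicted = math.fsum(s.delta_wavenumber for s in components)
    return AdditivityReport(
        component_shifts=tuple(components),
        combined_shift=combined,
        predicted_sum=predicted,
        deviation=combined.delta_wavenumber - predicted,
    )


@dataclass(frozen=True)
class CCStretchModel:
    """Linear map from red-shift (nm) to C=C stretch downshift (cm^-1).

    The default slope 70/270 encodes the empirical ~70 cm^-1 downshift per
    270 nm of red-shift for retinal Schiff bases.
    """

    slope: float = 70.0 / 270.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError("CCStretchModel slope must be positive")


def predict_cc_downshift(
    model: CCStretchModel, delta_nm: float
) -> tuple[float, int]:
    """Predicted nu_C=C downshift (cm^-1) for a red-shift of ``delta_nm`` nm.

    Returns ``(value, nearest_integer)`` with half-away-from-zero rounding.
    """
    value = model.slope * float(delta_nm) + model.intercept
    return value, round_half_away(value)
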