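"""Conversions among delta notation, isotope ratio, fractional abundance and
excess enrichment for the two tracer systems used in feeding experiments,
13C/12C and 15N/14N.

Delta values (δ, in ‰) express the heavy/light isotope ratio of a sample
relative to an international reference::

    δ = (R_sample / R_ref − 1) × 1000

with R_ref = 0.01118 for carbon (Vienna Pee Dee Belemnite) and
R_ref = 0.00368 for nitrogen (atmospheric N2).  The fractional abundance
(atom fraction of the heavy isotope) is F = R / (1 + R), and the excess
enrichment of a labelled sample over its natural-abundance background is
E = F_sample − F_background.  E multiplied by an element pool gives moles of
tracer atoms; every downstream rate is linear in E.

Two conversion modes are provided for δ → F.  ``"exact"`` (the default
everywhere) uses the atom-fraction definition F = R/(1+R).  ``"paper_approx"``
evaluates F ≈ ((δ/1000) + 1) × R_ref, a shortcut sometimes used in tracer
studies that simply omits the 1/(1+R) normalization; the two differ by the
factor (1 + R_sample), about 1.1 % for carbon near natural abundance.  A
single ``mode`` argument threads through all downstream computations so the
sensitivity of final rates to this choice can be checked directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Element",
    "ReferenceStandard",
    "VPDB",
    "AIR",
    "STANDARDS",
    "DeltaValue",
    "FractionalAbundance",
    "ExcessEnrichment",
    "ElementMismatchError",
    "IsotopeDomainError",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_fraction",
    "fraction_to_ratio",
    "delta_to_fraction",
    "fraction_to_delta",
    "excess",
]


class Element(str, enum.Enum):
    """Tracer system: the heavy isotope measured."""

    C13 = "C13"
    N15 = "N15"


class ElementMismatchError(TypeError):
    """Raised when quantities of different isotope systems are combined."""


class IsotopeDomainError(ValueError):
    """Raised when a value lies outside the physical domain (e.g. δ ≤ −1000 ‰)."""


@dataclass(frozen=True)
class ReferenceStandard:
    """International reference material defining the δ = 0 point.

    ``r_ref`` is the heavy/light isotope ratio of the reference.
    """

    element: Element
    name: str
    r_ref: float

    def __post_init__(self) -> None:
        if not self.r_ref > 0:
            raise IsotopeDomainError(f"r_ref must be positive, got {self.r_ref}")


#: Vienna Pee Dee Belemnite, the carbon reference (13C/12C = 0.01118).
VPDB = ReferenceStandard(Element.C13, "VPDB", 0.01118)
#: Atmospheric N2, the nitrogen reference (15N/14N = 0.00368).
AIR = ReferenceStandard(Element.N15, "AIR", 0.00368)

#: Default registry: exactly one standard per element.
STANDARDS: dict[Element, ReferenceStandard] = {Element.C13: VPDB, Element.N15: AIR}


@dataclass(frozen=True)
class DeltaValue:
    """A δ value in ‰ for a given isotope system."""

    value: float
    element: Element

    def __post_init__(self) -> None:
        if not self.value > -1000.0:
            raise IsotopeDomainError(
                f"delta must exceed -1000 per mil (ratio positive), got {self.value}"
            )


@dataclass(frozen=True)
class FractionalAbundance:
    """Atom fraction of the heavy isotope (dimensionless, strictly in (0, 1))."""

    value: float
    element: Element

    def __post_init__(self) -> None:
        if not (0.0 < self.value < 1.0):
            raise IsotopeDomainError(
                f"fractional abundance must lie in (0, 1), got {self.value}"
            )


@dataclass(frozen=True)
class ExcessEnrichment:
    """Atom fraction excess over background; may be slightly negative for
    noisy near-background samples (preserved, not clamped)."""

    value: float
    element: Element

    def __post_init__(self) -> None:
        if not abs(self.value) < 1.0:
            raise IsotopeDomainError(f"|excess| must be < 1, got {self.value}")


def _check_elements(a: Element, b: Element) -> None:
    if a != b:
        raise ElementMismatchError(f"isotope systems differ: {a} vs {b}")


# ---------------------------------------------------------------------------
# numeric core: plain floats / numpy arrays, used by the table pipelines
# ---------------------------------------------------------------------------

def _delta_to_ratio(delta, r_ref):
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise IsotopeDomainError("delta must exceed -1000 per mil")
    return (delta / 1000.0 + 1.0) * r_ref


def _ratio_to_delta(ratio, r_ref):
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise IsotopeDomainError("isotope ratio must be positive")
    return (ratio / r_ref - 1.0) * 1000.0


def _ratio_to_fraction(ratio):
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise IsotopeDomainError("isotope ratio must be positive")
    return ratio / (1.0 + ratio)


def _fraction_to_ratio(fraction):
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction <= 0) | (fraction >= 1)):
        raise IsotopeDomainError("fraction must lie in (0, 1)")
    return fraction / (1.0 - fraction)


def _delta_to_fraction(delta, r_ref, mode: str = "exact"):
    r = _delta_to_ratio(delta, r_ref)
    if mode == "exact":
        return _ratio_to_fraction(r)
    if mode == "paper_approx":
        # the shortcut F ≈ R: skips the 1/(1+R) normalization
        return r
    raise ValueError(f"unknown mode {mode!r}; use 'exact' or 'paper_approx'")


def _fraction_to_delta(fraction, r_ref, mode: str = "exact"):
    if mode == "exact":
        return _ratio_to_delta(_fraction_to_ratio(fraction), r_ref)
    if mode == "paper_approx":
        return _ratio_to_delta(fraction, r_ref)
    raise ValueError(f"unknown mode {mode!r}; use 'exact' or 'paper_approx'")


# ---------------------------------------------------------------------------
# typed API
# ---------------------------------------------------------------------------

def delta_to_ratio(d: DeltaValue, std: ReferenceStandard | None = None) -> float:
    """Solve R_sample from the δ definition: R = (δ/1000 + 1) × R_ref."""
    if std is None:
        std = STANDARDS[d.element]
    _check_elements(d.element, std.element)
    return float(_delta_to_ratio(d.value, std.r_ref))


def ratio_to_delta(ratio: float, std: ReferenceStandard) -> DeltaValue:
    """Inverse of :func:`delta_to_ratio`."""
    return DeltaValue(float(_ratio_to_delta(ratio, std.r_ref)), std.element)


def ratio_to_fraction(ratio: float, element: Element = Element.C13) -> FractionalAbundance:
    """Atom fraction F = R/(1+R) of the heavy isotope."""
    return FractionalAbundance(float(_ratio_to_fraction(ratio)), element)


def fraction_to_ratio(f: FractionalAbundance | float) -> float:
    """Inverse of :func:`ratio_to_fraction`: R = F/(1−F)."""
    value = f.value if isinstance(f, FractionalAbundance) else f
    return float(_fraction_to_ratio(value))


def delta_to_fraction(
    d: DeltaValue,
    std: ReferenceStandard | None = None,
    mode: str = "exact",
) -> FractionalAbundance:
    """Convert a δ value to atom fraction.

    mode="exact" composes δ→R→F; mode="paper_approx" evaluates the shortcut
    ((δ/1000) + 1) × R_ref verbatim (which equals R_sample).
    """
    if std is None:
        std = STANDARDS[d.element]
    _check_elements(d.element, std.element)
    return FractionalAbundance(float(_delta_to_fraction(d.value, std.r_ref, mode)), d.element)


def fraction_to_delta(
    f: FractionalAbundance,
    std: ReferenceStandard | None = None,
    mode: str = "exact",
) -> DeltaValue:
    """Inverse of :func:`delta_to_fraction` under the same mode."""
    if std is None:
        std = STANDARDS[f.element]
    _check_elements(f.element, std.element)
    return DeltaValue(float(_fraction_to_delta(f.value, std.r_ref, mode)), f.element)


def excess(sample: FractionalAbundance, background: FractionalAbundance) -> ExcessEnrichment:
    """Excess enrichment E = F_sample − F_background (antisymmetric in its
    arguments; negative values are kept and flagged downstream, not clamped)."""
    _check_elements(sample.element, background.element)
    return ExcessEnrichment(sample.value - background.value, sample.element)
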