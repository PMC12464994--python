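"""Statistical model of labeled/unlabeled monomer mixing and conformer populations.

A sample is prepared by mixing a fluorine-labeled protein with an unlabeled
partner.  Monomers pair into dimers; assuming purely statistical (binomial)
pairing, the probability that a monomer carries fluorine is
``q = labeled_ratio * incorporation_efficiency`` and the dimer pool splits
into 2F (both labeled), 1F (one labeled) and 0F (invisible) species.  Only
2F and 1F dimers contribute NMR signal.

The 1F heterodimer has two distinguishable conformers depending on whether
the distinguished (labeled and/or mutant) monomer occupies position A or B;
their populations follow a two-state Boltzmann distribution parameterized by
a free-energy bias in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from scipy.special import expit

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL

__all__ = [
    "MixingSpec",
    "SpeciesDistribution",
    "BiasParameters",
    "dimer_species_fractions",
    "conformer_populations",
    "heterodimer_bias",
]

LABEL_KINDS = ("5FW", "6FW")


@dataclass(frozen=True)
class MixingSpec:
    """Experimental composition of one mixed-dimer sample.

    Parameters
    ----------
    labeled_ratio
        Mole fraction in (0, 1] of the fluorine-carrying protein among total
        protein (e.g. 0.25 for a 1:3 labeled:unlabeled mixture).
    incorporation_efficiency
        Fraction in (0, 1] of the "labeled" pool that actually carries
        fluorine.  Defaults to 1.0 (no number is available for incomplete
        incorporation; it is observed only qualitatively).
    labeled_variant, unlabeled_variant
        Identifiers of the two proteins (e.g. ``"W63"``, ``"W63+L51I"``).
    label_kind
        Fluorotryptophan isomer, ``"5FW"`` or ``"6FW"``.
    temperature
        Sample temperature in kelvin.
    """

    labeled_ratio: float
    incorporation_efficiency: float = 1.0
    labeled_variant: str = "W63"
    unlabeled_variant: str = "W63"
    label_kind: str = "5FW"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not 0.0 < self.labeled_ratio <= 1.0:
            raise ValueError(
                f"labeled_ratio must be in (0, 1], got {self.labeled_ratio}"
            )
        if not 0.0 < self.incorporation_efficiency <= 1.0:
            raise ValueError(
                "incorporation_efficiency must be in (0, 1], got "
                f"{self.incorporation_efficiency}"
            )
        if self.temperature <= 0.0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(
                f"label_kind must be one of {LABEL_KINDS}, got {self.label_kind!r}"
            )

    @property
    def fluorinated_fraction(self) -> float:
        """Probability q that a random monomer carries a fluorine."""
        return self.labeled_ratio * self.incorporation_efficiency


@dataclass(frozen=True)
class SpeciesDistribution:
    """Dimer species fractions and 1F-heterodimer conformer populations.

    ``f_2F + f_1F + f_0F = 1`` over all dimers; ``f_homo`` / ``f_het`` are
    the 2F and 1F shares of fluorine-visible dimers only.  ``p_A`` / ``p_B``
    are the conformer populations of the 1F heterodimer (distinguished
    monomer in position A vs B); they are unset until a bias is applied.
    """

    f_2F: float
    f_1F: float
    f_0F: float
    f_homo: float
    f_het: float
    p_A: Optional[float] = None
    p_B: Optional[float] = None
    #: records the binomial no-preferential-association assumption
    statistical_mixing: bool = True

    def __post_init__(self) -> None:
        for name in ("f_2F", "f_1F", "f_0F", "f_homo", "f_het"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.f_2F + self.f_1F + self.f_0F - 1.0) > 1e-12:
            raise ValueError("dimer fractions do not sum to 1")
        if abs(self.f_homo + self.f_het - 1.0) > 1e-12:
            raise ValueError("visible fractions do not sum to 1")
        if (self.p_A is None) != (self.p_B is None):
            raise ValueError("p_A and p_B must be set together")
        if self.p_A is not None:
            if not (0.0 <= self.p_A <= 1.0 and 0.0 <= self.p_B <= 1.0):
                raise ValueError("populations outside [0, 1]")
            if abs(self.p_A + self.p_B - 1.0) > 1e-9:
                raise ValueError("p_A + p_B must equal 1")

    @property
    def has_populations(self) -> bool:
        return self.p_A is not None

    def with_populations(self, p_A: float, p_B: Optional[float] = None) -> "SpeciesDistribution":
        """Return a copy with heterodimer conformer populations attached."""
        if p_B is None:
            p_B = 1.0 - p_A
        return replace(self, p_A=p_A, p_B=p_B)


@dataclass(frozen=True)
class BiasParameters:
    """Free-energy biases acting on the distinguished heterodimer monomer.

    ``dg_fw`` is the fluorine-label bias and ``dg_mut`` the mutation bias,
    both in kcal/mol with positive values meaning a preference for position
    A.  ``label_on_mutant`` records whether the fluorine and the mutation
    reside on the same monomer (they add) or on opposite monomers (they
    oppose).
    """

    dg_fw: float
    dg_mut: float = 0.0
    label_on_mutant: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dg_fw) and math.isfinite(self.dg_mut)):
            raise ValueError("bias free energies must be finite")


def dimer_species_fractions(spec: MixingSpec) -> SpeciesDistribution:
    """Binomial dimer statistics for a mixed sample.

    With ``q = labeled_ratio * incorporation_efficiency``::

        f_2F = q^2,  f_1F = 2 q (1 - q),  f_0F = (1 - q)^2

    and, over fluorine-visible dimers only,
    ``f_homo = f_2F / (f_2F + f_1F)`` and ``f_het = 1 - f_homo``.
    A 1:3 mixture at full incorporation gives the reference values
    ``f_homo = 1/7`` and ``f_het = 6/7``.

    Conformer populations are left unset; attach them with
    :meth:`SpeciesDistribution.with_populations`.
    """
    q = spec.fluorinated_fraction
    if q <= 0.0:
        raise ValueError("no fluorine-visible species: labeled fraction is zero")
    f_2f = q * q
    f_1f = 2.0 * q * (1.0 - q)
    f_0f = (1.0 - q) * (1.0 - q)
    visible = f_2f + f_1f
    f_homo = f_2f / visible
    return SpeciesDistribution(
        f_2F=f_2f, f_1F=f_1f, f_0F=f_0f, f_homo=f_homo, f_het=1.0 - f_homo
    )


def conformer_populations(
    dg_total: float, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """Two-state Boltzmann populations (p_A, p_B) for a total bias.

    ``p_A = K' / (1 + K')`` with ``K' = exp(dg_total / (R T))`` so that a
    positive ``dg_total`` means the distinguished monomer prefers position A
    (package-wide sign convention).
    """
    if temperature <= 0.0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    if not math.isfinite(dg_total):
        raise ValueError("dg_total must be finite")
    t = dg_total / (GAS_CONSTANT_KCAL * temperature)
    # expit is overflow-safe and makes p_A(-x) == p_B(x) bit-for-bit
    return float(expit(t)), float(expit(-t))


def heterodimer_bias(params: BiasParameters) -> float:
    """Total apparent bias (kcal/mol) of the distinguished monomer toward A.

    The label and mutation contributions are additive: they sum when on the
    same monomer and subtract when on opposite monomers.
    """
    if params.label_on_mutant:
        return params.dg_mut + params.dg_fw
    return params.dg_mut - params.dg_fw
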