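"""Nitrogen isotope-ratio arithmetic for :sup:`15`\\ N tracer experiments.

The module covers the small amount of algebra that every :sup:`15`\\ N tracer
study relies on:

* conversions between the raw isotope ratio (:sup:`15`\\ N/:sup:`14`\\ N),
  delta notation (permil vs. atmospheric N\\ :sub:`2`) and atom percent
  (:sup:`15`\\ N as a share of total N);
* atom percent excess (APE) of a labelled sample over a natural-abundance
  control — the tracer-incorporation signal;
* the two-source mixing model used to recover the delta value of a small
  nucleic-acid sample measured together with a carrier spike of known mass
  and isotopic composition;
* conversion of a measured bulk :sup:`15`\\ N incorporation rate into the
  ethylene production an acetylene-reduction assay (ARA) would have had to
  detect, given the nominal 3:1 C2H2:N stoichiometry of nitrogenase.

All conversions are exact algebra; the only physical constants involved are
the isotope ratio of atmospheric N\\ :sub:`2` and, for the ARA equivalence,
the molar volume of an ideal gas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ATMOSPHERIC_N2_RATIO",
    "IsotopeMeasurement",
    "SpikeMix",
    "TracerIncubation",
    "AraEquivalence",
    "delta_from_ratio",
    "ratio_from_delta",
    "atom_percent_from_ratio",
    "ratio_from_atom_percent",
    "atom_percent_from_delta",
    "atom_percent_excess",
    "unmix_spike",
    "mix_with_spike",
    "ara_equivalent",
    "fold_change_equivalent",
]

#: 15N/14N ratio of atmospheric N2, the international delta-scale reference.
ATMOSPHERIC_N2_RATIO = 0.0036765


def delta_from_ratio(ratio_sample: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> float:
    """Convert a raw 15N/14N ratio to delta notation (permil).

    delta = (R_sample / R_reference - 1) * 1000.  A sample identical to the
    atmospheric standard has delta = 0 permil; a sample devoid of 15N has the
    limiting value -1000 permil.
    """
    if ratio_sample < 0:
        raise ValueError(f"isotope ratio must be non-negative, got {ratio_sample}")
    if reference_ratio <= 0:
        raise ValueError("reference ratio must be positive")
    return (ratio_sample / reference_ratio - 1.0) * 1000.0


def ratio_from_delta(delta_permil: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if delta_permil < -1000.0:
        raise ValueError(f"delta below -1000 permil is unphysical, got {delta_permil}")
    return reference_ratio * (1.0 + delta_permil / 1000.0)


def atom_percent_from_ratio(ratio_sample: float) -> float:
    """Atom percent 15N from a 15N/14N ratio: 100 * R / (1 + R)."""
    if ratio_sample < 0:
        raise ValueError(f"isotope ratio must be non-negative, got {ratio_sample}")
    return 100.0 * ratio_sample / (1.0 + ratio_sample)


def ratio_from_atom_percent(atom_percent: float) -> float:
    """Inverse of :func:`atom_percent_from_ratio`."""
    if not 0.0 <= atom_percent < 100.0:
        raise ValueError(f"atom percent must be in [0, 100), got {atom_percent}")
    frac = atom_percent / 100.0
    return frac / (1.0 - frac)


def atom_percent_from_delta(delta_permil: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> float:
    """Atom percent 15N from a delta value (permil)."""
    return atom_percent_from_ratio(ratio_from_delta(delta_permil, reference_ratio))


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A single 15N measurement with mutually consistent representations.

    Construct from exactly one of ``ratio``, ``delta_permil`` or
    ``atom_percent`` via the classmethods; the remaining representations are
    derived so the triplet always satisfies the delta and atom-percent
    identities.
    """

    ratio: float
    delta_permil: float
    atom_percent: float
    reference_ratio: float = ATMOSPHERIC_N2_RATIO

    @classmethod
    def from_ratio(cls, ratio: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> "IsotopeMeasurement":
        return cls(
            ratio=ratio,
            delta_permil=delta_from_ratio(ratio, reference_ratio),
            atom_percent=atom_percent_from_ratio(ratio),
            reference_ratio=reference_ratio,
        )

    @classmethod
    def from_delta(cls, delta_permil: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> "IsotopeMeasurement":
        return cls.from_ratio(ratio_from_delta(delta_permil, reference_ratio), reference_ratio)

    @classmethod
    def from_atom_percent(cls, atom_percent: float, reference_ratio: float = ATMOSPHERIC_N2_RATIO) -> "IsotopeMeasurement":
        return cls.from_ratio(ratio_from_atom_percent(atom_percent), reference_ratio)


def atom_percent_excess(sample: IsotopeMeasurement, control: IsotopeMeasurement) -> float:
    """Atom percent excess: labelled sample atom% minus natural-abundance control atom%.

    A negative value (possible through measurement noise when the sample is
    effectively unlabelled) is reported as-is with a warning rather than
    clamped, so that distributions of control APEs stay unbiased.
    """
    ape = sample.atom_percent - control.atom_percent
    if ape < 0:
        warnings.warn(
            f"negative atom percent excess ({ape:.3g}); sample below control, "
            "reported unclamped",
            stacklevel=2,
        )
    return ape


@dataclass(frozen=True)
class SpikeMix:
    """A measured sample+spike mixture for the two-source mixing model.

    ``delta_total``/``n_total`` describe the combined IRMS signal of sample
    plus carrier spike; ``delta_spike``/``n_spike`` the spike alone.  Masses
    are in consistent units (µg N).
    """

    delta_total: float
    n_total: float
    delta_spike: float
    n_spike: float

    def __post_init__(self) -> None:
        if not self.n_total > self.n_spike > 0:
            raise ValueError(
                f"require n_total > n_spike > 0, got n_total={self.n_total}, n_spike={self.n_spike}"
            )


def unmix_spike(mix: SpikeMix) -> float:
    """Recover the sample delta from a sample+spike measurement.

    delta_sample = (delta_total*N_total - delta_spike*N_spike) / (N_total - N_spike),
    the exact inverse of mass-weighted mixing of two N pools.
    """
    return (mix.delta_total * mix.n_total - mix.delta_spike * mix.n_spike) / (
        mix.n_total - mix.n_spike
    )


def mix_with_spike(delta_sample: float, n_sample: float, delta_spike: float, n_spike: float) -> float:
    """Forward mixing model: delta of the combined pool (algebraic inverse of unmix)."""
    if n_sample <= 0 or n_spike <= 0:
        raise ValueError("pool masses must be positive")
    return (delta_sample * n_sample + delta_spike * n_spike) / (n_sample + n_spike)


@dataclass(frozen=True)
class TracerIncubation:
    """Parameters of a soil 15N2 incubation for the ARA equivalence estimate.

    soil_n_content    µmol N per g dry soil
    ape               atom-percent excess measured after incubation (%)
    incubation_time   hours under the 15N2 atmosphere
    conversion_factor mol C2H2 reduced per mol N fixed (nominal 3)
    soil_dry_mass     g dry soil per vial
    headspace_volume  ml gas headspace per vial
    molar_volume      L/mol of ideal gas (24.465 at 25 degC, 1 atm)
    """

    soil_n_content: float
    ape: float
    incubation_time: float
    conversion_factor: float = 3.0
    soil_dry_mass: float = 1.0
    headspace_volume: float = 14.0
    molar_volume: float = 24.465

    def __post_init__(self) -> None:
        for name in ("soil_n_content", "incubation_time", "conversion_factor",
                     "soil_dry_mass", "headspace_volume", "molar_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ape < 0:
            raise ValueError("ape must be non-negative")


@dataclass(frozen=True)
class AraEquivalence:
    """ARA-equivalent rates derived from a 15N tracer measurement."""

    n2_fix_rate: float  # µmol 15N g^-1 h^-1
    ethylene_rate: float  # µmol C2H2 g^-1 h^-1
    incubation: TracerIncubation = field(repr=False)

    def ethylene_ppmv_over(self, hours: float) -> float:
        """Ethylene mixing ratio (ppmv) accumulated in the vial headspace.

        Produced ethylene (µmol) over the window divided by the total µmol of
        headspace gas, times 1e6.
        """
        if hours <= 0:
            raise ValueError("window must be positive")
        produced_umol = self.ethylene_rate * self.incubation.soil_dry_mass * hours
        headspace_umol = (self.incubation.headspace_volume / 1000.0) / self.incubation.molar_volume * 1e6
        return produced_umol / headspace_umol * 1e6


def ara_equivalent(inc: TracerIncubation) -> AraEquivalence:
    """Translate a bulk 15N incorporation into the equivalent ARA signal.

    The N2-fixation rate is soil N content times the fractional atom excess,
    divided by the incubation time; the ethylene (acetylene reduction) rate
    follows from the nominal stoichiometry.  Both are linear in APE and soil
    N, and inversely linear in incubation time.
    """
    fix_rate = inc.soil_n_content * (inc.ape / 100.0) / inc.incubation_time
    ethylene_rate = fix_rate * inc.conversion_factor
    return AraEquivalence(n2_fix_rate=fix_rate, ethylene_rate=ethylene_rate, incubation=inc)


def fold_change_equivalent(log2_fold_change: float) -> float:
    """Linear fold enrichment corresponding to a log2 fold-change threshold."""
    return math.pow(2.0, log2_fold_change)
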