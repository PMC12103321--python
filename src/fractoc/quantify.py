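"""Carbon <-> mass <-> number conversions and recovery arithmetic.

The quantities of interest are ratios and differences of measured
carbon concentrations:

* polymer mass concentration = TOC / w_C, with w_C the carbon mass
  fraction of the polymer;
* a spike of known composition adds sum(c_i * w_C,i) mg C/L to the
  matrix; the native carbon of the unspiked matrix is subtracted before
  computing a recovery;
* recovery = 100 * measured / expected, with the standard uncertainty
  propagated to first order (relative uncertainties in quadrature for a
  ratio, absolute in quadrature for a difference); a linear
  (worst-case-addition) rule is available as an alternative and every
  result records which rule produced it;
* a component invisible to a particle counter can still be estimated by
  subtraction: residual = total (from TOC) - sum(counted components),
  e.g. a 200 nm population below a single-particle counter's detection
  range;
* field-flow-fractionation recovery comes in two flavours: absolute
  (eluted mass over injected mass, the primary ISO definition) and
  relative (eluted mass over a no-crossflow reference run); totals at or
  above 70 % meet the ISO acceptability threshold.

Negative differences (net carbon, residuals) are physically impossible
and signal contamination or interference; they are returned unclipped
with a NegativeCarbonWarning so downstream code can see them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formulas import PolymerSpec
from .sedimentation import ParticleSpec
from .toc import NegativeCarbonWarning

__all__ = [
    "UValue",
    "RecoveryValue",
    "SpikeDesign",
    "SubtractionResult",
    "AF4Recovery",
    "mass_concentration_from_toc",
    "spike_equivalent_carbon",
    "recovery",
    "background_subtract",
    "number_to_mass_concentration",
    "mass_to_number_concentration",
    "subtraction_estimator",
    "af4_recovery",
    "filtration_recovery",
]

ISO_AF4_THRESHOLD = 70.0  # % — ISO acceptability floor for AF4 recovery

_RULES = ("quadrature", "linear")


@dataclass(frozen=True)
class UValue:
    """A measured value with one standard uncertainty."""

    value: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("uncertainty must be >= 0")

    @staticmethod
    def of(x: "UValue | float") -> "UValue":
        return x if isinstance(x, UValue) else UValue(float(x))


def _check_rule(rule: str) -> None:
    if rule not in _RULES:
        raise ValueError(f"unknown uncertainty rule {rule!r}; use one of {_RULES}")


def _u_diff(a: UValue, b: UValue, rule: str) -> float:
    if rule == "quadrature":
        return math.hypot(a.u, b.u)
    return a.u + b.u


def _u_ratio_rel(a: UValue, b: UValue, rule: str) -> float:
    ra = a.u / a.value if a.value != 0 else 0.0
    rb = b.u / b.value if b.value != 0 else 0.0
    if rule == "quadrature":
        return math.hypot(ra, rb)
    return ra + rb


@dataclass(frozen=True)
class RecoveryValue:
    """A recovery percentage with propagated standard uncertainty and
    provenance of its numerator and denominator."""

    value: float
    uncertainty: float
    numerator_provenance: str = ""
    denominator_provenance: str = ""
    rule: str = "quadrature"

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        if not math.isfinite(self.value):
            raise ValueError("recovery value must be finite")

    @property
    def rounded(self) -> int:
        """Nearest-integer percent, half-up (report-table style)."""
        return int(math.floor(self.value + 0.5))


@dataclass(frozen=True)
class SpikeDesign:
    """Particles spiked into a matrix, plus the matrix's native carbon.

    ``spikes`` holds (polymer, mass concentration mg/L) pairs; the
    native TOC of the unspiked matrix is carried both unfiltered and
    filtered so either condition can be background-subtracted.
    """

    spikes: tuple[tuple[PolymerSpec, float], ...]
    native_toc_unfiltered: UValue = UValue(0.0)
    native_toc_filtered: UValue = UValue(0.0)

    def __post_init__(self) -> None:
        for _, conc in self.spikes:
            if conc < 0:
                raise ValueError("spike concentrations must be >= 0")


def mass_concentration_from_toc(toc: float, polymer: PolymerSpec) -> float:
    """Polymer mass concentration (mg/L) from organic carbon (mg C/L)."""
    if polymer.carbon_fraction <= 0:
        raise ValueError("polymer carbon fraction must be positive")
    return toc / polymer.carbon_fraction


def spike_equivalent_carbon(
    design: SpikeDesign | Iterable[tuple[PolymerSpec, float]],
) -> float:
    """Organic carbon (mg C/L) added by a spike: sum(c_i * w_C,i)."""
    spikes = design.spikes if isinstance(design, SpikeDesign) else tuple(design)
    return sum(conc * polymer.carbon_fraction for polymer, conc in spikes)


def recovery(
    measured: UValue | float,
    expected: UValue | float,
    rule: str = "quadrature",
    numerator: str = "measured",
    denominator: str = "expected",
) -> RecoveryValue:
    """Recovery = 100 * measured / expected, % with propagated uncertainty."""
    _check_rule(rule)
    m, e = UValue.of(measured), UValue.of(expected)
    if e.value <= 0:
        raise ValueError("expected value must be positive")
    value = 100.0 * m.value / e.value
    u = abs(value) * _u_ratio_rel(m, e, rule)
    return RecoveryValue(value, u, numerator, denominator, rule)


def background_subtract(
    spiked_toc: UValue | float, native_toc: UValue | float, rule: str = "quadrature"
) -> UValue:
    """Net carbon of a spiked sample after removing the matrix's native
    contribution.  Negative nets are returned with a warning."""
    _check_rule(rule)
    s, n = UValue.of(spiked_toc), UValue.of(native_toc)
    net = s.value - n.value
    if net < 0:
        warnings.warn(
            f"negative net TOC ({net:.3g} mg/L) after background subtraction",
            NegativeCarbonWarning,
        )
    return UValue(net, _u_diff(s, n, rule))


def number_to_mass_concentration(
    number_concentration: float, particle: ParticleSpec
) -> float:
    """Convert particles/mL into mg/L for spheres of known size/density."""
    mass_per_particle_g = particle.volume_cm3 * particle.density
    return number_concentration * mass_per_particle_g * 1e6  # g/mL -> mg/L


def mass_to_number_concentration(
    mass_concentration: float, particle: ParticleSpec
) -> float:
    """Inverse of number_to_mass_concentration (mg/L -> particles/mL)."""
    mass_per_particle_g = particle.volume_cm3 * particle.density
    return mass_concentration / (mass_per_particle_g * 1e6)


@dataclass(frozen=True)
class SubtractionResult:
    residual: UValue
    recovery: RecoveryValue | None


def subtraction_estimator(
    total: UValue | float,
    counted_components: Sequence[UValue | float],
    nominal: float | None = None,
    rule: str = "quadrature",
) -> SubtractionResult:
    """Estimate an uncounted component by mass-balance subtraction.

    residual = total - sum(counted components), all in the same
    mass-concentration units; if a nominal concentration is given the
    residual is also expressed as a recovery against it.  Linear in its
    inputs; a negative residual is flagged, not clipped.
    """
    _check_rule(rule)
    t = UValue.of(total)
    comps = [UValue.of(c) for c in counted_components]
    residual_value = t.value - sum(c.value for c in comps)
    us = [t.u] + [c.u for c in comps]
    residual_u = math.hypot(*us) if rule == "quadrature" else sum(us)
    if residual_value < 0:
        warnings.warn(
            f"negative residual ({residual_value:.3g}) from subtraction",
            NegativeCarbonWarning,
        )
    residual = UValue(residual_value, residual_u)
    rec = None
    if nominal is not None:
        rec = recovery(
            residual,
            UValue(nominal),
            rule=rule,
            numerator="total - counted components",
            denominator="nominal concentration",
        )
    return SubtractionResult(residual, rec)


@dataclass(frozen=True)
class AF4Recovery:
    """Per-fraction and total AF4 recoveries with ISO compliance flags."""

    absolute: dict[str, float]  # % per fraction plus "total"
    relative: dict[str, float] | None
    compliant_absolute: bool
    compliant_relative: bool | None
    iso_threshold: float = ISO_AF4_THRESHOLD


def af4_recovery(
    fraction_masses: Mapping[str, float],
    injected_mass: float,
    no_crossflow_reference_mass: float | None = None,
    iso_threshold: float = ISO_AF4_THRESHOLD,
) -> AF4Recovery:
    """Fractionation recovery of collected AF4 fractions (masses in ug).

    Absolute recovery divides each fraction (and the fraction-wise
    total) by the injected mass; relative recovery divides by the mass
    recovered in a no-crossflow reference run.  A total at or above the
    ISO threshold (70 % by default) is flagged compliant.
    """
    if injected_mass <= 0:
        raise ValueError("injected mass must be positive")
    if any(m < 0 for m in fraction_masses.values()):
        raise ValueError("fraction masses must be >= 0")
    total = sum(fraction_masses.values())
    absolute = {k: 100.0 * m / injected_mass for k, m in fraction_masses.items()}
    absolute["total"] = 100.0 * total / injected_mass
    relative = None
    compliant_relative = None
    if no_crossflow_reference_mass is not None:
        if no_crossflow_reference_mass <= 0:
            raise ValueError("no-crossflow reference mass must be positive")
        relative = {
            k: 100.0 * m / no_crossflow_reference_mass
            for k, m in fraction_masses.items()
        }
        relative["total"] = 100.0 * total / no_crossflow_reference_mass
        compliant_relative = relative["total"] >= iso_threshold
    return AF4Recovery(
        absolute=absolute,
        relative=relative,
        compliant_absolute=absolute["total"] >= iso_threshold,
        compliant_relative=compliant_relative,
        iso_threshold=iso_threshold,
    )


def filtration_recovery(
    filtrate_conc: UValue | float,
    pre_filtration_conc: UValue | float,
    rule: str = "quadrature",
) -> RecoveryValue:
    """Recovery of a filtration step: filtrate over pre-filtration
    concentration, %."""
    return recovery(
        filtrate_conc,
        pre_filtration_conc,
        rule=rule,
        numerator="filtrate concentration",
        denominator="pre-filtration concentration",
    )
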