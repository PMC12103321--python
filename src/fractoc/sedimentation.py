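"""Stokes sedimentation under gravity and in a swing-bucket centrifuge.

In a spinning rotor the centripetal acceleration grows linearly with
radial position, so a tube of liquid experiences a g-force gradient: the
relative centrifugal force (RCF) at the meniscus is lower than at the
tube bottom.  For a particle of diameter ``d`` and density ``rho_p`` in
a fluid of density ``rho_f`` and viscosity ``mu``, the Stokes radial
velocity is position dependent,

    dr/dt = k * r,      k = d^2 (rho_p - rho_f) omega^2 / (18 mu),

so trajectories are exponential, ``r(t) = r0 * exp(k t)``.  Two distinct
size cutoffs follow:

* the *nominal* (planning) cutoff treats the RCF set on the instrument
  as uniform over the column and asks which diameter crosses the column
  height at constant speed — this is how spin durations are usually
  chosen at the bench;
* the *effective* cutoff integrates the exponential trajectory from the
  meniscus ``r_top`` to the bottom ``r_bottom`` and is the diameter that
  just traverses the full column in the actual spin time,

      d_eff = sqrt( 18 mu ln(r_bottom/r_top) /
                    ((rho_p - rho_f) omega^2 t) ).

Because bench settings quote RCF at the rotor's outer limit, the radii
actually spanned by the liquid column can be reconstructed from the RCF
values at its two ends: RCF is proportional to r at fixed speed, so
``r_top/r_bottom = rcf_top/rcf_bottom`` with ``r_bottom - r_top`` equal
to the column height.

For a suspension that is homogeneous along the column when the spin
starts, the fraction of a component that reaches the pellet is the
fraction of starting positions whose trajectory arrives at ``r_bottom``
within ``t``:

    f(d) = min(1, (r_bottom / H) * (1 - exp(-k t))),   H = r_bottom - r_top,

assuming a uniform initial distribution per unit radial length
(swing bucket at full deflection, tube axis radial).  Chaining this over
successive spins of the supernatant yields theoretical pellet
compositions for polydisperse mixtures.

Units: SI internally; the interfaces use the bench units declared per
field (mm radii, g/cm^3 densities, mPa*s viscosity, mg/L concentrations,
cm/min settling speeds, nm cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formulas import PolymerSpec

__all__ = [
    "G",
    "FluidSpec",
    "WATER_20C",
    "ParticleSpec",
    "CentrifugeRun",
    "SuspensionComponent",
    "FractionationResult",
    "BuoyantParticleError",
    "stokes_settling_speed",
    "geometry_from_rcf_gradient",
    "rcf_to_rpm",
    "rpm_to_rcf",
    "sedimentation_rate",
    "effective_cutoff_diameter",
    "spin_time_for_cutoff",
    "nominal_cutoff_diameter",
    "nominal_spin_time",
    "pellet_fraction",
    "simulate_sequential_fractionation",
]

#: standard acceleration of gravity, m/s^2
G = 9.81

_SIZE_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


class BuoyantParticleError(ValueError):
    """Particle not denser than the fluid: no sedimentation cutoff exists."""


@dataclass(frozen=True)
class FluidSpec:
    """Suspending fluid. density g/cm^3, viscosity mPa*s; temperature is
    an annotation only (no viscosity lookup is performed)."""

    density: float = 1.0
    viscosity: float = 1.0016
    temperature: float | None = 20.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.viscosity <= 0:
            raise ValueError("fluid viscosity must be positive")

    @property
    def density_si(self) -> float:  # kg/m^3
        return self.density * 1e3

    @property
    def viscosity_si(self) -> float:  # Pa*s
        return self.viscosity * 1e-3


#: water at 20 degC: 0.9982 ~ 1 g/cm^3 (the value used throughout), 1.0016 mPa*s
WATER_20C = FluidSpec(density=1.0, viscosity=1.0016, temperature=20.0)


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical particle: diameter in metres, density in g/cm^3."""

    diameter: float
    density: float
    polymer: PolymerSpec | None = None

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be non-negative")
        if self.density <= 0:
            raise ValueError("particle density must be positive")

    @classmethod
    def from_size(
        cls,
        value: float,
        unit: str,
        density: float,
        polymer: PolymerSpec | None = None,
    ) -> "ParticleSpec":
        if unit not in _SIZE_UNITS:
            raise ValueError(f"unknown size unit {unit!r} (use {sorted(_SIZE_UNITS)})")
        return cls(diameter=value * _SIZE_UNITS[unit], density=density, polymer=polymer)

    @property
    def diameter_nm(self) -> float:
        return self.diameter * 1e9

    @property
    def diameter_um(self) -> float:
        return self.diameter * 1e6

    @property
    def volume_cm3(self) -> float:
        return math.pi / 6.0 * (self.diameter * 1e2) ** 3

    @property
    def mass_ug(self) -> float:
        """Whole-particle mass in micrograms."""
        return self.volume_cm3 * self.density * 1e6

    @property
    def carbon_mass_ug(self) -> float:
        """Carbon mass per particle in micrograms (requires a polymer)."""
        if self.polymer is None:
            raise ValueError("particle has no polymer reference")
        return self.mass_ug * self.polymer.carbon_fraction

    def is_buoyant(self, fluid: FluidSpec) -> bool:
        return self.density <= fluid.density


@dataclass(frozen=True)
class CentrifugeRun:
    """One spin: fluid-column radii (mm), angular speed (rad/s), duration (s)."""

    r_top: float
    r_bottom: float
    angular_speed: float
    duration: float
    fluid: FluidSpec = WATER_20C

    def __post_init__(self) -> None:
        if not 0 < self.r_top < self.r_bottom:
            raise ValueError("require 0 < r_top < r_bottom")
        if self.angular_speed <= 0:
            raise ValueError("angular speed must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def from_rcf_gradient(
        cls,
        rcf_top: float,
        rcf_bottom: float,
        column_height: float,
        duration: float,
        fluid: FluidSpec = WATER_20C,
    ) -> "CentrifugeRun":
        """Build a run from the RCF values at the two ends of the liquid
        column (g units), the column height (mm) and the spin time (s)."""
        r_top, r_bottom, omega = geometry_from_rcf_gradient(
            rcf_top, rcf_bottom, column_height
        )
        return cls(r_top, r_bottom, omega, duration, fluid)

    @property
    def column_height(self) -> float:  # mm
        return self.r_bottom - self.r_top

    @property
    def rpm(self) -> float:
        return self.angular_speed * 60.0 / (2.0 * math.pi)

    def rcf_at(self, r_mm: float) -> float:
        """Relative centrifugal force (g units) at radial position r (mm)."""
        return self.angular_speed**2 * (r_mm * 1e-3) / G

    @property
    def rcf_top(self) -> float:
        return self.rcf_at(self.r_top)

    @property
    def rcf_bottom(self) -> float:
        return self.rcf_at(self.r_bottom)


@dataclass(frozen=True)
class SuspensionComponent:
    """One monodisperse component of a mixture at a mass concentration (mg/L)."""

    particle: ParticleSpec
    mass_concentration: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.mass_concentration < 0:
            raise ValueError("mass concentration must be >= 0")
        if not self.name:
            label = self.particle.polymer.name if self.particle.polymer else "particle"
            object.__setattr__(
                self, "name", f"{label} {self.particle.diameter_nm:.0f} nm"
            )


@dataclass
class FractionationResult:
    """Outcome of one spin applied to the current supernatant.

    Masses are expressed as mg per litre of the original suspension
    volume (the theoretical model does not deduct pellet liquid volume
    or sampling aliquots).
    """

    stage: int
    pellet_fractions: dict[str, float]
    pellet_mass: dict[str, float]
    pellet_shares: dict[str, float] = field(default_factory=dict)
    supernatant_concentration: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-component table for CSV export."""
        rows = [
            {
                "stage": self.stage,
                "component": name,
                "pellet_fraction": self.pellet_fractions[name],
                "pellet_mg_L": self.pellet_mass[name],
                "share_pct": self.pellet_shares[name],
                "supernatant_mg_L": self.supernatant_concentration[name],
            }
            for name in self.pellet_fractions
        ]
        return pd.DataFrame(rows)


def geometry_from_rcf_gradient(
    rcf_top: float, rcf_bottom: float, column_height: float
) -> tuple[float, float, float]:
    """Reconstruct (r_top, r_bottom) in mm and omega (rad/s) from the RCF
    at the two ends of a liquid column of the given height (mm).

    At fixed speed RCF is proportional to radius, so
    r_top/r_bottom = rcf_top/rcf_bottom, and the radii follow from the
    height constraint; omega comes from the RCF at the bottom.
    """
    if not 0 < rcf_top < rcf_bottom:
        raise ValueError("require 0 < rcf_top < rcf_bottom (geometry impossible)")
    if column_height <= 0:
        raise ValueError("column height must be positive")
    r_bottom = column_height / (1.0 - rcf_top / rcf_bottom)
    r_top = r_bottom - column_height
    omega = math.sqrt(rcf_bottom * G / (r_bottom * 1e-3))
    return r_top, r_bottom, omega


def rcf_to_rpm(rcf: float, radius_mm: float) -> float:
    """Rotor speed (rpm) giving the stated RCF at the stated radius."""
    omega = math.sqrt(rcf * G / (radius_mm * 1e-3))
    return omega * 60.0 / (2.0 * math.pi)


def rpm_to_rcf(rpm: float, radius_mm: float) -> float:
    omega = rpm * 2.0 * math.pi / 60.0
    return omega**2 * (radius_mm * 1e-3) / G


def stokes_settling_speed(
    particle: ParticleSpec, fluid: FluidSpec, acceleration: float = G
) -> float:
    """Stokes settling speed in cm/min under a uniform acceleration (m/s^2).

    Negative for buoyant particles (flotation is not modeled further).
    """
    v = (
        particle.diameter**2
        * (particle.density - fluid.density)
        * 1e3
        * acceleration
        / (18.0 * fluid.viscosity_si)
    )
    return v * 6000.0  # m/s -> cm/min


def sedimentation_rate(particle: ParticleSpec, run: CentrifugeRun) -> float:
    """Exponential-trajectory rate constant k (1/s): dr/dt = k r."""
    return (
        particle.diameter**2
        * (particle.density - run.fluid.density)
        * 1e3
        * run.angular_speed**2
        / (18.0 * run.fluid.viscosity_si)
    )


def effective_cutoff_diameter(run: CentrifugeRun, particle_density: float) -> float:
    """Effective size cutoff (nm) of a spin: the diameter whose exponential
    trajectory traverses the full liquid column in exactly the run time."""
    delta_rho = (particle_density - run.fluid.density) * 1e3
    if delta_rho <= 0:
        raise BuoyantParticleError("particle must be denser than the fluid")
    d2 = (
        18.0
        * run.fluid.viscosity_si
        * math.log(run.r_bottom / run.r_top)
        / (delta_rho * run.angular_speed**2 * run.duration)
    )
    return math.sqrt(d2) * 1e9


def spin_time_for_cutoff(
    cutoff_nm: float, run: CentrifugeRun, particle_density: float
) -> float:
    """Spin duration (s) giving the requested effective cutoff (nm) on the
    run's geometry and speed.  Exact inverse of effective_cutoff_diameter."""
    delta_rho = (particle_density - run.fluid.density) * 1e3
    if delta_rho <= 0:
        raise BuoyantParticleError("particle must be denser than the fluid")
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    d = cutoff_nm * 1e-9
    return (
        18.0
        * run.fluid.viscosity_si
        * math.log(run.r_bottom / run.r_top)
        / (delta_rho * run.angular_speed**2 * d**2)
    )


def nominal_cutoff_diameter(
    rcf: float,
    column_height_mm: float,
    duration_s: float,
    particle_density: float,
    fluid: FluidSpec = WATER_20C,
) -> float:
    """Nominal (planning) cutoff in nm: the set RCF taken as uniform over
    the column, constant-speed traversal of the full height."""
    delta_rho = (particle_density - fluid.density) * 1e3
    if delta_rho <= 0:
        raise BuoyantParticleError("particle must be denser than the fluid")
    d2 = (
        18.0
        * fluid.viscosity_si
        * (column_height_mm * 1e-3)
        / (delta_rho * rcf * G * duration_s)
    )
    return math.sqrt(d2) * 1e9


def nominal_spin_time(
    cutoff_nm: float,
    rcf: float,
    column_height_mm: float,
    particle_density: float,
    fluid: FluidSpec = WATER_20C,
) -> float:
    """Planning spin time (s) for a nominal cutoff at a set RCF: the time a
    particle of that diameter needs to cross the column at constant Stokes
    speed under the set RCF."""
    delta_rho = (particle_density - fluid.density) * 1e3
    if delta_rho <= 0:
        raise BuoyantParticleError("particle must be denser than the fluid")
    d = cutoff_nm * 1e-9
    v = d**2 * delta_rho * rcf * G / (18.0 * fluid.viscosity_si)  # m/s
    return column_height_mm * 1e-3 / v


def pellet_fraction(particle: ParticleSpec, run: CentrifugeRun) -> float:
    """Fraction of a component's mass reaching the pellet during a spin.

    Assumes the component is uniformly distributed per unit radial length
    along the column at spin start.  Buoyant particles give 0.
    """
    if particle.is_buoyant(run.fluid):
        return 0.0
    k = sedimentation_rate(particle, run)
    f = (run.r_bottom / run.column_height) * (1.0 - math.exp(-k * run.duration))
    return min(1.0, f)


def simulate_sequential_fractionation(
    mixture: list[SuspensionComponent], runs: list[CentrifugeRun]
) -> list[FractionationResult]:
    """Spin a mixture through successive runs, each applied to the previous
    supernatant, and report per-stage pellet fractions, pellet masses,
    pellet composition shares and supernatant concentrations.

    Mass is conserved per component across the chain: pellet masses plus
    the final supernatant add back to the input concentration.
    """
    if not mixture:
        raise ValueError("mixture must contain at least one component")
    if not runs:
        raise ValueError("at least one centrifuge run is required")
    names = [c.name for c in mixture]
    if len(set(names)) != len(names):
        raise ValueError("component names must be unique")

    remaining = {c.name: c.mass_concentration for c in mixture}
    results: list[FractionationResult] = []
    for stage, run in enumerate(runs, start=1):
        fractions = {c.name: pellet_fraction(c.particle, run) for c in mixture}
        pellet = {n: remaining[n] * fractions[n] for n in remaining}
        supernatant = {n: remaining[n] - pellet[n] for n in remaining}
        total_pellet = sum(pellet.values())
        shares = {
            n: (100.0 * pellet[n] / total_pellet if total_pellet > 0 else 0.0)
            for n in pellet
        }
        results.append(
            FractionationResult(
                stage=stage,
                pellet_fractions=fractions,
                pellet_mass=pellet,
                pellet_shares=shares,
                supernatant_concentration=supernatant,
            )
        )
        remaining = supernatant
    return results
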