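"""Data reduction for a liquid TOC analyzer.

Total organic carbon is measured indirectly as TOC = TC - TIC: total
carbon by catalytic combustion, total inorganic carbon by acid
degradation of carbonates, both quantified from the CO2 released.  The
analyzer injects each sample twice and adds a third injection when the
coefficient of variation (CV) of the first two exceeds 2 %; the
accepted value is the mean of the two closest replicates, the third (if
drawn) being rejected.

Injection volume and calibration curve are picked from the carbon
concentration: for colloidal samples (particles <= 10 um) TC uses
2000 uL (0.01-0.1 mg/L, Curve 1), 408 uL (0.1-1.0, Curve 2) or 50 uL
(1.0-10.0, Curve 3), and TIC uses 2000 uL (0.02-0.2, Curve 1) or 130 uL
(0.2-5.0, Curve 2).  Particles larger than 10 um lose colloidal
behaviour, settle fast, and are few per injected volume, so a modified
TC procedure applies: fixed 500 uL injections, calibration extended to
1.0-50.0 mg/L (Curve 4), continuous stirring and no syringe dead time.

Whether the particle count per injection is statistically adequate is
itself a quantitative question: the expected number injected is the
injected carbon mass over the carbon mass per particle, and the actual
number drawn is Poisson.  A 90 um PS particle carries ~0.37 ug of
carbon, so a standard 50 uL injection aiming at 5 mg C/L expects only
~0.68 particles — roughly even odds of injecting zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .sedimentation import WATER_20C, FluidSpec, ParticleSpec, stokes_settling_speed

__all__ = [
    "NegativeCarbonWarning",
    "ThirdReplicateNeeded",
    "DilutionRequired",
    "MeasurementRecord",
    "InjectionPlan",
    "INJECTION_PLANS",
    "toc_from_tc_tic",
    "replicate_cv",
    "accept_replicates",
    "select_injection_plan",
    "ExpectedCount",
    "expected_particles_injected",
    "injection_count_distribution",
    "ProcedureRecommendation",
    "recommend_procedure",
]

#: carbon concentration aimed for after gravimetric dilution, mg/L
STANDARD_TC_TARGET = 5.0
#: modified-procedure carbon target, mg/L (500 uL injections)
MODIFIED_TC_TARGET = 25.0
#: particle size above which the modified TC procedure applies, um (strict >)
MODIFIED_SIZE_THRESHOLD_UM = 10.0


class NegativeCarbonWarning(UserWarning):
    """A carbon difference came out negative — physically impossible,
    indicates a measurement problem; the value is returned unclipped."""


class ThirdReplicateNeeded(Exception):
    """Two replicates disagree beyond the CV threshold; the instrument
    would draw a third injection."""

    def __init__(self, cv: float, threshold: float):
        self.cv = cv
        self.threshold = threshold
        super().__init__(
            f"replicate CV {cv:.2f}% exceeds {threshold:.2f}%: third replicate required"
        )


class DilutionRequired(Exception):
    """Estimated concentration falls outside every calibration range."""

    def __init__(self, concentration: float, suggested_factor: float, target: float):
        self.concentration = concentration
        self.suggested_factor = suggested_factor
        self.target = target
        super().__init__(
            f"{concentration} mg/L outside all calibration ranges; dilute by "
            f"{suggested_factor}x (targeting {target} mg/L)"
        )


@dataclass(frozen=True)
class MeasurementRecord:
    """Accepted result of one TC or TIC determination."""

    channel: str
    replicate_values: tuple[float, ...]
    accepted_value: float
    rejected_index: int | None = None
    cv_first_two: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in ("TC", "TIC"):
            raise ValueError("channel must be 'TC' or 'TIC'")
        if not 2 <= len(self.replicate_values) <= 3:
            raise ValueError("2 or 3 replicates expected")


@dataclass(frozen=True)
class InjectionPlan:
    """One row of the injection-volume / calibration-range table."""

    channel: str
    procedure: str  # "standard" | "modified"
    injection_volume: float  # uL
    calibration_curve: str
    concentration_range: tuple[float, float]  # mg/L

    def __post_init__(self) -> None:
        if self.channel not in ("TC", "TIC"):
            raise ValueError("channel must be 'TC' or 'TIC'")
        if self.procedure not in ("standard", "modified"):
            raise ValueError("procedure must be 'standard' or 'modified'")
        if self.procedure == "modified" and (
            self.injection_volume != 500.0 or self.concentration_range != (1.0, 50.0)
        ):
            raise ValueError("modified procedure is 500 uL over 1.0-50.0 mg/L")


#: the instrument's volume/range table, verbatim
INJECTION_PLANS: tuple[InjectionPlan, ...] = (
    InjectionPlan("TC", "standard", 2000.0, "TC Curve 1", (0.01, 0.1)),
    InjectionPlan("TC", "standard", 408.0, "TC Curve 2", (0.1, 1.0)),
    InjectionPlan("TC", "standard", 50.0, "TC Curve 3", (1.0, 10.0)),
    InjectionPlan("TIC", "standard", 2000.0, "TIC Curve 1", (0.02, 0.2)),
    InjectionPlan("TIC", "standard", 130.0, "TIC Curve 2", (0.2, 5.0)),
    InjectionPlan("TC", "modified", 500.0, "TC Curve 4", (1.0, 50.0)),
)


def toc_from_tc_tic(tc: float, tic: float) -> float:
    """TOC = TC - TIC (mg C/L).  A negative difference is returned but
    raises NegativeCarbonWarning."""
    if tc < 0 or tic < 0:
        raise ValueError("TC and TIC must be >= 0")
    toc = tc - tic
    if toc < 0:
        warnings.warn(
            f"negative TOC ({toc:.3g} mg/L): TIC exceeds TC", NegativeCarbonWarning
        )
    return toc


def replicate_cv(values: tuple[float, float] | list[float]) -> float:
    """Coefficient of variation, %, of two replicates: sample standard
    deviation (n-1 denominator) over the mean.  The instrument convention
    is not published; this choice is configurable only by computing your
    own CV and calling accept_replicates with a matching threshold."""
    a, b = values[0], values[1]
    mean = (a + b) / 2.0
    if mean == 0:
        return math.inf if a != b else 0.0
    sd = abs(a - b) / math.sqrt(2.0)
    return 100.0 * sd / mean


def accept_replicates(
    values: list[float], cv_threshold: float = 2.0, channel: str = "TC"
) -> MeasurementRecord:
    """Apply the replicate acceptance rule of the analyzer.

    Two values with CV <= threshold: accept their mean.  Two values with
    CV > threshold: raise ThirdReplicateNeeded.  Three values: accept the
    mean of the pair with the smallest absolute difference and record the
    rejected index; when the third replicate sits exactly equidistant
    from the first two, the first two are kept (deterministic tie-break;
    the instrument's convention is not published).
    """
    if not 2 <= len(values) <= 3:
        raise ValueError("expected 2 or 3 replicate values")
    cv = replicate_cv(values[:2])
    if len(values) == 2:
        if cv > cv_threshold:
            raise ThirdReplicateNeeded(cv, cv_threshold)
        return MeasurementRecord(
            channel=channel,
            replicate_values=tuple(values),
            accepted_value=(values[0] + values[1]) / 2.0,
            rejected_index=None,
            cv_first_two=cv,
        )
    if math.isclose(
        abs(values[0] - values[2]), abs(values[1] - values[2]), rel_tol=1e-12
    ):
        best = (0, 1)  # third equidistant from both: keep the first two
    else:
        pairs = [(0, 1), (0, 2), (1, 2)]
        best = min(pairs, key=lambda ij: abs(values[ij[0]] - values[ij[1]]))
    rejected = ({0, 1, 2} - set(best)).pop()
    return MeasurementRecord(
        channel=channel,
        replicate_values=tuple(values),
        accepted_value=(values[best[0]] + values[best[1]]) / 2.0,
        rejected_index=rejected,
        cv_first_two=cv,
    )


def select_injection_plan(
    estimated_concentration: float, channel: str, particle_size_um: float
) -> InjectionPlan:
    """Pick the injection volume and calibration curve for an estimated
    carbon concentration (mg/L), measurement channel and particle size.

    Particles above 10 um route TC to the modified plan.  Concentrations
    outside every range raise DilutionRequired with a gravimetric
    dilution factor aiming at 5 mg/L (standard) or 25 mg/L (modified),
    rounded up to one decimal.
    """
    if channel not in ("TC", "TIC"):
        raise ValueError("channel must be 'TC' or 'TIC'")
    if estimated_concentration <= 0:
        raise ValueError("estimated concentration must be positive")
    modified = channel == "TC" and particle_size_um > MODIFIED_SIZE_THRESHOLD_UM
    procedure = "modified" if modified else "standard"
    rows = [
        p for p in INJECTION_PLANS if p.channel == channel and p.procedure == procedure
    ]
    for i, plan in enumerate(rows):
        lo, hi = plan.concentration_range
        last = i == len(rows) - 1
        if lo <= estimated_concentration < hi or (last and estimated_concentration == hi):
            return plan
    target = MODIFIED_TC_TARGET if modified else STANDARD_TC_TARGET
    factor = math.ceil(estimated_concentration / target * 10.0) / 10.0
    raise DilutionRequired(estimated_concentration, factor, target)


class ExpectedCount(NamedTuple):
    expected: float
    rounded: int


def expected_particles_injected(
    target_tc: float, injection_volume: float, particle: ParticleSpec
) -> ExpectedCount:
    """Expected number of particles in one injection.

    Injected carbon mass (target TC in mg/L times injection volume in
    uL) divided by the carbon mass per particle.  The real value is what
    matters statistically; the rounded (half-up) value is for display.
    """
    if target_tc <= 0 or injection_volume <= 0:
        raise ValueError("target TC and injection volume must be positive")
    carbon_per_particle = particle.carbon_mass_ug
    if carbon_per_particle <= 0:
        raise ValueError("particle carries no carbon")
    injected_carbon_ug = target_tc * injection_volume * 1e-3  # mg/L == ug/mL
    expected = injected_carbon_ug / carbon_per_particle
    return ExpectedCount(expected, int(math.floor(expected + 0.5)))


def injection_count_distribution(expected_count: float) -> np.ndarray:
    """Poisson pmf over the number of particles actually injected.

    Returned as an array indexed by count, truncated adaptively so the
    retained mass is within 1e-9 of 1.
    """
    if expected_count < 0:
        raise ValueError("expected count must be >= 0")
    if expected_count == 0:
        return np.array([1.0])
    kmax = int(stats.poisson.ppf(1.0 - 1e-12, expected_count)) + 10
    pmf = stats.poisson.pmf(np.arange(kmax + 1), expected_count)
    if abs(pmf.sum() - 1.0) > 1e-9:
        raise RuntimeError("pmf truncation failed to capture the distribution")
    return pmf


@dataclass(frozen=True)
class ProcedureRecommendation:
    """Standard-vs-modified recommendation with quantitative rationale."""

    procedure: str
    diameter_um: float
    size_rule: str
    expected_count_standard: float
    expected_count_modified: float
    settling_speed_cm_min: float


def recommend_procedure(
    particle: ParticleSpec, fluid: FluidSpec = WATER_20C
) -> ProcedureRecommendation:
    """Recommend standard or modified TOC measurement for a particle.

    The deciding rule is size: strictly above 10 um the colloidal
    behaviour is lost and the modified procedure applies (10 um itself
    works under both).  Expected counts under both plans and the
    gravitational settling speed are attached as rationale.
    """
    d_um = particle.diameter_um
    modified = d_um > MODIFIED_SIZE_THRESHOLD_UM
    n_std = expected_particles_injected(STANDARD_TC_TARGET, 50.0, particle).expected
    n_mod = expected_particles_injected(MODIFIED_TC_TARGET, 500.0, particle).expected
    return ProcedureRecommendation(
        procedure="modified" if modified else "standard",
        diameter_um=d_um,
        size_rule=(
            f"diameter {d_um:g} um "
            + (">" if modified else "<=")
            + f" {MODIFIED_SIZE_THRESHOLD_UM:g} um threshold"
        ),
        expected_count_standard=n_std,
        expected_count_modified=n_mod,
        settling_speed_cm_min=stokes_settling_speed(particle, fluid),
    )
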