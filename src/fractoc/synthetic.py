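"""Synthetic measurement generator.

Emulates the statistical structure of the two instruments the analysis
consumes so that every pipeline stage can be exercised without real
data:

* TOC replicates: the true TC of a suspension is the carbon carried by
  its particulate components plus the dissolved organic carbon of the
  matrix; TIC is the matrix's inorganic carbon.  Replicates are drawn
  lognormally with a stated CV (lognormal keeps concentrations
  positive; for small CV it is indistinguishable from normal noise).
  If the vial is not stirred, large particles settle during the syringe
  dead time and the component's contribution is attenuated by a simple
  linear depletion factor max(0, 1 - v_settle * dead_time / intake
  height).  The loss model is deliberately illustrative — the
  qualitative collapse of unstirred large-particle recoveries — not a
  calibrated hydrodynamic model.

* Single-particle counting (SPES-like): components outside the
  counter's 250 nm - 5 um window are invisible; visible components
  yield Poisson counts with mean = true number concentration x analyzed
  volume, reported back as a number concentration with its Poisson
  standard error.

All randomness flows from the scenario seed: identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import UValue, mass_to_number_concentration
from .sedimentation import (
    WATER_20C,
    FluidSpec,
    SuspensionComponent,
    simulate_sequential_fractionation,
    stokes_settling_speed,
)
from .toc import ThirdReplicateNeeded, accept_replicates, toc_from_tc_tic

__all__ = [
    "ScenarioSpec",
    "SPES_WINDOW_NM",
    "simulate_toc_replicates",
    "simulate_spes_counts",
    "generate_fractionation_experiment",
    "estimate_mass_concentration_from_toc_table",
]

#: detection window of the single-particle counter, nm
SPES_WINDOW_NM = (250.0, 5000.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth plus instrument noise for one simulated experiment.

    CVs are relative standard deviations of single replicate readings
    (defaults match the ~7 % TOC and ~10 % SPES between-replicate
    spread of the experiments the package models).  ``dead_time`` is
    the syringe idle time between automatic replicate injections (s);
    ``intake_height`` the liquid depth above the intake (cm) over which
    unstirred settling depletes particles.
    """

    components: tuple[SuspensionComponent, ...]
    doc_background: float = 0.03  # mg C/L (ultrapure-water level)
    tic_background: float = 0.0  # mg C/L
    cv_tc: float = 0.07
    cv_tic: float = 0.07
    cv_spes: float = 0.10
    stirred: bool = True
    dead_time: float = 120.0
    intake_height: float = 2.0
    fluid: FluidSpec = WATER_20C
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_tc, self.cv_tic, self.cv_spes) < 0:
            raise ValueError("CVs must be >= 0")
        if self.intake_height <= 0:
            raise ValueError("intake height must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def settling_loss_factor(self, component: SuspensionComponent) -> float:
        """Fraction of a component surviving the syringe dead time.

        1.0 when stirred; otherwise linear depletion of the intake zone
        at the gravitational Stokes speed, floored at 0.
        """
        if self.stirred:
            return 1.0
        v_cm_min = stokes_settling_speed(component.particle, self.fluid)
        if v_cm_min <= 0:  # buoyant or neutrally buoyant: no settling loss
            return 1.0
        return max(0.0, 1.0 - v_cm_min / 60.0 * self.dead_time / self.intake_height)

    def true_tc(self) -> float:
        """True total carbon (mg C/L) reaching the injection syringe."""
        particulate = sum(
            c.mass_concentration
            * (c.particle.polymer.carbon_fraction if c.particle.polymer else 0.0)
            * self.settling_loss_factor(c)
            for c in self.components
        )
        return particulate + self.doc_background


def _lognormal_with_cv(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    """Draws with the requested mean and relative SD; degenerate at cv=0
    or mean=0."""
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def simulate_toc_replicates(
    scenario: ScenarioSpec,
    n_samples: int = 1,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate TC and TIC readings for a scenario.

    Returns a tidy frame (sample_id, channel, replicate_no,
    value_mg_per_L) in the same schema the reduction step reads.
    """
    if rng is None:
        rng = scenario.rng()
    truths = {"TC": scenario.true_tc(), "TIC": scenario.tic_background}
    cvs = {"TC": scenario.cv_tc, "TIC": scenario.cv_tic}
    rows = []
    for sample in range(n_samples):
        for channel in ("TC", "TIC"):
            values = _lognormal_with_cv(rng, truths[channel], cvs[channel], n_replicates)
            for i, v in enumerate(values, start=1):
                rows.append(
                    {
                        "sample_id": sample,
                        "channel": channel,
                        "replicate_no": i,
                        "value_mg_per_L": float(v),
                    }
                )
    return pd.DataFrame(rows)


def simulate_spes_counts(
    scenario: ScenarioSpec,
    analyzed_volume: float = 25.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Detected number concentrations from a single-particle counter.

    ``analyzed_volume`` in mL.  Components outside the detection window
    appear with detected=False and NaN estimates.  Standard errors are
    Poisson (sqrt of the observed count).
    """
    if analyzed_volume <= 0:
        raise ValueError("analyzed volume must be positive")
    if rng is None:
        rng = scenario.rng()
    lo, hi = SPES_WINDOW_NM
    rows = []
    for c in scenario.components:
        d_nm = c.particle.diameter_nm
        visible = lo <= d_nm <= hi
        if not visible:
            rows.append(
                {
                    "component": c.name,
                    "diameter_nm": d_nm,
                    "detected": False,
                    "number_per_mL": np.nan,
                    "number_se_per_mL": np.nan,
                }
            )
            continue
        true_nc = mass_to_number_concentration(c.mass_concentration, c.particle)
        mean_count = true_nc * analyzed_volume
        # noise beyond counting statistics enters as a lognormal factor
        factor = _lognormal_with_cv(rng, 1.0, scenario.cv_spes, 1)[0]
        count = rng.poisson(mean_count * factor) if mean_count > 0 else 0
        rows.append(
            {
                "component": c.name,
                "diameter_nm": d_nm,
                "detected": True,
                "number_per_mL": count / analyzed_volume,
                "number_se_per_mL": math.sqrt(count) / analyzed_volume,
            }
        )
    return pd.DataFrame(rows)


def generate_fractionation_experiment(
    mixture: list[SuspensionComponent],
    runs: list,
    scenario: ScenarioSpec,
    analyzed_volume: float = 25.0,
) -> dict:
    """A full synthetic centrifugal-fractionation dataset.

    Ground truth comes from the sequential-fractionation model; the
    pre-spin sample, each pellet, and the final supernatant then get
    TOC replicates and particle counts generated per the scenario's
    noise settings.  The truth is stored alongside the observations so
    recovery of known parameters can be tested.
    """
    truth_stages = simulate_sequential_fractionation(mixture, runs)
    rng = scenario.rng()

    def observe(components: tuple[SuspensionComponent, ...]) -> dict:
        sub = ScenarioSpec(
            components=components,
            doc_background=scenario.doc_background,
            tic_background=scenario.tic_background,
            cv_tc=scenario.cv_tc,
            cv_tic=scenario.cv_tic,
            cv_spes=scenario.cv_spes,
            stirred=scenario.stirred,
            dead_time=scenario.dead_time,
            intake_height=scenario.intake_height,
            fluid=scenario.fluid,
            seed=scenario.seed,
        )
        return {
            "toc": simulate_toc_replicates(sub, rng=rng),
            "spes": simulate_spes_counts(sub, analyzed_volume, rng=rng),
            "true_tc": sub.true_tc(),
        }

    def as_components(conc: dict[str, float]) -> tuple[SuspensionComponent, ...]:
        by_name = {c.name: c for c in mixture}
        return tuple(
            SuspensionComponent(by_name[n].particle, conc[n], name=n) for n in conc
        )

    samples = {"initial": observe(tuple(mixture))}
    for res in truth_stages:
        samples[f"pellet_{res.stage}"] = observe(as_components(res.pellet_mass))
    samples["final_supernatant"] = observe(
        as_components(truth_stages[-1].supernatant_concentration)
    )
    return {"truth": truth_stages, "samples": samples, "scenario": scenario}


def estimate_mass_concentration_from_toc_table(
    toc_table: pd.DataFrame,
    doc_background: float,
    carbon_fraction: float,
    cv_tc: float,
    cv_tic: float,
    cv_threshold: float = 100.0,
    sample_id: int = 0,
) -> UValue:
    """Reduce a replicate table to a total particulate mass concentration.

    Applies the replicate acceptance rule per channel, forms
    TOC = TC - TIC, removes the known dissolved background and divides
    by the carbon fraction.  The combined standard uncertainty uses the
    known instrument CVs (each accepted value is a mean of two
    replicates, hence cv/sqrt(2)) propagated in quadrature.  The default
    CV acceptance threshold is permissive because noisy synthetic
    scenarios routinely exceed the instrument's 2 %.
    """
    sub = toc_table[toc_table["sample_id"] == sample_id]
    accepted = {}
    for channel in ("TC", "TIC"):
        values = list(
            sub[sub["channel"] == channel].sort_values("replicate_no")["value_mg_per_L"]
        )
        try:
            rec = accept_replicates(values, cv_threshold=cv_threshold, channel=channel)
        except ThirdReplicateNeeded:
            rec = accept_replicates(values + [values[-1]], channel=channel)
        accepted[channel] = rec.accepted_value
    toc = toc_from_tc_tic(accepted["TC"], accepted["TIC"])
    u_tc = cv_tc * accepted["TC"] / math.sqrt(2.0)
    u_tic = cv_tic * accepted["TIC"] / math.sqrt(2.0)
    net = toc - doc_background
    u = math.hypot(u_tc, u_tic)
    return UValue(net / carbon_fraction, u / carbon_fraction)
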