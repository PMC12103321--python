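"""Recompute the reference results from the bundled study inputs.

Everything here is recomputed at call time from the printed inputs of
the experiments the package models (run settings, mixture composition,
net carbon concentrations) — nothing is looked up.  The reference
column only serves the pass/fail comparison.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from . import quantify, sedimentation, toc
from .formulas import get_material
from .quantify import UValue
from .sedimentation import (
    CentrifugeRun,
    FluidSpec,
    ParticleSpec,
    SuspensionComponent,
    simulate_sequential_fractionation,
)

__all__ = ["study_inputs", "build_runs", "build_mixture", "reproduce_reference_results"]


def study_inputs() -> dict:
    """The bundled reference dataset (parsed JSON)."""
    return json.loads(
        resources.files("fractoc.data").joinpath("study_inputs.json").read_text()
    )


def build_runs(inputs: dict | None = None) -> list[CentrifugeRun]:
    """The two reference spins, reconstructed from their RCF-gradient
    endpoints, column height and duration."""
    inputs = inputs or study_inputs()
    fluid = FluidSpec(**inputs["fluid"])
    return [
        CentrifugeRun.from_rcf_gradient(
            r["rcf_top"],
            r["rcf_bottom"],
            r["column_height_mm"],
            r["duration_min"] * 60.0,
            fluid,
        )
        for r in inputs["runs"]
    ]


def build_mixture(inputs: dict | None = None) -> list[SuspensionComponent]:
    inputs = inputs or study_inputs()
    density = inputs["ps_density"]
    return [
        SuspensionComponent(
            ParticleSpec.from_size(
                c["diameter_nm"], "nm", density, get_material(c["polymer"])
            ),
            c["mg_per_L"],
        )
        for c in inputs["mixture"]
    ]


def reproduce_reference_results(uncertainty_rule: str = "quadrature") -> pd.DataFrame:
    """Recompute every reference quantity and compare at its tolerance.

    Returns a table (quantity, computed, reference, tolerance, unit,
    passed).  Central values are insensitive to the uncertainty rule;
    uncertainty columns are not.
    """
    inputs = study_inputs()
    ps = get_material("PS")
    density = inputs["ps_density"]
    runs = build_runs(inputs)
    mixture = build_mixture(inputs)

    rows: list[dict] = []

    def add(name, computed, reference, tol, unit):
        rows.append(
            {
                "quantity": name,
                "computed": computed,
                "reference": reference,
                "tolerance": tol,
                "unit": unit,
                "passed": abs(computed - reference) <= tol,
            }
        )

    # effective cutoffs from reconstructed geometry, +-0.5 %
    for run, spec, ref in zip(runs, inputs["runs"], (1341.0, 724.0)):
        add(
            f"effective cutoff {spec['name']}",
            sedimentation.effective_cutoff_diameter(run, density),
            ref,
            0.005 * ref,
            "nm",
        )

    # sequential pellet composition shares, +-0.3 points
    stages = simulate_sequential_fractionation(mixture, runs)
    f1, f2 = stages[0].pellet_shares, stages[1].pellet_shares
    add("F1 share PS 1000 nm", f1["PS 1000 nm"], 75.1, 0.3, "%")
    add("F1 share PS 500 nm", f1["PS 500 nm"], 21.3, 0.3, "%")
    add("F2 share PS 500 nm", f2["PS 500 nm"], 49.5, 0.3, "%")
    add("F2 share PS 1000 nm", f2["PS 1000 nm"], 39.9, 0.3, "%")

    # injection statistics (rounded display counts; Poisson zero odds)
    ps30 = ParticleSpec.from_size(30.0, "um", density, ps)
    ps90 = ParticleSpec.from_size(90.0, "um", density, ps)
    add(
        "particles injected, 30 um standard plan",
        float(toc.expected_particles_injected(5.0, 50.0, ps30).rounded),
        18.0,
        0.0,
        "count",
    )
    add(
        "particles injected, 90 um modified plan",
        float(toc.expected_particles_injected(25.0, 500.0, ps90).rounded),
        34.0,
        0.0,
        "count",
    )
    mean90 = toc.expected_particles_injected(5.0, 50.0, ps90).expected
    add(
        "P(zero particles), 90 um standard plan",
        float(toc.injection_count_distribution(mean90)[0]),
        0.5,
        0.1,
        "probability",
    )

    # carbon fractions at two-decimal display rounding
    for mat, ref in (("PS", 92.26), ("KHP", 47.05), ("Na2CO3", 11.33)):
        add(
            f"carbon fraction {mat}",
            round(100.0 * get_material(mat).carbon_fraction, 2),
            ref,
            0.0,
            "%",
        )

    # spike equivalent carbon at the table's 4-decimal display rounding
    spike = [(ps, s["mg_per_L"]) for s in inputs["spike_recovery_table"]["spike"]]
    add(
        "spike equivalent carbon (1+1 mg/L PS)",
        round(quantify.spike_equivalent_carbon(spike), 4),
        1.8452,
        0.0,
        "mg C/L",
    )

    # spike recoveries against the ultrapure-water reference, +-1 integer %
    net = inputs["spike_recovery_table"]["net_toc_mg_per_L"]
    for matrix, condition, ref in (("lake", "unfiltered", 96.0), ("river", "filtered", 70.0)):
        measured = UValue(**net[matrix][condition])
        reference = UValue(**net["UPW"][condition])
        rec = quantify.recovery(measured, reference, rule=uncertainty_rule)
        add(f"spike recovery, {matrix} {condition}", float(rec.rounded), ref, 1.0, "%")

    # subtraction estimator for the counter-invisible 200 nm component
    pre = inputs["pre_centrifugation_recoveries"]
    total_nominal = pre["toc_total_pct"]["nominal_mg_per_L"]
    comp_nominal = pre["spes_500_pct"]["nominal_mg_per_L"]
    total = UValue(
        pre["toc_total_pct"]["value"] / 100.0 * total_nominal,
        pre["toc_total_pct"]["u"] / 100.0 * total_nominal,
    )
    comps = [
        UValue(
            pre[k]["value"] / 100.0 * pre[k]["nominal_mg_per_L"],
            pre[k]["u"] / 100.0 * pre[k]["nominal_mg_per_L"],
        )
        for k in ("spes_500_pct", "spes_1000_pct")
    ]
    sub = quantify.subtraction_estimator(
        total, comps, nominal=comp_nominal, rule=uncertainty_rule
    )
    add("subtraction recovery, PS 200 nm", sub.recovery.value, 81.5, 0.3, "%")

    return pd.DataFrame(rows)
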