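"""YAML descriptions of runs, mixtures and scenarios.

Keeps the on-disk schema in one place so generated datasets and analysis
inputs round-trip through the same field names the dataclasses use.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .formulas import get_material
from .sedimentation import (
    WATER_20C,
    CentrifugeRun,
    FluidSpec,
    ParticleSpec,
    SuspensionComponent,
)
from .synthetic import ScenarioSpec

__all__ = ["load_fluid", "load_runs", "load_mixture", "load_scenario"]


def load_fluid(entry: dict | None) -> FluidSpec:
    return FluidSpec(**entry) if entry else WATER_20C


def load_runs(doc: dict) -> list[CentrifugeRun]:
    """Runs given either as radii (r_top_mm/r_bottom_mm) or as an RCF
    gradient (rcf_top/rcf_bottom + column_height_mm), plus duration_min."""
    fluid = load_fluid(doc.get("fluid"))
    runs = []
    for entry in doc["runs"]:
        duration = entry["duration_min"] * 60.0
        if "rcf_top" in entry:
            runs.append(
                CentrifugeRun.from_rcf_gradient(
                    entry["rcf_top"],
                    entry["rcf_bottom"],
                    entry["column_height_mm"],
                    duration,
                    fluid,
                )
            )
        else:
            runs.append(
                CentrifugeRun(
                    entry["r_top_mm"],
                    entry["r_bottom_mm"],
                    entry["angular_speed_rad_s"],
                    duration,
                    fluid,
                )
            )
    return runs


def load_mixture(doc: dict) -> list[SuspensionComponent]:
    return [
        SuspensionComponent(
            ParticleSpec.from_size(
                entry["diameter_nm"],
                "nm",
                entry.get("density", 1.05),
                get_material(entry["polymer"]) if "polymer" in entry else None,
            ),
            entry["mg_per_L"],
            name=entry.get("name", ""),
        )
        for entry in doc["mixture"]
    ]


def load_scenario(path: str | Path) -> ScenarioSpec:
    """A full synthetic scenario: mixture plus noise/background settings."""
    doc = yaml.safe_load(Path(path).read_text())
    components = tuple(load_mixture(doc))
    fields = {
        k: doc[k]
        for k in (
            "doc_background",
            "tic_background",
            "cv_tc",
            "cv_tic",
            "cv_spes",
            "stirred",
            "dead_time",
            "intake_height",
            "seed",
        )
        if k in doc
    }
    return ScenarioSpec(
        components=components, fluid=load_fluid(doc.get("fluid")), **fields
    )
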